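"""Orthogonal preparatory and movement subspaces.

Non-jump condition-averaged rates from the delay epoch (0-300 ms after
target onset) and the movement epoch (0-300 ms after movement onset) are
arranged as n x (conditions * timepoints) matrices, projected into the
null space of the trigger dimension and row-centered.  With C_prep and
C_move their covariance matrices and sigma(i) the i-th singular value,
the subspaces maximize the mean normalized captured variance

    J(Q_prep, Q_move) = 1/2 [ Tr(Q_prep' C_prep Q_prep) / sum_i^d_prep sigma_prep(i)
                            + Tr(Q_move' C_move Q_move) / sum_i^d_move sigma_move(i) ]

subject to Q_prep' Q_move = 0 and both bases orthonormal.  J is at most 1,
with equality exactly when each basis spans its covariance's top
eigenspace.  The constraint set is the Stiefel manifold of joint
orthonormal frames [Q_prep | Q_move]; we ascend it by Riemannian gradient
steps with QR retraction and a backtracking line search (monotone by
construction), from multiple seeded starts plus a spectral start.

Subspace dimensionalities follow the variance rule: the smallest d whose
top-d principal components explain strictly more than 70% of the epoch's
variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .errors import ArgumentError, DimensionError, OptimizationError, \
    StatisticsError
from .preprocess import ConditionAverage


@dataclass
class EpochData:
    """Null-space epoch matrices and their covariances (inputs to J)."""

    X_prep: np.ndarray        # (n-1) x (c*t), row-centered
    X_move: np.ndarray
    C_prep: np.ndarray
    C_move: np.ndarray
    sv_prep: np.ndarray       # eigenvalues of C_prep, descending
    sv_move: np.ndarray
    null_basis: np.ndarray    # n x (n-1): lifts null-space coords to units
    trigger_w: np.ndarray


@dataclass
class SubspacePair:
    Q_prep: np.ndarray        # (n-1) x d_prep
    Q_move: np.ndarray        # (n-1) x d_move
    d_prep: int
    d_move: int
    objective: float
    term_prep: float          # normalized captured variance per epoch
    term_move: float
    null_basis: np.ndarray | None = None
    objective_history: np.ndarray | None = None

    def lift(self, Q: np.ndarray) -> np.ndarray:
        """Express a null-space basis in the original unit space."""
        if self.null_basis is None:
            raise ArgumentError("no trigger null basis attached")
        return self.null_basis @ Q


def epoch_matrix(avg: ConditionAverage, window: tuple,
                 keys=None) -> np.ndarray:
    """Stack condition averages into n x (c*t) over a time window."""
    if keys is None:
        keys = sorted(avg.groups)
    mask = (avg.time >= window[0] - 1e-9) & (avg.time <= window[1] + 1e-9)
    if not mask.any():
        raise ArgumentError(f"window {window} outside the averaged grid")
    return np.hstack([avg.groups[k][:, mask] for k in keys])


def project_trigger_null(X: np.ndarray, w: np.ndarray):
    """Coordinates of unit-space data in the trigger dimension's complement.

    Returns ``(X_null, K)`` with K an orthonormal n x (n-1) basis of the
    complement; ``K @ X_null + w (w . x)`` reconstructs the data exactly.
    """
    w = np.asarray(w, dtype=float)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ArgumentError("trigger vector must be nonzero")
    K = null_space(w.reshape(1, -1) / nw)
    return K.T @ X, K


def choose_dims(X: np.ndarray, threshold: float = 0.70) -> int:
    """Smallest d whose top-d principal components exceed ``threshold``
    cumulative variance (strict: a tie at the threshold resolves upward)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    ev = np.linalg.eigvalsh(Xc @ Xc.T)[::-1]
    ev = np.maximum(ev, 0.0)
    total = ev.sum()
    if total <= 0:
        raise DimensionError("epoch data have no variance")
    frac = np.cumsum(ev) / total
    above = np.nonzero(frac > threshold + 1e-12)[0]
    if above.size == 0:
        raise DimensionError(f"threshold {threshold} unreachable")
    return int(above[0]) + 1


def build_epoch_data(avg_delay: ConditionAverage, avg_move: ConditionAverage,
                     trigger_w: np.ndarray, delay_window: tuple = (0.0, 0.3),
                     move_window: tuple = (0.0, 0.3)) -> EpochData:
    """Assemble Eq-ready epoch matrices: null-project then row-center."""
    Xp = epoch_matrix(avg_delay, delay_window)
    Xm = epoch_matrix(avg_move, move_window)
    Xp_n, K = project_trigger_null(Xp, trigger_w)
    Xm_n = K.T @ Xm
    Xp_n = Xp_n - Xp_n.mean(axis=1, keepdims=True)
    Xm_n = Xm_n - Xm_n.mean(axis=1, keepdims=True)
    Cp = Xp_n @ Xp_n.T / max(Xp_n.shape[1] - 1, 1)
    Cm = Xm_n @ Xm_n.T / max(Xm_n.shape[1] - 1, 1)
    return EpochData(
        X_prep=Xp_n, X_move=Xm_n, C_prep=Cp, C_move=Cm,
        sv_prep=np.sort(np.linalg.eigvalsh(Cp))[::-1],
        sv_move=np.sort(np.linalg.eigvalsh(Cm))[::-1],
        null_basis=K, trigger_w=np.asarray(trigger_w, float))


def _check_psd(C, name):
    C = 0.5 * (C + C.T)
    ev = np.linalg.eigvalsh(C)
    if ev[-1] <= 0:
        raise ArgumentError(f"{name} has no positive eigenvalue")
    if ev[0] < -1e-8 * ev[-1]:
        raise ArgumentError(f"{name} is not positive semidefinite")
    return C


def _objective_terms(Qp, Qm, Cp, Cm, sp, sm):
    tp = float(np.trace(Qp.T @ Cp @ Qp)) / sp
    tm = float(np.trace(Qm.T @ Cm @ Qm)) / sm
    return tp, tm


def _retract(Y):
    Q, R = np.linalg.qr(Y)
    return Q * np.sign(np.diag(R))


def optimize_subspaces(epochs: EpochData, d_prep: int, d_move: int,
                       seed: int = 0, n_starts: int = 10, tol: float = 1e-9,
                       max_iter: int = 1000) -> SubspacePair:
    """Maximize J over joint orthonormal frames; multi-start, keep the best."""
    Cp = _check_psd(epochs.C_prep, "C_prep")
    Cm = _check_psd(epochs.C_move, "C_move")
    n = Cp.shape[0]
    if d_prep + d_move > n:
        raise ArgumentError("d_prep + d_move exceeds the null-space dimension")
    if d_prep < 1 or d_move < 1:
        raise ArgumentError("subspace dimensions must be >= 1")
    sp = float(epochs.sv_prep[:d_prep].sum())
    sm = float(epochs.sv_move[:d_move].sum())
    if sp <= 0 or sm <= 0:
        raise ArgumentError("epoch covariance is rank-deficient below d")

    def J(Q):
        tp, tm = _objective_terms(Q[:, :d_prep], Q[:, d_prep:], Cp, Cm, sp, sm)
        return 0.5 * (tp + tm)

    def rgrad(Q):
        G = np.empty_like(Q)
        G[:, :d_prep] = Cp @ Q[:, :d_prep] / sp
        G[:, d_prep:] = Cm @ Q[:, d_prep:] / sm
        QtG = Q.T @ G
        return G - Q @ (0.5 * (QtG + QtG.T))

    # spectral start: top prep eigenvectors, then top move eigenvectors
    # orthogonalized against them
    ep = np.linalg.eigh(Cp)
    Vp = ep.eigenvectors[:, ::-1][:, :d_prep]
    em = np.linalg.eigh(Cm)
    Vm = em.eigenvectors[:, ::-1][:, : d_move + d_prep]
    Vm_perp = Vm - Vp @ (Vp.T @ Vm)
    q, r = np.linalg.qr(Vm_perp)
    keep = np.abs(np.diag(r)) > 1e-12
    Vm_o = q[:, keep][:, :d_move]
    if Vm_o.shape[1] < d_move:  # fall back to any completion
        Vm_o = _retract(np.hstack([Vp, np.eye(n)[:, : d_move + d_prep]])
                        )[:, d_prep:d_prep + d_move]
    starts = [np.hstack([Vp, Vm_o])]
    rng = np.random.default_rng(seed)
    for _ in range(max(n_starts - 1, 0)):
        starts.append(_retract(rng.standard_normal((n, d_prep + d_move))))

    best = None
    for Q0 in starts:
        Q = Q0
        f = J(Q)
        hist = [f]
        step = 1.0
        converged = False
        for _ in range(max_iter):
            xi = rgrad(Q)
            gnorm2 = float(np.sum(xi * xi))
            if gnorm2 < 1e-24:
                converged = True
                break
            improved = False
            while step > 1e-14:
                Q_new = _retract(Q + step * xi)
                f_new = J(Q_new)
                if f_new >= f + 1e-4 * step * gnorm2:
                    improved = True
                    break
                step *= 0.5
            if not improved:
                converged = True
                break
            gain = f_new - f
            Q, f = Q_new, f_new
            hist.append(f)
            step = min(step * 1.8, 1e6)
            if gain < tol:
                converged = True
                break
        if not converged:
            continue
        if best is None or f > best[1]:
            best = (Q, f, np.asarray(hist))
    if best is None:
        raise OptimizationError(
            "no start converged; check covariance conditioning")
    Q, f, hist = best
    tp, tm = _objective_terms(Q[:, :d_prep], Q[:, d_prep:], Cp, Cm, sp, sm)
    return SubspacePair(Q_prep=Q[:, :d_prep], Q_move=Q[:, d_prep:],
                        d_prep=d_prep, d_move=d_move, objective=f,
                        term_prep=tp, term_move=tm,
                        null_basis=epochs.null_basis, objective_history=hist)


@dataclass
class VarianceTrace:
    time: np.ndarray
    var_prep: np.ndarray
    var_move: np.ndarray
    var_total: np.ndarray

    @property
    def share_prep(self):
        return self.var_prep / np.maximum(self.var_total, 1e-300)

    @property
    def share_move(self):
        return self.var_move / np.maximum(self.var_total, 1e-300)


def cross_condition_variance(avg_null: ConditionAverage,
                             pair: SubspacePair) -> VarianceTrace:
    """Across-condition variance summed over each subspace's dimensions.

    ``avg_null`` must hold condition averages already expressed in the
    trigger null-space coordinates (same space as the Q bases).  The
    normalized shares divide by the variance summed over the full space.
    """
    keys = sorted(avg_null.groups)
    if len(keys) < 2:
        raise StatisticsError("cross-condition variance needs >= 2 conditions")
    M = np.stack([avg_null.groups[k] for k in keys])      # C x (n-1) x T
    if M.shape[1] != pair.Q_prep.shape[0]:
        raise DimensionError(
            f"averages have {M.shape[1]} rows; bases expect "
            f"{pair.Q_prep.shape[0]}")
    Mc = M - M.mean(axis=0, keepdims=True)
    denom = len(keys) - 1

    def _var(Q):
        proj = np.einsum("cnt,nd->cdt", Mc, Q)
        return (proj ** 2).sum(axis=(0, 1)) / denom

    var_total = (Mc ** 2).sum(axis=(0, 1)) / denom
    return VarianceTrace(time=avg_null.time, var_prep=_var(pair.Q_prep),
                         var_move=_var(pair.Q_move), var_total=var_total)


def project_average(avg: ConditionAverage, K: np.ndarray) -> ConditionAverage:
    """Express a unit-space ConditionAverage in null-space coordinates."""
    return ConditionAverage(
        groups={k: K.T @ v for k, v in avg.groups.items()},
        counts=dict(avg.counts), time=avg.time, alignment=avg.alignment,
        unit_ids=[f"null{k}" for k in range(K.shape[1])])
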