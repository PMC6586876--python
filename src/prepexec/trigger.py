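"""The trigger dimension: decoding when (not where) a reach is initiated.

A linear SVM is trained on single-timepoint population rate vectors from
non-jump trials, pooling all reach directions: points 360-180 ms before
movement onset form one class, points from 120 ms before to 60 ms after
onset the other.  The unit-normalized hyperplane normal is the trigger
dimension; the signed decision value's first zero crossing after the go
cue is the per-trial neural trigger event.  On jump trials the offset
between that event and the jump time predicts the initial reach angle via
a sigmoid, scored with leave-one-out cross-validated R^2
(R^2 = 1 - SS_res/SS_tot on the held-out predictions, which can be
negative).  A bootstrap against random unit-sphere projections tests
whether the weights concentrate on a subset of units (kurtosis test).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

from .errors import (
    ArgumentError,
    DatasetExclusionError,
    StatisticsError,
    TrainingError,
)
from .behavior import fit_sigmoid_params, _logistic4
from .preprocess import RateTensor
from .session import Session

PRE_EPOCH = (-0.360, -0.180)   # relative to movement onset, [start, end)
PERI_EPOCH = (-0.120, 0.060)


@dataclass
class TriggerModel:
    w: np.ndarray               # unit-norm weights, one per unit
    b: float                    # offset on the same scale
    unit_ids: list
    regions: list
    pre_epoch: tuple = PRE_EPOCH
    peri_epoch: tuple = PERI_EPOCH
    heldout_fraction: float = 0.1
    heldout_accuracy: float = np.nan
    heldout_trials: list = field(default_factory=list)

    def decision(self, x: np.ndarray) -> np.ndarray:
        """Signed activity in the trigger dimension for (n_units, T) rates."""
        return self.w @ x + self.b


@dataclass
class TriggerEvent:
    trial_id: str
    crossing_time: float | None        # absolute trial time, seconds
    offset_vs_jump: float | None = None  # crossing - jump_time, jump trials


def _epoch_mask(time: np.ndarray, epoch: tuple) -> np.ndarray:
    return (time >= epoch[0] - 1e-9) & (time < epoch[1] - 1e-9)


def train_trigger_svm(rates: RateTensor, session: Session, seed: int = 0,
                      heldout_fraction: float = 0.1, C: float = 1e-3,
                      pre_epoch: tuple = PRE_EPOCH,
                      peri_epoch: tuple = PERI_EPOCH,
                      class_labels: dict | None = None) -> TriggerModel:
    """Fit the movement-onset classifier on non-jump trials.

    ``rates`` must be movement-onset aligned and normalized.  A random 10%
    of non-jump trials is held out; the reported accuracy is the fraction
    of their epoch timepoints classified correctly.  ``class_labels`` maps
    trial_id -> permuted 0/1 epoch-swap labels for shuffle controls.

    The sign convention makes decision values negative in the pre epoch
    and positive around movement onset; (w, b) are scaled so ||w|| = 1,
    which leaves the zero crossing unchanged.
    """
    if rates.alignment != "move_onset":
        raise ArgumentError("trigger training requires move_onset alignment")
    if rates.n_units < 10:
        raise DatasetExclusionError(
            f"dataset has {rates.n_units} units; need >= 10")
    nonjump = [t.trial_id for t in session.trials
               if not t.is_jump and t.trial_id in rates.trial_ids]
    if len(nonjump) < 10:
        raise TrainingError("too few non-jump trials for a held-out split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(nonjump))
    n_held = max(1, int(round(heldout_fraction * len(nonjump))))
    held = [nonjump[i] for i in order[:n_held]]
    train = [nonjump[i] for i in order[n_held:]]

    mask_pre = _epoch_mask(rates.time, pre_epoch)
    mask_peri = _epoch_mask(rates.time, peri_epoch)
    if not mask_pre.any() or not mask_peri.any():
        raise ArgumentError("rate tensor window does not cover the epochs")

    def _points(trial_ids):
        X, y = [], []
        for tid in trial_ids:
            v = rates.values[:, :, rates.trial_index(tid)]
            lab = (0, 1)
            if class_labels is not None and class_labels.get(tid, 0):
                lab = (1, 0)
            X.append(v[:, mask_pre].T)
            y.append(np.full(mask_pre.sum(), lab[0]))
            X.append(v[:, mask_peri].T)
            y.append(np.full(mask_peri.sum(), lab[1]))
        return np.vstack(X), np.concatenate(y)

    X_train, y_train = _points(train)
    if len(np.unique(y_train)) < 2:
        raise TrainingError("training data contain a single class")
    clf = LinearSVC(C=C, max_iter=20000, tol=1e-5)
    clf.fit(X_train, y_train)
    w = clf.coef_[0].astype(float)
    b = float(clf.intercept_[0])
    # canonical sign: peri-epoch decision values positive on training data
    peri_mean = float(np.mean((X_train[y_train == 1] @ w) + b))
    if peri_mean < 0:
        w, b = -w, -b
    scale = np.linalg.norm(w)
    w, b = w / scale, b / scale

    X_held, y_held = _points(held)
    pred = ((X_held @ w) + b) > 0
    acc = float(np.mean(pred == (y_held == 1)))
    regions = [u.region for u in session.units]
    return TriggerModel(w=w, b=b, unit_ids=list(rates.unit_ids),
                        regions=regions, pre_epoch=pre_epoch,
                        peri_epoch=peri_epoch,
                        heldout_fraction=heldout_fraction,
                        heldout_accuracy=acc, heldout_trials=held)


def trigger_crossing_time(decision: np.ndarray, time: np.ndarray):
    """First upward zero crossing d(t-) < 0 <= d(t), linearly interpolated.

    ``time`` must start at (or after) the go cue.  Returns the crossing
    time on the same axis, or ``None`` (absence is a valid outcome).
    """
    d = np.asarray(decision, dtype=float)
    for k in range(1, d.size):
        if d[k - 1] < 0.0 <= d[k]:
            frac = -d[k - 1] / (d[k] - d[k - 1])
            return float(time[k - 1] + frac * (time[k] - time[k - 1]))
    return None


def trigger_events(model: TriggerModel, rates: RateTensor,
                   session: Session) -> list:
    """Per-trial trigger events from go-cue-aligned normalized rates."""
    if rates.alignment != "go_cue":
        raise ArgumentError("trigger events require go_cue alignment")
    by_trial = {t.trial_id: t for t in session.trials}
    grid = rates.time[rates.time >= -1e-9]
    keep = rates.time >= -1e-9
    events = []
    for idx, tid in enumerate(rates.trial_ids):
        trial = by_trial[tid]
        d = model.decision(rates.values[:, keep, idx])
        rel = trigger_crossing_time(d, grid)
        if rel is None:
            events.append(TriggerEvent(tid, None))
            continue
        crossing = trial.go_cue_time + rel
        offset = crossing - trial.jump_time if trial.jump_time is not None \
            else None
        events.append(TriggerEvent(tid, crossing, offset))
    return events


def r_squared(y_pred, y) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = float(np.sum((y_pred - y) ** 2))
    ss_tot = float(np.sum((y.mean() - y) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


@dataclass
class BehaviorPrediction:
    r2: float
    accuracy: float
    n_trials: int
    fit_params: tuple              # (lower, upper, t50, slope) on all trials
    predictions: np.ndarray
    observed: np.ndarray


def predict_jump_behavior(offsets_ms: dict, angles: dict,
                          min_trials: int = 8):
    """Leave-one-out sigmoid prediction of initial angle from trigger offset.

    ``offsets_ms``/``angles`` map jump condition -> per-trial arrays of
    (trigger crossing - jump) in ms and normalized angles.  Per condition,
    a sigmoid fitted on all-but-one trials predicts the left-out angle;
    R^2 is computed on those held-out predictions and accuracy is the
    fraction of trials predicted on the correct side of zero (nearer -1
    vs nearer +1).  Conditions below ``min_trials`` are skipped.
    """
    results, skipped = {}, []
    for cond in offsets_ms:
        t = np.asarray(offsets_ms[cond], dtype=float)
        y = np.asarray(angles[cond], dtype=float)
        ok = np.isfinite(t) & np.isfinite(y)
        t, y = t[ok], y[ok]
        if t.size < min_trials:
            skipped.append((cond, f"{t.size} usable trials"))
            continue
        try:
            full_params, _ = fit_sigmoid_params(t, y)
        except Exception as e:
            skipped.append((cond, str(e)))
            continue
        span = max(float(t.max() - t.min()), 1.0)
        bounds = ([-1.5, 0.0, t.min() - span, 1e-3],
                  [0.0, 1.5, t.max() + span, 10.0 * span])
        preds = np.empty(t.size)
        from scipy.optimize import curve_fit
        for i in range(t.size):
            m = np.ones(t.size, bool)
            m[i] = False
            try:
                popt, _ = curve_fit(_logistic4, t[m], y[m], p0=full_params,
                                    bounds=bounds, maxfev=800)
            except RuntimeError:
                popt = full_params
            preds[i] = _logistic4(t[i], *popt)
        acc = float(np.mean((preds > 0) == (y > 0)))
        results[cond] = BehaviorPrediction(
            r2=r_squared(preds, y), accuracy=acc, n_trials=int(t.size),
            fit_params=tuple(full_params), predictions=preds, observed=y)
    return results, skipped


def sample_null_kurtoses(dim: int, n_random: int = 10000, seed: int = 0,
                         excess: bool = False) -> np.ndarray:
    """Kurtoses of unit vectors uniform on the sphere (isotropic Gaussian,
    normalized) — the rotation-invariant null for projection weights."""
    rng = np.random.default_rng(seed)
    V = rng.standard_normal((n_random, dim))
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    return stats.kurtosis(V, axis=1, fisher=excess, bias=True)


@dataclass
class KurtosisTest:
    kurtosis: float
    p_value: float
    significant: bool
    null_q95: float
    n_random: int


def kurtosis_projection_test(w: np.ndarray, n_random: int = 10000,
                             seed: int = 0,
                             null_kurtoses: np.ndarray | None = None,
                             excess: bool = False) -> KurtosisTest:
    """Is the weight vector more concentrated than a random projection?

    The statistic is the sample kurtosis of the entries of ``w``
    (fourth standardized moment by default, excess with ``excess=True``;
    the choice shifts observed and null identically, so p-values do not
    depend on it); the null is ``n_random`` uniform unit vectors in the
    same dimension; p is the fraction of null kurtoses >= the observed
    value.
    """
    w = np.asarray(w, dtype=float)
    if w.size < 4:
        raise ArgumentError("kurtosis test needs >= 4 units")
    if np.ptp(w) == 0:
        raise StatisticsError("kurtosis undefined for a constant weight vector")
    k = float(stats.kurtosis(w, fisher=excess, bias=True))
    if null_kurtoses is None:
        null_kurtoses = sample_null_kurtoses(w.size, n_random, seed, excess)
    p = float(np.mean(null_kurtoses >= k))
    q95 = float(np.percentile(null_kurtoses, 95))
    return KurtosisTest(kurtosis=k, p_value=p, significant=k > q95,
                        null_q95=q95, n_random=len(null_kurtoses))
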