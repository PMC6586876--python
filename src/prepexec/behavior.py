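"""Behavioral characterization of target-jump responses.

The initial reach angle is the hand's direction when it first crosses a
1 cm radius from the start position.  Per jump condition, angles are
normalized onto the first->final target axis (-1 = first target's
direction, +1 = final target's; overshoots may exceed +/-1) and fitted
against the jump-to-movement-onset latency with a 4-parameter logistic.
The fit's 5%/50%/95% crossing times summarize when behavior starts,
transitions and finishes responding to the jump; a trial bootstrap gives
the confidence interval on the 50% crossing used to filter unreliable
conditions (CI half-width must be < 50 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from .errors import ArgumentError, BehaviorError, FitError, StatisticsError
from .session import JumpCondition, Trial


@dataclass
class SigmoidFit:
    """4-parameter logistic y = lower + (upper-lower) / (1 + exp(-(t-t50)/s))."""

    lower: float
    upper: float
    t50: float          # ms
    slope: float        # logistic scale s, ms (transition width)
    crossings: dict     # fraction -> ms
    ci50: float | None  # half-width of 95% bootstrap CI on t50, ms
    n_trials: int
    goodness: float     # in-sample fraction of variance explained

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return _logistic4(t, self.lower, self.upper, self.t50, self.slope)


def initial_reach_angle(trial: Trial, radius: float = 1.0) -> float:
    """Hand direction (degrees, atan2 convention) at the 1 cm radius crossing."""
    traj = trial.hand_trajectory
    r = np.hypot(traj[:, 1], traj[:, 2])
    beyond = np.nonzero(r >= radius)[0]
    if beyond.size == 0:
        raise BehaviorError(
            f"trial {trial.trial_id}: hand never reaches {radius} cm")
    i = int(beyond[0])
    if i == 0:
        x, y = traj[0, 1], traj[0, 2]
    else:
        frac = (radius - r[i - 1]) / (r[i] - r[i - 1])
        x = traj[i - 1, 1] + frac * (traj[i, 1] - traj[i - 1, 1])
        y = traj[i - 1, 2] + frac * (traj[i, 2] - traj[i - 1, 2])
    return float(np.degrees(np.arctan2(y, x)))


def normalize_angle(angle_deg: float, condition: JumpCondition) -> float:
    """Map a reach angle onto the first->final axis: -1 first, +1 final.

    The map is linear in angular position along the shorter arc between
    the two target directions (for 180 degrees the +180 arc is used);
    reaches beyond either target give values outside [-1, 1].
    """
    th1 = np.degrees(np.arctan2(condition.first_target_xy[1],
                                condition.first_target_xy[0]))
    th2 = np.degrees(np.arctan2(condition.final_target_xy[1],
                                condition.final_target_xy[0]))
    delta = (th2 - th1 + 180.0) % 360.0 - 180.0
    if delta == -180.0:
        delta = 180.0
    if abs(delta) < 1e-9:
        raise BehaviorError("first and final target directions coincide")
    # branch cut opposite the arc midpoint, so overshoots just past either
    # target stay continuous (+/-1 and a bit, not a 360-degree wrap)
    d = (angle_deg - th1 - delta / 2.0 + 180.0) % 360.0 - 180.0 + delta / 2.0
    return float(2.0 * d / delta - 1.0)


def _logistic4(t, lower, upper, t50, s):
    return lower + (upper - lower) * expit((t - t50) / s)


def _fit_once(t, y, p0, bounds):
    popt, _ = optimize.curve_fit(_logistic4, t, y, p0=p0, bounds=bounds,
                                 maxfev=2000)
    resid = y - _logistic4(t, *popt)
    return popt, float(np.sum(resid ** 2))


def fit_sigmoid_params(latencies_ms: np.ndarray, angles: np.ndarray,
                       n_starts: int = 5, asymptote_limit: float = 1.5):
    """Bounded least-squares 4PL fit with a deterministic t50 multi-start.

    ``asymptote_limit`` bounds the asymptotes to [-limit, 0] and
    [0, limit]; 1.0 pins them to the normalized target directions, the
    default 1.5 tolerates overshoot reaches.  Returns (params, sse).
    Raises :class:`FitError` when the angles carry no transition (all on
    one side of zero) or no start converges.
    """
    t = np.asarray(latencies_ms, dtype=float)
    y = np.asarray(angles, dtype=float)
    if t.size < 8:
        raise FitError(f"need >= 8 trials, got {t.size}")
    if np.all(y > 0) or np.all(y < 0):
        raise FitError("no behavioral transition: angles all on one side")
    lo, hi = float(t.min()), float(t.max())
    span = max(hi - lo, 1.0)
    bounds = ([-asymptote_limit, 0.0, lo - span, 1e-3],
              [0.0, asymptote_limit, hi + span, 10.0 * span])
    best = None
    for t50_0 in np.linspace(lo, hi, n_starts):
        try:
            popt, sse = _fit_once(t, y, [-1.0, 1.0, t50_0, span / 10.0], bounds)
        except RuntimeError:
            continue
        if best is None or sse < best[1]:
            best = (popt, sse)
    if best is None:
        raise FitError("sigmoid fit failed to converge from every start")
    return best


def fit_behavior_sigmoid(latencies_ms: np.ndarray, angles: np.ndarray,
                         n_bootstrap: int = 1000, seed: int = 0,
                         fractions=(0.05, 0.5, 0.95)) -> SigmoidFit:
    """Fit the behavioral sigmoid, its crossing times and a bootstrap CI.

    ``latencies_ms`` is movement onset minus jump time.  The 95% CI on the
    50% crossing comes from ``n_bootstrap`` trial resamples (percentile
    interval); its half-width is reported as ``ci50``.
    """
    t = np.asarray(latencies_ms, dtype=float)
    y = np.asarray(angles, dtype=float)
    (lower, upper, t50, s), sse = fit_sigmoid_params(t, y)
    crossings = {f: float(t50 + s * np.log(f / (1.0 - f))) for f in fractions}
    sstot = float(np.sum((y - y.mean()) ** 2))
    goodness = 1.0 - sse / sstot if sstot > 0 else 0.0

    ci50 = None
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        boots = []
        span = max(float(t.max() - t.min()), 1.0)
        bounds = ([-1.5, 0.0, t.min() - span, 1e-3],
                  [0.0, 1.5, t.max() + span, 10.0 * span])
        for _ in range(n_bootstrap):
            idx = rng.integers(0, t.size, t.size)
            tb, yb = t[idx], y[idx]
            if np.all(yb > 0) or np.all(yb < 0):
                continue
            try:
                popt, _ = _fit_once(tb, yb, [lower, upper, t50, s], bounds)
            except RuntimeError:
                continue
            boots.append(popt[2])
        if len(boots) >= max(20, n_bootstrap // 10):
            qlo, qhi = np.percentile(boots, [2.5, 97.5])
            ci50 = float((qhi - qlo) / 2.0)
        else:
            ci50 = np.inf
    return SigmoidFit(lower=float(lower), upper=float(upper), t50=float(t50),
                      slope=float(s), crossings=crossings, ci50=ci50,
                      n_trials=int(t.size), goodness=float(goodness))


def filter_fits_by_ci(fits: dict, max_ci_ms: float = 50.0):
    """Retain conditions whose t50 CI half-width is strictly below 50 ms."""
    retained, excluded = {}, {}
    for key, fit in fits.items():
        if fit.ci50 is not None and fit.ci50 < max_ci_ms:
            retained[key] = fit
        else:
            excluded[key] = fit
    return retained, excluded


def anova_crossing_times(values_by_angle: dict):
    """One-way ANOVA across jump angles on per-condition fit summaries.

    ``values_by_angle`` maps jump angle -> list of per-condition values
    (50% crossing times or slopes).  Returns (F, p, df_between, df_within,
    group sizes).
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_angle.values()]
    if len(groups) < 2:
        raise StatisticsError("ANOVA needs >= 2 jump-angle groups")
    ns = [g.size for g in groups]
    if min(ns) < 2:
        raise StatisticsError("each jump-angle group needs >= 2 conditions")
    if all(np.ptp(g) == 0 for g in groups) and \
            np.ptp([g[0] for g in groups]) == 0:
        # identical everywhere: no variance anywhere, F defined as 0
        return 0.0, 1.0, len(groups) - 1, sum(ns) - len(groups), ns
    F, p = stats.f_oneway(*groups)
    return float(F), float(p), len(groups) - 1, sum(ns) - len(groups), ns


def reach_probability_curve(latencies_ms: np.ndarray, final_labels,
                            bin_width_ms: float = 20.0, alpha: float = 0.05):
    """Binned probability of initiating toward the final target vs latency.

    Returns (bin centers, probability, ci_low, ci_high, n per bin) with
    Clopper-Pearson binomial intervals; empty bins are omitted.
    """
    t = np.asarray(latencies_ms, dtype=float)
    lab = np.asarray([l == "final" if isinstance(l, str) else bool(l)
                      for l in final_labels])
    if t.size == 0:
        raise ArgumentError("no trials")
    edges = np.arange(t.min(), t.max() + bin_width_ms, bin_width_ms)
    if edges.size < 2:
        edges = np.array([t.min(), t.min() + bin_width_ms])
    idx = np.clip(np.digitize(t, edges) - 1, 0, edges.size - 2)
    centers, p, lo, hi, ns = [], [], [], [], []
    for b in range(edges.size - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        k = int(lab[sel].sum())
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        p.append(k / n)
        lo.append(stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0)
        hi.append(stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0)
        ns.append(n)
    return (np.array(centers), np.array(p), np.array(lo), np.array(hi),
            np.array(ns))
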