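"""Spikes and kinematics -> aligned, soft-normalized firing-rate tensors.

Firing rates are estimated by convolving each spike train with a Gaussian
kernel (30 ms s.d. by default) evaluated analytically on a uniform grid;
near the trial boundaries the kernel is renormalized by the fraction of
its mass inside the observed window, so a spike's contribution always
integrates to one.  Rates are soft-normalized per unit: divided by the
standard deviation of the unit's rate concatenated across all trials,
floored at 1 so that near-silent units are not inflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import ndtr

from .errors import AlignmentError, ArgumentError, DetectionError
from .session import Session, Trial, Unit

ALIGNMENTS = ("target_on", "go_cue", "jump", "move_onset")


@dataclass
class RateTensor:
    """units x timepoints x trials of firing rates on an aligned grid."""

    values: np.ndarray            # (n_units, n_time, n_trials)
    time: np.ndarray              # seconds relative to the alignment event
    alignment: str
    unit_ids: list
    trial_ids: list
    normalization: np.ndarray | None = None   # per-unit divisors, >= 1
    excluded_trials: list = field(default_factory=list)

    @property
    def n_units(self):
        return self.values.shape[0]

    def trial_index(self, trial_id: str) -> int:
        return self.trial_ids.index(trial_id)

    def subset(self, trial_ids) -> "RateTensor":
        idx = [self.trial_ids.index(t) for t in trial_ids]
        return replace(self, values=self.values[:, :, idx],
                       trial_ids=list(trial_ids))


@dataclass
class ConditionAverage:
    """Per-group trial-averaged rates on a common aligned grid."""

    groups: dict                  # key -> (n_units, n_time)
    counts: dict                  # key -> number of trials
    time: np.ndarray
    alignment: str
    unit_ids: list


def _event_time(trial: Trial, alignment: str) -> float | None:
    if alignment == "target_on":
        return trial.target_on_time
    if alignment == "go_cue":
        return trial.go_cue_time
    if alignment == "jump":
        return trial.jump_time
    if alignment == "move_onset":
        return trial.move_onset_time
    raise ArgumentError(f"unknown alignment {alignment!r}")


def smooth_rates(session: Session, alignment: str = "target_on",
                 window: tuple = (0.0, 0.5), kernel_sd: float = 0.030,
                 step: float = 0.010) -> RateTensor:
    """Gaussian-kernel rate estimates on an event-aligned grid (spikes/s).

    Trials whose aligned window falls outside the recorded interval, or
    that lack the alignment event, are excluded and listed in
    ``excluded_trials``.
    """
    if step <= 0:
        raise ArgumentError("step must be positive")
    if kernel_sd <= 0:
        raise ArgumentError("kernel_sd must be positive")
    time = np.arange(window[0], window[1] + step / 2, step)
    peak = 1.0 / (kernel_sd * np.sqrt(2.0 * np.pi))

    cols, trial_ids, excluded = [], [], []
    for k, trial in enumerate(session.trials):
        ev = _event_time(trial, alignment)
        t0 = float(trial.hand_trajectory[0, 0])
        t1 = float(trial.hand_trajectory[-1, 0])
        if ev is None:
            excluded.append(trial.trial_id)
            continue
        grid = ev + time
        if grid[0] < t0 - 1e-9 or grid[-1] > t1 + 1e-9:
            excluded.append(trial.trial_id)
            continue
        spikes = [np.asarray(u.spike_times[k]) for u in session.units]
        ns = np.array([s.size for s in spikes])
        rates = np.zeros((len(spikes), time.size))
        if ns.sum():
            allsp = np.concatenate(spikes)
            contrib = peak * np.exp(
                -0.5 * ((grid[None, :] - allsp[:, None]) / kernel_sd) ** 2)
            bounds = np.concatenate([[0], np.cumsum(ns)])
            summed = np.add.reduceat(
                np.vstack([contrib, np.zeros((1, time.size))]),
                np.minimum(bounds[:-1], ns.sum()), axis=0)
            rates = summed[: len(spikes)]
            # reduceat quirk: empty slices repeat the row at the boundary
            rates[ns == 0] = 0.0
        mass = ndtr((t1 - grid) / kernel_sd) - ndtr((t0 - grid) / kernel_sd)
        rates = rates / np.maximum(mass, 1e-12)[None, :]
        cols.append(rates)
        trial_ids.append(trial.trial_id)

    if not cols:
        raise AlignmentError(
            f"no trial admits alignment {alignment!r} with window {window}")
    values = np.stack(cols, axis=2)
    return RateTensor(values=values, time=time, alignment=alignment,
                      unit_ids=[u.unit_id for u in session.units],
                      trial_ids=trial_ids, excluded_trials=excluded)


def unit_normalization(session: Session, kernel_sd: float = 0.030,
                       step: float = 0.010) -> np.ndarray:
    """Soft-normalization divisors: max(sd of rate over all trials, 1).

    The standard deviation is taken over each unit's rate concatenated
    across every trial's full recorded interval.
    """
    n = session.n_units
    tot_n = 0
    tot_s = np.zeros(n)
    tot_ss = np.zeros(n)
    for k, trial in enumerate(session.trials):
        t0 = float(trial.hand_trajectory[0, 0])
        t1 = float(trial.hand_trajectory[-1, 0])
        sub = Session(
            units=[Unit(u.unit_id, u.region, [u.spike_times[k]])
                   for u in session.units],
            trials=[trial], session_id=session.session_id)
        # evaluate on the trial's own full window, target_on-relative
        ev = trial.target_on_time
        n_steps = int(np.floor((t1 - t0) / step - 1e-9))
        rt = smooth_rates(sub, "target_on",
                          (t0 - ev, t0 - ev + n_steps * step), kernel_sd, step)
        vals = rt.values[:, :, 0]
        tot_n += vals.shape[1]
        tot_s += vals.sum(axis=1)
        tot_ss += (vals ** 2).sum(axis=1)
    mean = tot_s / tot_n
    var = np.maximum(tot_ss / tot_n - mean ** 2, 0.0)
    return np.maximum(np.sqrt(var), 1.0)


def normalize_rates(rates: RateTensor,
                    divisors: np.ndarray | None = None) -> RateTensor:
    """Divide each unit by max(s.d., 1); s.d. over all timepoints and trials."""
    if divisors is None:
        sd = rates.values.reshape(rates.values.shape[0], -1).std(axis=1)
        divisors = np.maximum(sd, 1.0)
    divisors = np.asarray(divisors, dtype=float)
    return replace(rates, values=rates.values / divisors[:, None, None],
                   normalization=divisors)


def detect_movement_onset(trial: Trial, speed_smooth: float = 0.010,
                          threshold: float = 0.05) -> float:
    """Movement onset: last time speed is below 5% of its max, tracing
    backward from the speed peak (linearly interpolated)."""
    traj = trial.hand_trajectory
    if traj.shape[0] < 5:
        raise DetectionError(f"trial {trial.trial_id}: too few hand samples")
    t = traj[:, 0]
    vx = np.gradient(traj[:, 1], t)
    vy = np.gradient(traj[:, 2], t)
    speed = np.hypot(vx, vy)
    dt = float(np.median(np.diff(t)))
    if speed_smooth > 0:
        speed = gaussian_filter1d(speed, speed_smooth / dt, mode="nearest")
    imax = int(np.argmax(speed))
    vmax = speed[imax]
    if vmax <= 0.5:  # cm/s; a stationary hand has no movement onset
        raise DetectionError(f"trial {trial.trial_id}: no movement detected")
    thresh = threshold * vmax
    below = np.nonzero(speed[: imax + 1] < thresh)[0]
    if below.size == 0:
        raise DetectionError(
            f"trial {trial.trial_id}: speed never below threshold before peak")
    j = int(below[-1])
    # interpolate the upward crossing between samples j and j+1
    if j + 1 <= imax and speed[j + 1] > speed[j]:
        frac = (thresh - speed[j]) / (speed[j + 1] - speed[j])
        return float(t[j] + frac * (t[j + 1] - t[j]))
    return float(t[j])


def align_and_average(rates: RateTensor, session: Session,
                      group_fn: Callable[[Trial], object]) -> ConditionAverage:
    """Average rates across trials per group key (``group_fn`` -> key/None).

    Jump conditions are conventionally grouped by ``(condition_id, label)``
    with the behavioral initial-direction label; see
    :func:`group_by_condition` and :func:`group_jump_by_label`.
    """
    by_trial = {t.trial_id: t for t in session.trials}
    sums: dict = {}
    counts: dict = {}
    for idx, tid in enumerate(rates.trial_ids):
        key = group_fn(by_trial[tid])
        if key is None:
            continue
        if key not in sums:
            sums[key] = np.zeros(rates.values.shape[:2])
            counts[key] = 0
        sums[key] += rates.values[:, :, idx]
        counts[key] += 1
    groups = {k: sums[k] / counts[k] for k in sums}
    return ConditionAverage(groups=groups, counts=counts, time=rates.time,
                            alignment=rates.alignment, unit_ids=rates.unit_ids)


def group_by_condition(trial: Trial):
    """Non-jump trials by condition id; jump trials excluded."""
    return None if trial.is_jump else trial.condition_id


def group_jump_by_label(labels: dict):
    """Jump trials keyed by (condition_id, initial-direction label)."""

    def fn(trial: Trial):
        if not trial.is_jump or trial.trial_id not in labels:
            return None
        return (trial.condition_id, labels[trial.trial_id])

    return fn
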