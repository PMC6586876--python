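"""Synthetic delayed-reach / target-jump sessions with exported ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes so that every estimator in the package can be scored against a
known answer:

* task timing — a 0–900 ms uniform delay between target onset and go cue,
  reaction times ~N(300, 50) ms, and on 20% of trials a target jump at a
  uniform time between the go cue and movement onset;
* latent dynamics — ``d_prep`` preparatory latents that ramp to a
  condition-specific pattern during the delay and decay after movement
  onset, ``d_move`` movement latents active during the reach, and one
  direction-independent trigger latent that crosses zero ``trigger_lead``
  seconds before movement onset (with logistic trial-to-trial jitter);
* the behavioral rule — a jump trial is initiated toward the *first*
  target exactly when the true trigger crossing precedes the jump.
  Because the crossing jitter is logistic with scale ``trigger_jitter``,
  the probability of reaching to the final target given the jump-to-onset
  latency L is exactly ``expit((L - trigger_lead)/trigger_jitter)``: the
  behavioral psychometric curve has a closed form with its 50% point at
  ``trigger_lead``;
* observation model — unit firing rates are a softplus link applied to a
  baseline plus an orthonormal mixture of the latents, and spikes are an
  inhomogeneous Poisson process (1 ms resolution).

By default the preparatory latents re-engage after a jump no matter how
late it occurs ("always prepare").  Setting ``direct_response=True``
suppresses preparatory re-engagement whenever the jump arrives after the
trigger crossing, so the pipeline's ability to discriminate the two
population-level hypotheses is itself testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.special import expit

from .errors import ArgumentError
from .session import Session, Trial, Unit, _det_dataset, _det_file

# 5% crossing point of the minimum-jerk speed profile, as a fraction of
# movement duration: solves 30 t^2 (1-t)^2 = 0.05 * 30/16.
_TAU5 = float((1.0 - np.sqrt(1.0 - 4.0 * np.sqrt(0.003125))) / 2.0)


def softplus(x):
    return np.logaddexp(0.0, x)


def inv_softplus(y):
    y = np.asarray(y, dtype=float)
    return y + np.log1p(-np.exp(-y))


def smoothstep(x):
    """C1 ramp: 0 for x<=0, 1 for x>=1, 3x^2-2x^3 between."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _minjerk(tau):
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic task, latent dynamics and observation model.

    Durations are seconds, positions centimetres, rates spikes/s.  ``snr``
    scales the latent-driven rate modulation relative to the Poisson noise
    floor of baseline firing.
    """

    n_units: int = 60
    n_conditions: int = 8
    jump_pairs: tuple = ((0, 4), (1, 5), (2, 6), (3, 7))
    n_trials: int = 1000
    p_jump: float = 0.2
    d_prep: int = 3
    d_move: int = 3
    trigger_lead: float = 0.150
    trigger_jitter: float = 0.010       # logistic scale of crossing jitter
    delay_range: tuple = (0.0, 0.9)
    rt_mean: float = 0.300
    rt_sd: float = 0.050
    rt_clip: tuple = (0.200, 0.450)
    snr: float = 2.0
    correction_latency: float = 0.100   # neural re-targeting latency
    kinematic_delay: float = 0.080      # extra motor delay for the hand
    angle_noise_deg: float = 8.0
    reach_distance: float = 10.0
    movement_duration: float = 0.400
    target_on_time: float = 0.25
    post_onset: float = 0.6
    baseline_range: tuple = (10.0, 20.0)
    prep_residual: float = 0.15         # prep envelope decays to this level
    pattern_amp_jitter: float = 0.2     # lognormal sd of per-condition tuning
    correction_gain: float = 1.5        # re-engagement amplitude vs delay
    direct_response: bool = False
    overshoot: bool = False             # optional anti-directional transient
    seed: int = 0
    latent_dt: float = 0.001
    kin_dt: float = 0.005

    # latent amplitude scales (population spikes/s per unit ``snr``)
    prep_amp_per_snr: float = 18.0
    move_amp_per_snr: float = 15.0
    trig_amp_per_snr: float = 15.0

    def __post_init__(self):
        if self.d_prep + self.d_move + 1 > self.n_units:
            raise ArgumentError("d_prep + d_move + 1 must not exceed n_units")
        if not 0.0 <= self.p_jump <= 1.0:
            raise ArgumentError("p_jump must be a probability")
        for name in ("trigger_lead", "trigger_jitter", "correction_latency",
                     "movement_duration", "rt_sd"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0")
        if self.delay_range[0] < 0 or self.delay_range[1] < self.delay_range[0]:
            raise ArgumentError("invalid delay_range")

    @property
    def a_prep(self):
        return self.prep_amp_per_snr * self.snr

    @property
    def a_move(self):
        return self.move_amp_per_snr * self.snr

    @property
    def a_trig(self):
        return self.trig_amp_per_snr * self.snr

    @property
    def behavior_t50_ms(self) -> float:
        """Closed-form 50% point of the behavioral transition (latency, ms)."""
        return self.trigger_lead * 1000.0

    def p_final(self, latency_s):
        """Closed-form P(initiated toward final target | jump-to-onset latency)."""
        return expit((np.asarray(latency_s, float) - self.trigger_lead)
                     / self.trigger_jitter)

    def target_angles_deg(self) -> np.ndarray:
        return np.arange(self.n_conditions) * 360.0 / self.n_conditions

    def target_xy(self, k: int) -> np.ndarray:
        th = np.radians(self.target_angles_deg()[k])
        return self.reach_distance * np.array([np.cos(th), np.sin(th)])

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        d["jump_pairs"] = [list(p) for p in self.jump_pairs]
        for k in ("delay_range", "rt_clip", "baseline_range"):
            d[k] = list(d[k])
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "GeneratorConfig":
        d = json.loads(s)
        d["jump_pairs"] = tuple(tuple(p) for p in d["jump_pairs"])
        for k in ("delay_range", "rt_clip", "baseline_range"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent bases, rate-model parameters and per-trial hidden variables."""

    B_prep: np.ndarray          # n_units x d_prep, orthonormal
    B_move: np.ndarray          # n_units x d_move, orthonormal
    b_trig: np.ndarray          # n_units, unit norm, orthogonal to both
    baseline: np.ndarray        # n_units baseline rates (spikes/s)
    prep_patterns: np.ndarray   # n_conditions x d_prep target patterns
    move_patterns: np.ndarray   # n_conditions x d_move target patterns
    trigger_crossing: dict = field(default_factory=dict)  # trial_id -> seconds
    initial_label: dict = field(default_factory=dict)     # trial_id -> first/final

    @property
    def mixing(self) -> np.ndarray:
        return np.column_stack([self.B_prep, self.B_move, self.b_trig[:, None]])

    def gram_residual(self) -> float:
        M = self.mixing
        return float(np.abs(M.T @ M - np.eye(M.shape[1])).max())


def _harmonics(angles_deg: np.ndarray, d: int, phase_deg: float = 0.0) -> np.ndarray:
    """(n_conditions x d) matrix of ring harmonics cos k0, sin k0, cos 2*0, ...

    Columns are orthogonal over an equally spaced ring and each has
    cross-condition variance 1/2, so a ``d``-dimensional pattern set spreads
    its variance evenly across dimensions.
    """
    th = np.radians(angles_deg + phase_deg)
    cols = []
    k = 1
    while len(cols) < d:
        cols.append(np.cos(k * th))
        if len(cols) < d:
            cols.append(np.sin(k * th))
        k += 1
    return np.column_stack(cols)


def make_ground_truth(config: GeneratorConfig,
                      rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw orthonormal latent bases and per-condition target patterns."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n, dp, dm = config.n_units, config.d_prep, config.d_move
    A = rng.standard_normal((n, dp + dm + 1))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    angles = config.target_angles_deg()

    def _patterns(d, amp, phase):
        H = _harmonics(angles, d, phase)
        scale = np.sqrt(np.mean(np.sum(H**2, axis=1)))
        # real tuning is not a perfect symmetric ring: per-condition
        # lognormal amplitude heterogeneity
        jit = np.exp(rng.normal(0.0, config.pattern_amp_jitter,
                                len(angles)))
        return amp * jit[:, None] * H / scale

    return GroundTruth(
        B_prep=Q[:, :dp],
        B_move=Q[:, dp:dp + dm],
        b_trig=Q[:, -1],
        baseline=rng.uniform(*config.baseline_range, size=n),
        prep_patterns=_patterns(dp, config.a_prep, 0.0),
        move_patterns=_patterns(dm, config.a_move, 22.5),
    )


# ---------------------------------------------------------------------------
# single-trial simulation
# ---------------------------------------------------------------------------

def simulate_trial(truth: GroundTruth, config: GeneratorConfig, is_jump: bool,
                   rng: np.random.Generator, first_idx: int,
                   final_idx: int | None = None):
    """Sample one trial's events, hidden variables and latent trajectory.

    Returns ``(events, latents, t_grid)`` where ``events`` is a dict with
    the sampled times, the true trigger crossing and the initial-direction
    label, and ``latents`` is a (T, d_prep + d_move + 1) array on the 1 ms
    grid ``t_grid``.
    """
    if is_jump and final_idx is None:
        raise ArgumentError("jump trial requires a final target index")
    if final_idx is None:
        final_idx = first_idx

    target_on = config.target_on_time
    delay = rng.uniform(*config.delay_range)
    go = target_on + delay
    rt = float(np.clip(rng.normal(config.rt_mean, config.rt_sd), *config.rt_clip))
    onset = go + rt
    t_cross = onset - config.trigger_lead + rng.logistic(0.0, config.trigger_jitter)
    if is_jump:
        jump = rng.uniform(go, onset)
        label = "first" if t_cross < jump else "final"
    else:
        jump = None
        label = "first"  # the cued (= final) target
    t_end = onset + config.post_onset

    t = np.arange(0.0, t_end + config.latent_dt / 2, config.latent_dt)
    dp, dm = config.d_prep, config.d_move
    z = np.zeros((t.size, dp + dm + 1))

    p_first = truth.prep_patterns[first_idx]
    p_final = truth.prep_patterns[final_idx]
    m_first = truth.move_patterns[first_idx]
    m_final = truth.move_patterns[final_idx]

    # preparatory latents: ramp to the cued pattern, optionally re-target
    # after the jump, and contract once the movement is triggered (the
    # trigger crossing, ~150 ms before onset, gates the decay; a late
    # re-targeting keeps the preparatory latents engaged into movement)
    if is_jump:
        t_corr = jump + config.correction_latency
        retarget = (not config.direct_response) or (t_corr <= t_cross)
    else:
        t_corr, retarget = None, False
    rise = smoothstep((t - (target_on + 0.05)) / 0.08)
    if retarget:
        c = smoothstep((t - t_corr) / 0.15)
        if config.overshoot:
            # brief anti-directional transient at correction onset
            c = c * (1.0 + 0.6 * np.exp(-((t - t_corr - 0.08) / 0.05) ** 2)) - \
                0.25 * np.exp(-((t - t_corr - 0.04) / 0.04) ** 2)
        decay_start = max(t_cross, t_corr + 0.15)
    else:
        c = np.zeros_like(t)
        decay_start = t_cross
    env_p = rise * (1.0 - (1.0 - config.prep_residual)
                    * smoothstep((t - decay_start) / 0.12))
    # the re-engaged pattern is disproportionate: corrections drive the
    # preparatory dimensions harder than ordinary delay-period preparation
    gain = config.correction_gain if retarget else 1.0
    z[:, :dp] = env_p[:, None] * ((1.0 - c)[:, None] * p_first
                                  + (gain * c)[:, None] * p_final)

    # movement latents: active from movement onset; the pattern blends to
    # the final target from the (neural) correction time on jump trials
    env_m = smoothstep((t - onset) / 0.08) * \
        (1.0 - smoothstep((t - (onset + 0.35)) / 0.15))
    if is_jump:
        g = smoothstep((t - t_corr) / 0.15)
    else:
        g = np.zeros_like(t)
    z[:, dp:dp + dm] = env_m[:, None] * \
        ((1.0 - g)[:, None] * m_first + g[:, None] * m_final)

    # trigger latent: direction-independent, crosses zero at t_cross
    z[:, -1] = config.a_trig * (2.0 * expit((t - t_cross) / 0.025) - 1.0)

    events = {
        "target_on_time": target_on, "go_cue_time": go, "move_onset_time": onset,
        "jump_time": jump, "trigger_crossing": t_cross, "initial_label": label,
        "t_end": t_end, "first_idx": first_idx, "final_idx": final_idx,
    }
    return events, z, t


def emit_spikes(latents: np.ndarray, t_grid: np.ndarray, truth: GroundTruth,
                config: GeneratorConfig, rng: np.random.Generator) -> list:
    """Poisson spikes from softplus rates; one sorted array per unit."""
    dt = float(t_grid[1] - t_grid[0])
    drive = truth.mixing @ latents.T              # n_units x T, spikes/s
    rates = softplus(inv_softplus(truth.baseline)[:, None] + drive)
    counts = rng.poisson(rates * dt)
    n = counts.shape[0]
    per_unit_tot = counts.sum(axis=1)
    bin_times = np.repeat(np.broadcast_to(t_grid, counts.shape).ravel(),
                          counts.ravel())
    jitter = rng.uniform(0.0, dt, size=bin_times.size)
    all_spikes = bin_times + jitter
    bounds = np.concatenate([[0], np.cumsum(per_unit_tot)])
    return [np.sort(all_spikes[bounds[i]:bounds[i + 1]]) for i in range(n)]


def simulate_kinematics(events: dict, label: str, first_xy: np.ndarray,
                        final_xy: np.ndarray, config: GeneratorConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Hand path: minimum-jerk reach with online correction on late jumps.

    Trials initiated toward the final target follow a direct minimum-jerk
    path; trials initiated toward the first target start along the first
    target's path and blend to the final target's path beginning
    ``correction_latency + kinematic_delay`` after the jump.  A small
    signed direction perturbation (s.d. ``angle_noise_deg``) decays with
    distance so that every reach ends on the final target.
    """
    onset = events["move_onset_time"]
    t_end = events["t_end"]
    T_mv = config.movement_duration
    t_start = onset - _TAU5 * T_mv
    t = np.arange(0.0, t_end + config.kin_dt / 2, config.kin_dt)
    s = _minjerk((t - t_start) / T_mv)

    A = s[:, None] * np.asarray(first_xy)[None, :]
    B = s[:, None] * np.asarray(final_xy)[None, :]
    if label == "first" and events["jump_time"] is not None:
        t_corr = events["jump_time"] + config.correction_latency + \
            config.kinematic_delay
        beta = smoothstep((t - t_corr) / 0.2)
    else:
        beta = np.ones_like(t)
    xy = (1.0 - beta)[:, None] * A + beta[:, None] * B

    eta0 = np.radians(rng.normal(0.0, config.angle_noise_deg))
    r = np.linalg.norm(xy, axis=1)
    ang = eta0 * (1.0 - np.minimum(r / config.reach_distance, 1.0))
    ca, sa = np.cos(ang), np.sin(ang)
    rotated = np.column_stack([ca * xy[:, 0] - sa * xy[:, 1],
                               sa * xy[:, 0] + ca * xy[:, 1]])
    return np.column_stack([t, rotated])


# ---------------------------------------------------------------------------
# session assembly
# ---------------------------------------------------------------------------

def generate_session(config: GeneratorConfig):
    """Full synthetic session plus its ground truth; deterministic per seed."""
    ss = np.random.SeedSequence([config.seed, 1])
    ev_rng, sp_rng, kin_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    truth = make_ground_truth(config)

    is_jump = ev_rng.random(config.n_trials) < config.p_jump
    nonjump_targets = ev_rng.integers(0, config.n_conditions, config.n_trials)
    pair_idx = ev_rng.integers(0, len(config.jump_pairs), config.n_trials)

    trials, spike_lists = [], [[] for _ in range(config.n_units)]
    for k in range(config.n_trials):
        if is_jump[k]:
            i, j = config.jump_pairs[pair_idx[k]]
            cond_id = f"J{i}-{j}"
        else:
            i = j = int(nonjump_targets[k])
            cond_id = f"T{i}"
        events, z, t_grid = simulate_trial(
            truth, config, bool(is_jump[k]), ev_rng, i,
            j if is_jump[k] else None)
        spikes = emit_spikes(z, t_grid, truth, config, sp_rng)
        first_xy = config.target_xy(i)
        final_xy = config.target_xy(j)
        traj = simulate_kinematics(
            events, events["initial_label"], first_xy, final_xy, config, kin_rng)
        trial_id = f"t{k:04d}"
        trials.append(Trial(
            trial_id=trial_id, condition_id=cond_id, is_jump=bool(is_jump[k]),
            target_on_time=events["target_on_time"],
            go_cue_time=events["go_cue_time"],
            jump_time=events["jump_time"],
            move_onset_time=events["move_onset_time"],
            first_target_xy=first_xy, final_target_xy=final_xy,
            hand_trajectory=traj,
        ))
        truth.trigger_crossing[trial_id] = events["trigger_crossing"]
        truth.initial_label[trial_id] = events["initial_label"]
        for u in range(config.n_units):
            spike_lists[u].append(spikes[u])

    units = [
        Unit(unit_id=f"u{u:03d}", region="M1" if u % 2 else "PMd",
             spike_times=spike_lists[u])
        for u in range(config.n_units)
    ]
    session = Session(units=units, trials=trials,
                      session_id=f"synth-{config.seed}")
    session.validate()
    return session, truth


def simulate_behavior_only(config: GeneratorConfig, n_per_condition: int,
                           seed: int) -> dict:
    """Sample jump-trial behavior from the trigger-vs-jump rule alone.

    No spikes or kinematics are produced; the observed normalized angle is
    the true label (+/-1) plus Gaussian noise scaled from
    ``angle_noise_deg`` onto the per-condition normalized-angle axis.
    Useful for behavioral statistics at large trial counts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    angles = config.target_angles_deg()
    out = {}
    for (i, j) in config.jump_pairs:
        arc = abs((angles[j] - angles[i] + 180.0) % 360.0 - 180.0)
        if arc == 0.0:
            arc = 180.0
        delay = rng.uniform(*config.delay_range, n_per_condition)
        rt = np.clip(rng.normal(config.rt_mean, config.rt_sd, n_per_condition),
                     *config.rt_clip)
        onset = config.target_on_time + delay + rt
        go = config.target_on_time + delay
        jump = rng.uniform(go, onset)
        t_cross = onset - config.trigger_lead + \
            rng.logistic(0.0, config.trigger_jitter, n_per_condition)
        label_first = t_cross < jump
        y = np.where(label_first, -1.0, 1.0)
        sigma_norm = 2.0 * config.angle_noise_deg * 0.9 / arc
        y_obs = y + rng.normal(0.0, sigma_norm, n_per_condition)
        out[f"J{i}-{j}"] = {
            "latency_ms": (onset - jump) * 1000.0,
            "offset_ms": (t_cross - jump) * 1000.0,
            "angle": y_obs,
            "label": np.where(label_first, "first", "final"),
        }
    return out


# ---------------------------------------------------------------------------
# ground-truth I/O (same deterministic container conventions as sessions)
# ---------------------------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> str:
    with _det_file(path) as f:
        for name in ("B_prep", "B_move", "b_trig", "baseline",
                     "prep_patterns", "move_patterns"):
            _det_dataset(f, name, getattr(truth, name))
        ids = sorted(truth.trigger_crossing)
        _det_dataset(f, "trial_id", np.array(ids, dtype="S64"))
        _det_dataset(f, "trigger_crossing",
                     [truth.trigger_crossing[i] for i in ids])
        _det_dataset(f, "initial_label",
                     np.array([truth.initial_label[i] for i in ids], dtype="S8"))
    return str(path)


def read_ground_truth(path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        truth = GroundTruth(
            B_prep=np.asarray(f["B_prep"]), B_move=np.asarray(f["B_move"]),
            b_trig=np.asarray(f["b_trig"]), baseline=np.asarray(f["baseline"]),
            prep_patterns=np.asarray(f["prep_patterns"]),
            move_patterns=np.asarray(f["move_patterns"]),
        )
        ids = [s.decode() for s in f["trial_id"][...]]
        cross = np.asarray(f["trigger_crossing"])
        labels = [s.decode() for s in f["initial_label"][...]]
        truth.trigger_crossing = dict(zip(ids, cross))
        truth.initial_label = dict(zip(ids, labels))
    return truth
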