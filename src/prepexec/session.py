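"""Session data model: units, trials, serialization and selection utilities.

A session is one day's simultaneously recorded dataset: a list of units
(each with one spike-time array per trial) and a list of trials (events,
target locations, the 2-D hand path).  All times are trial-relative seconds
with the target-onset time stored explicitly; hand and target coordinates
are centimetres with the origin at the central hold target.

Sessions round-trip losslessly through a single HDF5 bundle whose layout is

    /meta                      JSON string: session id, units table, conditions
    /spikes/<unit_id>/<k>      float64 spike times for trial k
    /trials/<field>            per-trial columns (ids, events, targets)
    /kinematics/<k>            (T, 3) float64 array: time, x, y

Bundles are written with HDF5 object timestamps disabled, so two writes of
the same session are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable

import h5py
import numpy as np
from h5py import h5f, h5g, h5p

from .errors import (
    ArgumentError,
    EmptySelectionError,
    SchemaError,
    SessionValidationError,
)

REGIONS = ("M1", "PMd", "unknown")


@dataclass
class Unit:
    """A single- or multi-unit with one spike array per trial (seconds)."""

    unit_id: str
    region: str = "unknown"
    spike_times: list = field(default_factory=list)

    def __eq__(self, other):
        if not isinstance(other, Unit):
            return NotImplemented
        return (
            self.unit_id == other.unit_id
            and self.region == other.region
            and len(self.spike_times) == len(other.spike_times)
            and all(
                np.array_equal(a, b)
                for a, b in zip(self.spike_times, other.spike_times)
            )
        )


@dataclass
class Trial:
    """One trial's events, targets and hand trajectory.

    ``jump_time`` and ``move_onset_time`` are ``None`` when absent;
    movement onset is computable from the trajectory
    (:func:`prepexec.preprocess.detect_movement_onset`).
    """

    trial_id: str
    condition_id: str
    is_jump: bool
    target_on_time: float
    go_cue_time: float
    first_target_xy: np.ndarray
    final_target_xy: np.ndarray
    hand_trajectory: np.ndarray  # (T, 3): time, x, y
    jump_time: float | None = None
    move_onset_time: float | None = None
    valid: bool = True

    def __post_init__(self):
        self.first_target_xy = np.asarray(self.first_target_xy, dtype=float)
        self.final_target_xy = np.asarray(self.final_target_xy, dtype=float)
        self.hand_trajectory = np.asarray(self.hand_trajectory, dtype=float)

    def __eq__(self, other):
        if not isinstance(other, Trial):
            return NotImplemented

        def _opt_eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return a == b

        return (
            self.trial_id == other.trial_id
            and self.condition_id == other.condition_id
            and self.is_jump == other.is_jump
            and self.target_on_time == other.target_on_time
            and self.go_cue_time == other.go_cue_time
            and _opt_eq(self.jump_time, other.jump_time)
            and _opt_eq(self.move_onset_time, other.move_onset_time)
            and self.valid == other.valid
            and np.array_equal(self.first_target_xy, other.first_target_xy)
            and np.array_equal(self.final_target_xy, other.final_target_xy)
            and np.array_equal(self.hand_trajectory, other.hand_trajectory)
        )


@dataclass(frozen=True)
class JumpCondition:
    """An ordered target pair: (A -> B) is a different condition from (B -> A)."""

    first_target_xy: tuple
    final_target_xy: tuple

    @property
    def jump_angle(self) -> float:
        """Unsigned angular separation between the two target directions, degrees."""
        a1 = np.degrees(np.arctan2(*self.first_target_xy[::-1]))
        a2 = np.degrees(np.arctan2(*self.final_target_xy[::-1]))
        d = abs((a2 - a1 + 180.0) % 360.0 - 180.0)
        return float(d)


@dataclass
class Session:
    units: list
    trials: list
    session_id: str = "session"
    bin_width: float = 0.010
    kernel_sd: float = 0.030

    # ------------------------------------------------------------------ basic
    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def condition_ids(self) -> list:
        seen: dict = {}
        for t in self.trials:
            seen.setdefault(t.condition_id, None)
        return list(seen)

    def jump_conditions(self) -> dict:
        """Map jump condition_id -> :class:`JumpCondition` (ordered pairs)."""
        out: dict = {}
        for t in self.trials:
            if t.is_jump and t.condition_id not in out:
                out[t.condition_id] = JumpCondition(
                    tuple(t.first_target_xy), tuple(t.final_target_xy)
                )
        return out

    def __eq__(self, other):
        if not isinstance(other, Session):
            return NotImplemented
        return (
            self.session_id == other.session_id
            and self.bin_width == other.bin_width
            and self.kernel_sd == other.kernel_sd
            and self.units == other.units
            and self.trials == other.trials
        )

    # ------------------------------------------------------------- validation
    def validate(self) -> list:
        """Check all structural invariants.

        Raises :class:`SessionValidationError` on hard violations.  Jump
        trials whose jump occurs at/after the recorded movement onset are
        not errors: they indicate an onset-detection failure, so they are
        flagged ``valid=False`` and their ids are returned.
        """
        flagged = []
        n_trials = len(self.trials)
        if n_trials == 0:
            raise SessionValidationError("session has no trials")
        for u in self.units:
            if len(u.spike_times) != n_trials:
                raise SessionValidationError(
                    f"unit {u.unit_id}: {len(u.spike_times)} spike arrays "
                    f"for {n_trials} trials"
                )
            if u.region not in REGIONS:
                raise SessionValidationError(
                    f"unit {u.unit_id}: unknown region {u.region!r}"
                )
            for k, st in enumerate(u.spike_times):
                st = np.asarray(st)
                if st.size and np.any(np.diff(st) < 0):
                    raise SessionValidationError(
                        f"unit {u.unit_id}, trial {k}: spike times not sorted"
                    )
        cond_pairs: dict = {}
        for t in self.trials:
            if not t.target_on_time < t.go_cue_time:
                raise SessionValidationError(
                    f"trial {t.trial_id}: target_on_time must precede go_cue_time"
                )
            traj_t = t.hand_trajectory[:, 0]
            if traj_t.size and np.any(np.diff(traj_t) <= 0):
                raise SessionValidationError(
                    f"trial {t.trial_id}: hand samples not time-ordered"
                )
            if t.is_jump:
                if t.jump_time is None:
                    raise SessionValidationError(
                        f"trial {t.trial_id}: jump trial without jump_time"
                    )
                if t.jump_time < t.go_cue_time:
                    raise SessionValidationError(
                        f"trial {t.trial_id}: jump_time precedes go_cue_time"
                    )
                if np.array_equal(t.first_target_xy, t.final_target_xy):
                    raise SessionValidationError(
                        f"trial {t.trial_id}: jump trial with equal targets"
                    )
                if t.move_onset_time is not None and t.jump_time >= t.move_onset_time:
                    t.valid = False
                    flagged.append(t.trial_id)
            else:
                if t.jump_time is not None:
                    raise SessionValidationError(
                        f"trial {t.trial_id}: non-jump trial with jump_time"
                    )
            # a condition id must always name the same ordered target pair
            key = (
                tuple(np.round(t.first_target_xy, 9)),
                tuple(np.round(t.final_target_xy, 9)),
            )
            prev = cond_pairs.setdefault(t.condition_id, key)
            if prev != key:
                raise SessionValidationError(
                    f"condition {t.condition_id}: inconsistent target pairs"
                )
        return flagged


# ---------------------------------------------------------------------------
# deterministic HDF5 plumbing
# ---------------------------------------------------------------------------

def _det_file(path: str) -> h5py.File:
    fcpl = h5p.create(h5p.FILE_CREATE)
    fcpl.set_obj_track_times(False)
    fid = h5f.create(str(path).encode(), h5f.ACC_TRUNC, fcpl=fcpl)
    return h5py.File(fid)


def _det_group(parent, name: str) -> h5py.Group:
    gcpl = h5p.create(h5p.GROUP_CREATE)
    gcpl.set_obj_track_times(False)
    gid = h5g.create(parent.id, name.encode(), gcpl=gcpl)
    return h5py.Group(gid)


def _det_dataset(group, name: str, data) -> None:
    group.create_dataset(name, data=np.asarray(data), track_times=False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_session(session: Session, path) -> str:
    """Write a session bundle; ``read_session(write_session(s)) == s``."""
    if session.n_trials == 0:
        raise ArgumentError("cannot write a session with no trials")
    session.validate()
    meta = {
        "session_id": session.session_id,
        "bin_width": session.bin_width,
        "kernel_sd": session.kernel_sd,
        "units": [
            {"unit_id": u.unit_id, "region": u.region} for u in session.units
        ],
        "conditions": session.condition_ids(),
    }
    try:
        f = _det_file(path)
    except OSError as e:  # pragma: no cover - depends on filesystem
        raise OSError(f"cannot write session bundle at {path}: {e}") from e
    with f:
        _det_dataset(
            f, "meta",
            np.frombuffer(
                json.dumps(meta, sort_keys=True, separators=(",", ":")).encode(),
                dtype=np.uint8,
            ),
        )
        spikes = _det_group(f, "spikes")
        for u in session.units:
            g = _det_group(spikes, u.unit_id)
            for k, st in enumerate(u.spike_times):
                _det_dataset(g, str(k), np.asarray(st, dtype=np.float64))
        trials = _det_group(f, "trials")
        nan = np.nan
        _det_dataset(trials, "trial_id",
                     np.array([t.trial_id for t in session.trials], dtype="S64"))
        _det_dataset(trials, "condition_id",
                     np.array([t.condition_id for t in session.trials], dtype="S64"))
        _det_dataset(trials, "is_jump",
                     np.array([t.is_jump for t in session.trials], dtype=np.uint8))
        _det_dataset(trials, "valid",
                     np.array([t.valid for t in session.trials], dtype=np.uint8))
        _det_dataset(trials, "target_on_time",
                     [t.target_on_time for t in session.trials])
        _det_dataset(trials, "go_cue_time",
                     [t.go_cue_time for t in session.trials])
        _det_dataset(trials, "jump_time",
                     [nan if t.jump_time is None else t.jump_time
                      for t in session.trials])
        _det_dataset(trials, "move_onset_time",
                     [nan if t.move_onset_time is None else t.move_onset_time
                      for t in session.trials])
        _det_dataset(trials, "first_target_xy",
                     np.array([t.first_target_xy for t in session.trials]))
        _det_dataset(trials, "final_target_xy",
                     np.array([t.final_target_xy for t in session.trials]))
        kin = _det_group(f, "kinematics")
        for k, t in enumerate(session.trials):
            _det_dataset(kin, str(k), t.hand_trajectory)
    return str(path)


def read_session(path) -> Session:
    """Read a session bundle written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        for key in ("meta", "spikes", "trials", "kinematics"):
            if key not in f:
                raise SchemaError(f"session bundle missing required group '{key}'")
        meta = json.loads(bytes(f["meta"][...]).decode())
        for key in ("session_id", "units", "bin_width", "kernel_sd"):
            if key not in meta:
                raise SchemaError(f"session metadata missing field '{key}'")
        tg = f["trials"]
        for key in ("trial_id", "condition_id", "is_jump", "target_on_time",
                    "go_cue_time", "jump_time", "move_onset_time",
                    "first_target_xy", "final_target_xy", "valid"):
            if key not in tg:
                raise SchemaError(f"trials table missing column '{key}'")
        n = len(tg["trial_id"])
        trials = []
        jt = np.asarray(tg["jump_time"])
        mo = np.asarray(tg["move_onset_time"])
        for k in range(n):
            trials.append(Trial(
                trial_id=tg["trial_id"][k].decode(),
                condition_id=tg["condition_id"][k].decode(),
                is_jump=bool(tg["is_jump"][k]),
                valid=bool(tg["valid"][k]),
                target_on_time=float(tg["target_on_time"][k]),
                go_cue_time=float(tg["go_cue_time"][k]),
                jump_time=None if np.isnan(jt[k]) else float(jt[k]),
                move_onset_time=None if np.isnan(mo[k]) else float(mo[k]),
                first_target_xy=np.asarray(tg["first_target_xy"][k]),
                final_target_xy=np.asarray(tg["final_target_xy"][k]),
                hand_trajectory=np.asarray(f["kinematics"][str(k)]),
            ))
        units = []
        for um in meta["units"]:
            uid = um["unit_id"]
            if uid not in f["spikes"]:
                raise SchemaError(f"spike group missing unit '{uid}'")
            g = f["spikes"][uid]
            spikes = [np.asarray(g[str(k)], dtype=np.float64) for k in range(n)]
            units.append(Unit(unit_id=uid, region=um["region"], spike_times=spikes))
        session = Session(
            units=units,
            trials=trials,
            session_id=meta["session_id"],
            bin_width=float(meta["bin_width"]),
            kernel_sd=float(meta["kernel_sd"]),
        )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def subsample_units(session: Session, n_keep: int, seed: int) -> Session:
    """Uniformly subsample ``n_keep`` units (trials untouched), seeded."""
    if not 1 <= n_keep <= session.n_units:
        raise ArgumentError(
            f"n_keep must be in [1, {session.n_units}], got {n_keep}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(session.n_units, size=n_keep, replace=False))
    return replace(session, units=[session.units[i] for i in idx],
                   trials=session.trials)


def select_trials(session: Session, predicate: Callable[[Trial], bool]) -> Session:
    """Filter trials by a predicate, preserving unit/trial correspondence."""
    keep = [k for k, t in enumerate(session.trials) if predicate(t)]
    if not keep:
        raise EmptySelectionError("predicate removed all trials")
    units = [
        Unit(u.unit_id, u.region, [u.spike_times[k] for k in keep])
        for u in session.units
    ]
    return replace(session, units=units,
                   trials=[session.trials[k] for k in keep])
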