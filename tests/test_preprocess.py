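import copy

import numpy as np
import pytest

from prepexec.errors import ArgumentError, DetectionError
from prepexec.preprocess import (
    RateTensor,
    align_and_average,
    detect_movement_onset,
    group_by_condition,
    normalize_rates,
    smooth_rates,
    unit_normalization,
)
from prepexec.session import Session, Trial, Unit
from prepexec.synth import GeneratorConfig, simulate_kinematics


def _session_with_spikes(spike_lists, t_end=2.0):
    t = np.arange(0.0, t_end + 1e-9, 0.01)
    traj = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
    trials = [Trial(trial_id=f"t{k}", condition_id="T0", is_jump=False,
                    target_on_time=0.25, go_cue_time=0.5,
                    first_target_xy=np.array([10.0, 0.0]),
                    final_target_xy=np.array([10.0, 0.0]),
                    hand_trajectory=traj)
              for k in range(len(spike_lists[0]))]
    units = [Unit(f"u{i}", "PMd", [np.asarray(s, float) for s in sl])
             for i, sl in enumerate(spike_lists)]
    return Session(units=units, trials=trials)


class TestSmoothRates:
    def test_single_spike_peak_matches_gaussian_density(self):
        s = _session_with_spikes([[[1.0]]])
        rt = smooth_rates(s, "target_on", (-0.25, 1.5), kernel_sd=0.030,
                          step=0.010)
        # grid point at absolute t = 1.0 (0.75 after target onset)
        i = np.argmin(np.abs(rt.time - 0.75))
        expected = 1.0 / (0.030 * np.sqrt(2 * np.pi))  # ~13.298 spikes/s
        assert rt.values[0, i, 0] == pytest.approx(expected, rel=1e-6)

    def test_no_spikes_gives_zero_rate(self):
        s = _session_with_spikes([[[]]])
        rt = smooth_rates(s, "target_on", (0.0, 1.0))
        assert np.all(rt.values == 0)

    def test_homogeneous_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        means = []
        for _ in range(30):
            n = rng.poisson(100 * 5.0)
            spikes = np.sort(rng.uniform(0.0, 5.0, n))
            s = _session_with_spikes([[spikes]], t_end=5.0)
            rt = smooth_rates(s, "target_on", (0.0, 4.5))
            means.append(rt.values[0, :, 0].mean())
        assert np.mean(means) == pytest.approx(100.0, abs=5.0)

    def test_smoothing_conserves_spike_mass(self, rng):
        spikes = np.sort(rng.uniform(0.5, 1.5, 40))
        s = _session_with_spikes([[spikes]], t_end=2.0)
        rt = smooth_rates(s, "target_on", (-0.25, 1.75), step=0.005)
        integral = np.trapezoid(rt.values[0, :, 0], rt.time)
        assert integral == pytest.approx(len(spikes), rel=1e-3)

    def test_bad_step_rejected(self):
        s = _session_with_spikes([[[1.0]]])
        with pytest.raises(ArgumentError):
            smooth_rates(s, "target_on", (0, 1), step=0.0)

    def test_alignment_shift_equivariance(self, small_session):
        """Shifting every event, spike and sample by a constant leaves
        event-aligned tensors unchanged."""
        session, _ = small_session
        delta = 0.35
        shifted = copy.deepcopy(session)
        for t in shifted.trials:
            t.target_on_time += delta
            t.go_cue_time += delta
            if t.jump_time is not None:
                t.jump_time += delta
            if t.move_onset_time is not None:
                t.move_onset_time += delta
            t.hand_trajectory = t.hand_trajectory.copy()
            t.hand_trajectory[:, 0] += delta
        for u in shifted.units:
            u.spike_times = [s + delta for s in u.spike_times]
        a = smooth_rates(session, "go_cue", (0.0, 0.4))
        b = smooth_rates(shifted, "go_cue", (0.0, 0.4))
        assert np.allclose(a.values, b.values, atol=1e-9)


class TestNormalization:
    def _tensor(self, values):
        v = np.asarray(values, float)
        return RateTensor(values=v, time=np.arange(v.shape[1]) * 0.01,
                          alignment="target_on",
                          unit_ids=[f"u{i}" for i in range(v.shape[0])],
                          trial_ids=[f"t{k}" for k in range(v.shape[2])])

    def test_sd_two_halves_values(self, rng):
        x = rng.normal(0.0, 2.0, (1, 2000, 1))
        x = (x - x.mean()) / x.std() * 2.0
        rt = normalize_rates(self._tensor(x))
        assert rt.normalization[0] == pytest.approx(2.0)
        assert np.allclose(rt.values, x / 2.0)

    def test_small_sd_uses_floor(self, rng):
        x = rng.normal(0.0, 0.5, (1, 2000, 1))
        rt = normalize_rates(self._tensor(x))
        assert rt.normalization[0] == 1.0
        assert np.allclose(rt.values, x)

    def test_all_zero_unit_unchanged(self):
        rt = normalize_rates(self._tensor(np.zeros((1, 50, 2))))
        assert np.all(rt.values == 0)
        assert rt.normalization[0] == 1.0

    def test_idempotence(self, rng):
        x = rng.normal(0.0, 3.0, (4, 200, 3))
        once = normalize_rates(self._tensor(x))
        twice = normalize_rates(self._tensor(once.values))
        assert np.allclose(once.values, twice.values)

    def test_session_level_divisors_floor(self, small_session):
        session, _ = small_session
        div = unit_normalization(session)
        assert np.all(div >= 1.0)


class TestMovementOnset:
    def _minjerk_trial(self, onset=0.8, scale=1.0):
        cfg = GeneratorConfig(seed=0, angle_noise_deg=0.0)
        events = {"move_onset_time": onset, "jump_time": None, "t_end": 1.6}
        traj = simulate_kinematics(events, "final", np.array([10.0, 0.0]),
                                   np.array([10.0, 0.0]), cfg,
                                   np.random.default_rng(0))
        traj = traj.copy()
        traj[:, 1:] *= scale
        return Trial(trial_id="t", condition_id="T0", is_jump=False,
                     target_on_time=0.2, go_cue_time=0.5,
                     first_target_xy=np.array([10.0, 0.0]),
                     final_target_xy=np.array([10.0, 0.0]),
                     hand_trajectory=traj), onset

    def test_detects_constructed_onset(self):
        trial, onset = self._minjerk_trial()
        assert detect_movement_onset(trial) == pytest.approx(onset, abs=0.005)

    def test_threshold_is_scale_invariant(self):
        t1, _ = self._minjerk_trial(scale=1.0)
        t2, _ = self._minjerk_trial(scale=2.0)
        assert detect_movement_onset(t1) == pytest.approx(
            detect_movement_onset(t2), abs=1e-9)

    def test_stationary_hand_raises(self):
        t = np.arange(0, 1.0, 0.005)
        traj = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        trial = Trial(trial_id="t", condition_id="T0", is_jump=False,
                      target_on_time=0.2, go_cue_time=0.5,
                      first_target_xy=np.array([10.0, 0.0]),
                      final_target_xy=np.array([10.0, 0.0]),
                      hand_trajectory=traj)
        with pytest.raises(DetectionError):
            detect_movement_onset(trial)

    def test_generator_onsets_recovered(self, small_session):
        session, _ = small_session
        errs = [abs(detect_movement_onset(t) - t.move_onset_time)
                for t in session.trials if not t.is_jump]
        assert np.median(errs) < 0.005
        assert np.max(errs) < 0.015


class TestAlignAndAverage:
    def _rate_tensor(self, values):
        v = np.asarray(values, float)
        return RateTensor(values=v, time=np.arange(v.shape[1]) * 0.01,
                          alignment="target_on", unit_ids=["u0"],
                          trial_ids=[f"t{k}" for k in range(v.shape[2])])

    def _two_trial_session(self):
        t = np.arange(0.0, 1.0, 0.01)
        traj = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        trials = [Trial(trial_id=f"t{k}", condition_id="T0", is_jump=False,
                        target_on_time=0.2, go_cue_time=0.5,
                        first_target_xy=np.array([10.0, 0.0]),
                        final_target_xy=np.array([10.0, 0.0]),
                        hand_trajectory=traj) for k in range(2)]
        units = [Unit("u0", "PMd", [np.array([]), np.array([])])]
        return Session(units=units, trials=trials)

    def test_identical_trials_average_to_one_trial(self, rng):
        x = rng.normal(size=(1, 30))
        v = np.stack([x[0], x[0]], axis=-1)[None, :, :]
        rt = self._rate_tensor(v)
        avg = align_and_average(rt, self._two_trial_session(),
                                group_by_condition)
        assert np.allclose(avg.groups["T0"][0], x[0])

    def test_linearity_of_average(self, rng):
        r = rng.normal(size=30)
        c = 1.7
        v = np.stack([r, -r + 2 * c], axis=-1)[None, :, :]
        rt = self._rate_tensor(v)
        avg = align_and_average(rt, self._two_trial_session(),
                                group_by_condition)
        assert np.allclose(avg.groups["T0"][0], c)
        assert avg.counts["T0"] == 2
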