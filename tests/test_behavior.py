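import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import kstest

from prepexec.behavior import (
    SigmoidFit,
    anova_crossing_times,
    filter_fits_by_ci,
    fit_behavior_sigmoid,
    fit_sigmoid_params,
    initial_reach_angle,
    normalize_angle,
    reach_probability_curve,
)
from prepexec.errors import BehaviorError, FitError, StatisticsError
from prepexec.session import JumpCondition, Trial
from prepexec.synth import GeneratorConfig, simulate_behavior_only


def _trial_with_path(xy):
    xy = np.asarray(xy, float)
    t = np.arange(len(xy)) * 0.01
    return Trial(trial_id="t", condition_id="J", is_jump=True,
                 target_on_time=0.0, go_cue_time=0.01, jump_time=0.02,
                 first_target_xy=np.array([10.0, 0.0]),
                 final_target_xy=np.array([-10.0, 0.0]),
                 hand_trajectory=np.column_stack([t, xy]))


class TestInitialAngle:
    def test_straight_paths(self):
        path = np.linspace([0, 0], [10, 0], 50)
        assert initial_reach_angle(_trial_with_path(path)) == pytest.approx(0.0)
        path = np.linspace([0, 0], [0, 10], 50)
        assert initial_reach_angle(_trial_with_path(path)) == pytest.approx(90.0)

    def test_interpolates_the_radius_crossing(self):
        # samples straddle r=1 at 0.8 and 1.2 cm along a 45 degree ray
        path = np.array([[0, 0], [0.8 / np.sqrt(2)] * 2, [1.2 / np.sqrt(2)] * 2,
                         [3.0, 3.0]])
        assert initial_reach_angle(_trial_with_path(path)) == \
            pytest.approx(45.0, abs=1e-6)

    def test_short_path_raises(self):
        path = np.linspace([0, 0], [0.5, 0], 20)
        with pytest.raises(BehaviorError):
            initial_reach_angle(_trial_with_path(path))


def _cond(first_deg, final_deg):
    return JumpCondition(
        (10 * np.cos(np.radians(first_deg)), 10 * np.sin(np.radians(first_deg))),
        (10 * np.cos(np.radians(final_deg)), 10 * np.sin(np.radians(final_deg))))


def _normalize_angle_reference(angle, first_deg, final_deg):
    """Independent formulation: rotate so the first target sits at zero,
    unwrap the reach into the half-circle band around the arc, and take
    the signed fraction along the arc."""
    delta = (final_deg - first_deg + 180.0) % 360.0 - 180.0
    if delta == -180.0:
        delta = 180.0
    r = (angle - first_deg) % 360.0
    if r > 180.0:
        r -= 360.0
    mid = delta / 2.0
    # move r into (mid - 180, mid + 180]
    if r <= mid - 180.0:
        r += 360.0
    elif r > mid + 180.0:
        r -= 360.0
    return 2.0 * r / delta - 1.0


class TestNormalizeAngle:
    def test_endpoints_and_midpoint(self):
        c = _cond(0.0, 90.0)
        assert normalize_angle(0.0, c) == pytest.approx(-1.0)
        assert normalize_angle(90.0, c) == pytest.approx(1.0)
        assert normalize_angle(45.0, c) == pytest.approx(0.0)

    def test_against_independent_formula(self):
        for first, final, reach in [(0, 180, 45), (0, 180, -45), (30, 75, 90),
                                    (170, -170, 175), (90, -45, 0)]:
            c = _cond(first, final)
            assert normalize_angle(reach, c) == pytest.approx(
                _normalize_angle_reference(reach, first, final), abs=1e-9)

    def test_degenerate_condition_raises(self):
        with pytest.raises(BehaviorError):
            normalize_angle(10.0, _cond(30.0, 30.0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(first=st.floats(-180, 180), sep=st.floats(20, 180),
           reach=st.floats(-180, 180), rot=st.floats(-180, 180))
    def test_global_rotation_invariance(self, first, sep, reach, rot):
        c1 = _cond(first, first + sep)
        c2 = _cond(first + rot, first + sep + rot)
        a = normalize_angle(reach, c1)
        b = normalize_angle(reach + rot, c2)
        assert a == pytest.approx(b, abs=1e-6)


class TestSigmoidFit:
    def test_recovers_noiseless_logistic(self, rng):
        t = np.linspace(0, 300, 60)
        y = -1 + 2 * expit((t - 100.0) / 12.0)
        fit = fit_behavior_sigmoid(t, y, n_bootstrap=0)
        assert fit.t50 == pytest.approx(100.0, abs=1.0)
        assert fit.crossings[0.5] == pytest.approx(fit.t50, abs=1e-6)
        assert fit.goodness > 0.999

    def test_crossings_increase_with_fraction(self, rng):
        data = simulate_behavior_only(GeneratorConfig(seed=2), 150, 2)["J0-4"]
        fit = fit_behavior_sigmoid(data["latency_ms"], data["angle"],
                                   n_bootstrap=0)
        assert fit.crossings[0.05] < fit.crossings[0.5] < fit.crossings[0.95]

    def test_no_transition_raises(self):
        t = np.linspace(0, 300, 30)
        with pytest.raises(FitError):
            fit_sigmoid_params(t, np.full(30, 0.98))

    def test_too_few_trials_raises(self):
        with pytest.raises(FitError):
            fit_sigmoid_params(np.arange(5.0), np.array([-1, -1, 0.1, 1, 1.0]))


class TestCiFilter:
    def _fit(self, ci):
        return SigmoidFit(lower=-1, upper=1, t50=150, slope=10,
                          crossings={}, ci50=ci, n_trials=50, goodness=0.9)

    def test_strict_boundary(self):
        fits = {"a": self._fit(49.0), "b": self._fit(50.0),
                "c": self._fit(None)}
        kept, dropped = filter_fits_by_ci(fits, max_ci_ms=50.0)
        assert set(kept) == {"a"}
        assert set(dropped) == {"b", "c"}


class TestAnova:
    def test_identical_everywhere(self):
        F, p, dfb, dfw, ns = anova_crossing_times(
            {45: [5.0, 5.0], 180: [5.0, 5.0]})
        assert F == 0.0 and p == 1.0

    def test_perfect_separation(self):
        F, p, *_ = anova_crossing_times({45: [0.0, 0.0], 180: [1.0, 1.0]})
        assert p < 1e-12

    def test_small_group_raises(self):
        with pytest.raises(StatisticsError):
            anova_crossing_times({45: [1.0], 180: [1.0, 2.0]})

    def test_null_calibration_p_uniform(self):
        """With jump-angle-independent true crossing times, ANOVA p-values
        are uniform across seeded runs."""
        cfg = GeneratorConfig(
            seed=0, jump_pairs=((0, 4), (1, 5), (2, 6), (0, 2), (4, 6), (3, 5)))
        pvals = []
        for seed in range(250):
            data = simulate_behavior_only(cfg, 60, seed)
            groups = {}
            for (i, j), (cid, d) in zip(cfg.jump_pairs, data.items()):
                try:
                    params, _ = fit_sigmoid_params(d["latency_ms"], d["angle"],
                                                   n_starts=2)
                except FitError:
                    continue
                ang = abs((cfg.target_angles_deg()[j]
                           - cfg.target_angles_deg()[i] + 180) % 360 - 180)
                groups.setdefault(ang, []).append(params[2])
            if all(len(v) >= 2 for v in groups.values()) and len(groups) >= 2:
                pvals.append(anova_crossing_times(groups)[1])
        assert len(pvals) >= 200
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestReachProbabilityCurve:
    def test_all_final_is_one(self):
        t = np.linspace(0, 300, 50)
        _, p, lo, hi, _ = reach_probability_curve(t, ["final"] * 50)
        assert np.all(p == 1.0) and np.all(hi == 1.0)

    def test_shuffled_labels_flat(self, rng):
        data = simulate_behavior_only(GeneratorConfig(seed=4), 2000, 4)["J0-4"]
        labels = rng.permutation(data["label"])
        _, p, *_ , ns = reach_probability_curve(data["latency_ms"], labels,
                                                bin_width_ms=30.0)
        overall = np.mean(labels == "final")
        band = 4 * np.sqrt(overall * (1 - overall) / ns)
        assert np.all(np.abs(p - overall) < band)

    def test_monotone_at_large_n(self):
        data = simulate_behavior_only(GeneratorConfig(seed=9), 1000, 9)["J0-4"]
        _, p, *_ = reach_probability_curve(data["latency_ms"], data["label"],
                                           bin_width_ms=25.0)
        assert np.all(np.diff(p) > -0.05)
        assert p[0] < 0.1 and p[-1] > 0.9
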