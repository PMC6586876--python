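import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prepexec.errors import ArgumentError, DimensionError
from prepexec.subspace import (
    EpochData,
    choose_dims,
    cross_condition_variance,
    optimize_subspaces,
    project_average,
    project_trigger_null,
)
from prepexec.preprocess import ConditionAverage
from prepexec.recovery import principal_angles_deg

from _oracles import random_psd, two_frame_grid_oracle


def _epoch_data(Cp, Cm):
    n = Cp.shape[0]
    return EpochData(
        X_prep=np.zeros((n, 1)), X_move=np.zeros((n, 1)),
        C_prep=Cp, C_move=Cm,
        sv_prep=np.sort(np.linalg.eigvalsh(Cp))[::-1],
        sv_move=np.sort(np.linalg.eigvalsh(Cm))[::-1],
        null_basis=np.eye(n + 1, n), trigger_w=np.zeros(n + 1))


class TestChooseDims:
    def _matrix_with_variances(self, variances, m=64):
        """Rows span orthogonal mean-zero patterns with given variances."""
        k = len(variances)
        rng = np.random.default_rng(0)
        V = np.linalg.qr(rng.standard_normal((m, m)))[0][:, :k]
        V -= V.mean(axis=0, keepdims=True)
        V = np.linalg.qr(V)[0]
        return (np.sqrt(np.asarray(variances) * m)[:, None] * V.T)

    def test_two_equal_components_need_two_dims(self):
        X = self._matrix_with_variances([1.0, 1.0])
        assert choose_dims(X, 0.70) == 2

    def test_one_dimensional_data(self):
        X = self._matrix_with_variances([2.0])
        assert choose_dims(X, 0.70) == 1

    def test_tie_at_threshold_resolves_upward(self):
        X = self._matrix_with_variances([7.0, 3.0])
        assert choose_dims(X, 0.70) == 2  # 'over 70%' is strict

    def test_zero_variance_raises(self):
        with pytest.raises(DimensionError):
            choose_dims(np.zeros((4, 10)))


class TestTriggerNull:
    def test_data_along_w_vanishes(self, rng):
        w = rng.standard_normal(8)
        w /= np.linalg.norm(w)
        X = np.outer(w, rng.standard_normal(20))
        Xn, K = project_trigger_null(X, w)
        assert np.abs(Xn).max() < 1e-10
        assert K.shape == (8, 7)

    def test_orthogonal_data_isometric(self, rng):
        w = np.zeros(6)
        w[0] = 1.0
        X = rng.standard_normal((6, 15))
        X[0] = 0.0
        Xn, _ = project_trigger_null(X, w)
        assert np.allclose(np.linalg.norm(Xn, axis=0),
                           np.linalg.norm(X, axis=0), atol=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ArgumentError):
            project_trigger_null(np.ones((3, 2)), np.zeros(3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 20))
    def test_pythagoras(self, seed, n):
        rng = np.random.default_rng(seed)
        w = rng.standard_normal(n)
        w /= np.linalg.norm(w)
        x = rng.standard_normal((n, 5))
        xn, _ = project_trigger_null(x, w)
        lhs = np.sum(x ** 2, axis=0)
        rhs = np.sum(xn ** 2, axis=0) + (w @ x) ** 2
        assert np.allclose(lhs, rhs, atol=1e-10)


class TestOptimizeSubspaces:
    def test_block_disjoint_attains_unit_objective(self):
        n = 8
        Cp = np.zeros((n, n))
        Cp[:3, :3] = random_psd(np.random.default_rng(0), 3) + np.eye(3)
        Cm = np.zeros((n, n))
        Cm[4:7, 4:7] = random_psd(np.random.default_rng(1), 3) + np.eye(3)
        pair = optimize_subspaces(_epoch_data(Cp, Cm), 3, 3, seed=0)
        assert pair.objective == pytest.approx(1.0, abs=1e-8)
        # bases span the respective top eigenspaces (coordinate blocks)
        assert np.abs(pair.Q_prep[3:]).max() < 1e-6
        assert np.abs(pair.Q_move[:4]).max() < 1e-6

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        A, B = random_psd(rng, 4), random_psd(rng, 4)
        ep = _epoch_data(A, B)
        pair = optimize_subspaces(ep, 1, 1, seed=0)
        oracle = two_frame_grid_oracle(A, B, ep.sv_prep[0], ep.sv_move[0])
        assert pair.objective == pytest.approx(oracle, abs=1e-3)

    def test_monotone_ascent(self, rng):
        A, B = random_psd(rng, 10, 3.0), random_psd(rng, 10, 2.0)
        pair = optimize_subspaces(_epoch_data(A, B), 2, 3, seed=1)
        assert np.all(np.diff(pair.objective_history) >= 0)
        assert pair.objective <= 1.0 + 1e-12

    def test_orthonormality_constraints(self, rng):
        A, B = random_psd(rng, 12), random_psd(rng, 12)
        pair = optimize_subspaces(_epoch_data(A, B), 3, 4, seed=2)
        Q = np.hstack([pair.Q_prep, pair.Q_move])
        assert np.abs(Q.T @ Q - np.eye(7)).max() < 1e-8

    def test_subspaces_not_bases_are_identified(self, rng):
        """Different random starts converge to the same subspaces even
        though the bases may differ by a rotation."""
        A, B = random_psd(rng, 9, 2.0), random_psd(rng, 9, 2.0)
        p1 = optimize_subspaces(_epoch_data(A, B), 2, 2, seed=3)
        p2 = optimize_subspaces(_epoch_data(A, B), 2, 2, seed=99)
        assert principal_angles_deg(p1.Q_prep, p2.Q_prep).max() < 0.5
        assert principal_angles_deg(p1.Q_move, p2.Q_move).max() < 0.5

    def test_capacity_check(self, rng):
        A, B = random_psd(rng, 5), random_psd(rng, 5)
        with pytest.raises(ArgumentError):
            optimize_subspaces(_epoch_data(A, B), 3, 3, seed=0)


def _avg_from_groups(groups, time):
    return ConditionAverage(groups=groups, counts={k: 1 for k in groups},
                            time=time, alignment="move_onset",
                            unit_ids=[f"n{i}" for i in range(
                                next(iter(groups.values())).shape[0])])


class TestCrossConditionVariance:
    def _pair(self, n, dp, dm, seed=0):
        rng = np.random.default_rng(seed)
        Q = np.linalg.qr(rng.standard_normal((n, dp + dm)))[0]
        from prepexec.subspace import SubspacePair
        return SubspacePair(Q_prep=Q[:, :dp], Q_move=Q[:, dp:], d_prep=dp,
                            d_move=dm, objective=1.0, term_prep=1.0,
                            term_move=1.0)

    def test_identical_conditions_zero_variance(self, rng):
        base = rng.standard_normal((6, 11))
        avg = _avg_from_groups({"a": base, "b": base.copy()},
                               np.arange(11) * 0.01)
        trace = cross_condition_variance(avg, self._pair(6, 2, 2))
        assert np.abs(trace.var_prep).max() < 1e-20
        assert np.abs(trace.var_move).max() < 1e-20

    def test_prep_only_differences(self, rng):
        pair = self._pair(7, 2, 3)
        time = np.arange(9) * 0.01
        base = rng.standard_normal((7, 9))
        shift = pair.Q_prep @ rng.standard_normal((2, 9))
        avg = _avg_from_groups({"a": base, "b": base + shift}, time)
        trace = cross_condition_variance(avg, pair)
        assert np.abs(trace.var_move).max() < 1e-20
        assert np.allclose(trace.share_prep, 1.0)

    def test_matches_bruteforce(self, rng):
        pair = self._pair(8, 3, 2, seed=4)
        time = np.arange(6) * 0.01
        groups = {f"c{k}": rng.standard_normal((8, 6)) for k in range(5)}
        trace = cross_condition_variance(_avg_from_groups(groups, time), pair)
        M = np.stack(list(groups.values()))
        for ti in range(6):
            S = M[:, :, ti]
            Sc = S - S.mean(axis=0)
            brute = sum(np.var(Sc @ pair.Q_prep[:, d], ddof=1)
                        for d in range(3))
            assert trace.var_prep[ti] == pytest.approx(brute, abs=1e-10)

    def test_shares_bounded(self, rng):
        pair = self._pair(10, 3, 3, seed=5)
        groups = {f"c{k}": rng.standard_normal((10, 4)) for k in range(6)}
        trace = cross_condition_variance(
            _avg_from_groups(groups, np.arange(4) * 0.01), pair)
        assert np.all(trace.share_prep + trace.share_move <= 1.0 + 1e-10)

    def test_single_condition_rejected(self, rng):
        avg = _avg_from_groups({"a": rng.standard_normal((6, 3))},
                               np.arange(3) * 0.01)
        from prepexec.errors import StatisticsError
        with pytest.raises(StatisticsError):
            cross_condition_variance(avg, self._pair(6, 2, 2))
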