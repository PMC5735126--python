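"""DFT machinery, subspace objectives, optimisers and the stationarity test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dssa.preprocess import prewhiten
from dssa.ssa import (
    compute_dft,
    dft_autocovariance,
    dssa_objective,
    epoch_statistics,
    estimate_dimension,
    issa_objective,
    optimize_dssa,
    optimize_issa,
    stationarity_test,
)
from dssa.synthetic import SourceSpec, TrialSeries, generate_sources


def brute_force_dft(Z):
    """O(T^2) direct evaluation of the DFT at omega_k = 2 pi k / T, k=1..T."""
    Z = np.atleast_2d(Z)
    d, T = Z.shape
    J = np.zeros((d, T), dtype=complex)
    for k in range(1, T + 1):
        w = 2 * np.pi * k / T
        for t in range(1, T + 1):
            J[:, k - 1] += Z[:, t - 1] * np.exp(-1j * t * w)
    return J / np.sqrt(2 * np.pi * T)


def brute_force_autocov(J, r):
    d, T = J.shape
    G = np.zeros((d, d), dtype=complex)
    for k in range(1, T + 1):
        k2 = (k + r - 1) % T + 1  # wrap modulo T
        G += np.outer(J[:, k - 1], np.conj(J[:, k2 - 1]))
    return G / T


class TestDFT:
    def test_zero_series_gives_zero_coefficients(self):
        assert np.all(compute_dft(np.zeros((2, 16))).coefficients == 0)

    def test_constant_series_value_at_full_cycle(self):
        """For Z_t = 1 every summand at k = T is 1, so J = sqrt(T / 2 pi)."""
        J = compute_dft(np.ones((1, 8))).coefficients
        assert J[0, -1] == pytest.approx(np.sqrt(8 / (2 * np.pi)), abs=1e-12)

    def test_matches_brute_force_summation(self, rng):
        Z = rng.standard_normal((3, 16))
        J = compute_dft(Z).coefficients
        assert np.max(np.abs(J - brute_force_dft(Z))) < 1e-10

    def test_conjugate_symmetry_for_real_input(self, rng):
        Z = rng.standard_normal((2, 12))
        J = compute_dft(Z).coefficients
        T = 12
        for k in range(1, T):
            assert np.allclose(J[:, (T - k) - 1], np.conj(J[:, k - 1]), atol=1e-12)

    def test_parseval_identity(self, rng):
        Z = rng.standard_normal((3, 64))
        J = compute_dft(Z).coefficients
        lhs = np.sum(np.abs(J) ** 2)
        rhs = np.sum(Z**2) / (2 * np.pi)
        assert abs(lhs - rhs) < 1e-8 * rhs

    def test_non_finite_input_rejected(self):
        Z = np.ones((1, 8))
        Z[0, 3] = np.inf
        with pytest.raises(ValueError, match="finite"):
            compute_dft(Z)


class TestDFTAutocovariance:
    def test_zero_series_gives_zero_matrix(self):
        dfts = compute_dft(np.zeros((2, 32)))
        assert np.all(dft_autocovariance(dfts, 1) == 0)

    @pytest.mark.parametrize("r", [1, 3, 30, 31])
    def test_matches_double_loop_oracle(self, rng, r):
        Z = rng.standard_normal((2, 32))
        dfts = compute_dft(Z)
        oracle = brute_force_autocov(dfts.coefficients, r)
        assert np.max(np.abs(dft_autocovariance(dfts, r) - oracle)) < 1e-10

    def test_lag_out_of_range_rejected(self, rng):
        dfts = compute_dft(rng.standard_normal((1, 16)))
        for r in (0, 16, -1):
            with pytest.raises(ValueError, match="lag"):
                dft_autocovariance(dfts, r)

    def test_magnitude_decays_with_sample_size(self):
        """For iid series the lag-1 autocovariance shrinks as T grows."""
        medians = []
        for T in (128, 512, 2048):
            norms = []
            for rep in range(200):
                rng = np.random.default_rng(rep * 7 + T)
                g = dft_autocovariance(compute_dft(rng.standard_normal((1, T))), 1)
                norms.append(np.linalg.norm(g))
            medians.append(np.median(norms))
        assert medians[0] > medians[1] > medians[2]


class TestDssaObjective:
    def test_invariant_under_row_rotation(self, rng):
        X = rng.standard_normal((4, 64))
        B1, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        B1 = B1.T
        theta = 0.7
        Q = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        a = dssa_objective(B1, X, m=3)
        b = dssa_objective(Q @ B1, X, m=3)
        assert abs(a - b) < 1e-10

    def test_matches_from_scratch_oracle(self, rng):
        X = rng.standard_normal((4, 64))
        B1, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        B1 = B1.T
        Y = B1 @ X
        J = brute_force_dft(Y)
        oracle = sum(
            np.sum(np.abs(brute_force_autocov(J, r)) ** 2) for r in range(1, 4)
        )
        assert abs(dssa_objective(B1, X, m=3) - oracle) < 1e-10

    def test_projection_transform_consistency(self, rng):
        """Projecting then transforming equals transforming then projecting."""
        X = rng.standard_normal((5, 128))
        B1, _ = np.linalg.qr(rng.standard_normal((5, 3)))
        B1 = B1.T
        direct = dssa_objective(B1, X, m=5)
        # project the full-dimensional DFT autocovariances instead
        dfts = compute_dft(X)
        indirect = sum(
            np.sum(np.abs(B1 @ dft_autocovariance(dfts, r) @ B1.T) ** 2)
            for r in range(1, 6)
        )
        assert abs(direct - indirect) < 1e-8

    def test_non_orthonormal_frame_rejected(self, rng):
        X = rng.standard_normal((3, 64))
        with pytest.raises(ValueError, match="orthonormal"):
            dssa_objective(np.ones((2, 3)), X, m=2)

    def test_separates_stationary_from_unit_root_pair(self):
        """The true stationary pair scores lower than the unit-root pair."""
        wins = 0
        n = 30
        for rep in range(n):
            rng = np.random.default_rng(70_000 + rep)
            stat = generate_sources(
                [SourceSpec("var_stationary", 1, {"coeffs": [c]}) for c in (0.4, -0.3)],
                2000,
                rng,
            )
            walks = np.cumsum(rng.standard_normal((2, 2000)), axis=1)
            X = np.vstack([stat, walks])
            e = np.eye(4)
            if dssa_objective(e[:2], X, m=3) < dssa_objective(e[2:], X, m=3):
                wins += 1
        assert wins >= int(0.95 * n)


class TestOptimizeDssa:
    def test_same_seed_identical_result(self, rng):
        X = rng.standard_normal((4, 256))
        with pytest.warns(UserWarning, match="prewhitened"):
            a = optimize_dssa(X, 2, m=3, n_restarts=3, seed=11)
            b = optimize_dssa(X, 2, m=3, n_restarts=3, seed=11)
        assert np.array_equal(a.B1, b.B1)
        assert a.objective == b.objective
        assert a.best_restart_seed == b.best_restart_seed

    def test_full_dimension_equals_identity_objective(self, rng):
        white, _ = prewhiten(TrialSeries("s", "t", rng.standard_normal((3, 256))))
        res = optimize_dssa(white.data, 3, m=4, n_restarts=2, seed=0)
        assert abs(res.objective - dssa_objective(np.eye(3), white.data, 4)) < 1e-8

    def test_descent_is_monotone(self, rng):
        white, _ = prewhiten(TrialSeries("s", "t", rng.standard_normal((5, 512))))
        res = optimize_dssa(white.data, 2, m=5, n_restarts=2, seed=4)
        assert np.all(np.diff(res.objective_history) <= 0)
        assert res.B1.shape == (2, 5)
        assert np.max(np.abs(res.B1 @ res.B1.T - np.eye(2))) < 1e-8

    def test_invalid_dimension_rejected(self, rng):
        with pytest.raises(ValueError, match="d"):
            optimize_dssa(rng.standard_normal((3, 128)), 4)

    def test_optimum_shrinks_with_sample_size(self):
        """For stationary input the optimised objective decays with T."""
        meds = []
        for T in (256, 1024):
            objs = []
            for rep in range(10):
                rng = np.random.default_rng(80_000 + rep)
                white, _ = prewhiten(TrialSeries("s", "t", rng.standard_normal((4, T))))
                objs.append(optimize_dssa(white.data, 2, m=5, n_restarts=2, seed=rep).objective)
            meds.append(np.median(objs))
        assert meds[1] < meds[0]


class TestEpochStats:
    def test_single_epoch_equals_whole_series_moments(self, rng):
        Y = rng.standard_normal((3, 90))
        stats = epoch_statistics(Y, 1)
        assert np.allclose(stats.grand_mean, Y.mean(axis=1))
        c = Y - Y.mean(axis=1, keepdims=True)
        assert np.allclose(stats.grand_covariance, c @ c.T / 90)

    def test_planted_block_means_recovered(self):
        Y = np.concatenate([np.zeros(40), np.ones(40)])[None, :]
        Y = np.vstack([Y, Y])  # 2 x 80 won't matter: use per-block means
        stats = epoch_statistics(Y, 2)
        assert np.allclose(stats.means[0], 0.0)
        assert np.allclose(stats.means[1], 1.0)

    def test_matches_slicing_oracle_with_remainder(self, rng):
        Y = rng.standard_normal((2, 103))  # 103 = 4 * 25 + 3 -> last block 28
        stats = epoch_statistics(Y, 4)
        bounds = [(0, 25), (25, 50), (50, 75), (75, 103)]
        for i, (a, b) in enumerate(bounds):
            block = Y[:, a:b]
            assert np.allclose(stats.means[i], block.mean(axis=1))
            c = block - block.mean(axis=1, keepdims=True)
            assert np.allclose(stats.covariances[i], c @ c.T / (b - a), atol=1e-12)
        assert np.allclose(stats.grand_mean, stats.means.mean(axis=0))
        assert np.allclose(stats.grand_covariance, stats.covariances.mean(axis=0))

    def test_too_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="short"):
            epoch_statistics(rng.standard_normal((4, 30)), 8)


class TestIssaObjective:
    def test_zero_for_identical_unit_epochs(self):
        # orthonormal rows scaled so every epoch has covariance I and mean 0
        rng = np.random.default_rng(0)
        base = rng.standard_normal((2, 50))
        base -= base.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(base.T)
        block = (q * np.sqrt(50)).T  # exact identity covariance, zero mean
        Y = np.hstack([block, block, block, block])
        L = issa_objective(np.eye(2), Y, N=4)
        assert abs(L) < 1e-8

    def test_mean_shift_increases_by_expansion_formula(self, rng):
        """Shifting one epoch's mean by delta adds delta^2 (N-1)/N."""
        rng = np.random.default_rng(1)
        base = rng.standard_normal((2, 40))
        base -= base.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(base.T)
        block = (q * np.sqrt(40)).T
        N, delta = 4, 0.9
        blocks = [block.copy() for _ in range(N)]
        L0 = issa_objective(np.eye(2), np.hstack(blocks), N=N)
        blocks[1] = blocks[1] + np.array([[delta], [0.0]])
        L1 = issa_objective(np.eye(2), np.hstack(blocks), N=N)
        assert abs((L1 - L0) - delta**2 * (N - 1) / N) < 1e-10

    def test_matches_brute_force_recomputation(self, rng):
        X = rng.standard_normal((4, 320))
        B1, _ = np.linalg.qr(rng.standard_normal((4, 2)))
        B1 = B1.T
        stats = epoch_statistics(B1 @ X, 5)
        oracle = 0.0
        for i in range(5):
            sign, logdet = np.linalg.slogdet(stats.covariances[i])
            diff = stats.means[i] - stats.grand_mean
            oracle += -logdet + diff @ diff
        assert abs(issa_objective(B1, X, N=5) - oracle) < 1e-10

    def test_full_dimension_matches_identity_on_whitened_input(self, rng):
        white, _ = prewhiten(TrialSeries("s", "t", rng.standard_normal((3, 400))))
        res = optimize_issa(white.data, 3, N=5, n_restarts=2, seed=0)
        assert abs(res.objective - issa_objective(np.eye(3), white.data, N=5)) < 1e-6

    def test_issa_same_seed_identical(self, rng):
        white, _ = prewhiten(TrialSeries("s", "t", rng.standard_normal((4, 400))))
        a = optimize_issa(white.data, 2, N=4, n_restarts=3, seed=9)
        b = optimize_issa(white.data, 2, N=4, n_restarts=3, seed=9)
        assert np.array_equal(a.B1, b.B1)


class TestStationarityTest:
    def test_p_value_within_permutation_bounds(self, rng):
        res = stationarity_test(rng.standard_normal((1, 128)), m=3, n_null_draws=19, seed=0)
        assert 1 / 20 <= res.p_value <= 1.0
        assert res.statistic >= 0

    def test_too_few_null_draws_rejected(self, rng):
        with pytest.raises(ValueError, match="n_null_draws"):
            stationarity_test(rng.standard_normal((1, 128)), n_null_draws=10)

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="T >= 64"):
            stationarity_test(rng.standard_normal((1, 32)))

    def test_variance_step_detected(self):
        rng = np.random.default_rng(42)
        y = rng.standard_normal(1024)
        y[512:] *= 2.0
        res = stationarity_test(y[None, :], m=10, n_null_draws=99, seed=7)
        assert res.p_value <= 0.05


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 1000))
def test_dssa_objective_nonnegative(seed):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((4, 96))
    B1, _ = np.linalg.qr(rng.standard_normal((4, 2)))
    assert dssa_objective(B1.T, X, m=4) >= 0


def test_estimate_dimension_smoke_mixture():
    """Modal estimate over a few replicates hits the true d = 2 (p = 4)."""
    d_hats = []
    for rep in range(5):
        rng = np.random.default_rng(90_000 + rep)
        stat = generate_sources(
            [SourceSpec("var_stationary", 1, {"coeffs": [c]}) for c in (0.5, -0.4)], 1500, rng
        )
        bursts = generate_sources(
            [
                SourceSpec(
                    "gaussian_tv_variance",
                    0,
                    {"variance_profile": {"type": "bump", "low": 0.05, "high": 18.0,
                                          "center": c, "width": 0.08}},
                )
                for c in (0.2, 0.65)
            ],
            1500,
            rng,
        )
        X = rng.standard_normal((4, 4)) @ np.vstack([stat, bursts])
        white, _ = prewhiten(TrialSeries("s", "t", X))
        d_hats.append(
            estimate_dimension(white.data, seed=rep, n_restarts=2, n_null_draws=49)
        )
    vals, counts = np.unique(d_hats, return_counts=True)
    assert vals[np.argmax(counts)] == 2
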