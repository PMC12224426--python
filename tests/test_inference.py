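import numpy as np
import pytest
from scipy import stats as sps

from cleanv import (
    estimate_effect_size,
    fwer_threshold,
    hcp_style_scenarios,
    kinship_test_retest,
    permutation_scores,
    permutation_stream,
    run_cleanv,
    score_statistics,
    simulate_dataset,
)
from cleanv.enhance import DegenerateDataError


class TestPermutationStream:
    def test_deterministic_given_seed(self):
        a = permutation_stream(10, 5, seed=3)
        b = permutation_stream(10, 5, seed=3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, permutation_stream(10, 5, seed=4))

    def test_rows_are_permutations(self):
        perms = permutation_stream(7, 20, seed=0)
        for p in perms:
            assert np.array_equal(np.sort(p), np.arange(7))

    def test_uniform_over_symmetric_group(self):
        # N=3: all 6 permutations should appear with frequency ~1/6
        perms = permutation_stream(3, 6000, seed=11)
        codes = perms[:, 0] * 9 + perms[:, 1] * 3 + perms[:, 2]
        _, counts = np.unique(codes, return_counts=True)
        assert counts.size == 6
        chi2 = np.sum((counts - 1000.0) ** 2 / 1000.0)
        assert chi2 < sps.chi2.ppf(0.999, df=5)

    def test_identity_permutation_reproduces_observed(self, rng):
        d = rng.standard_normal((6, 4))
        K = kinship_test_retest(np.repeat(["a", "b", "c"], 2)).K
        U = score_statistics(d, K).U
        U_perm = permutation_scores(d, K, np.arange(6)[None, :])
        assert np.allclose(U_perm[0], U)


class TestPermutationScores:
    def test_fixed_permutation_matches_bruteforce(self, rng):
        d = rng.standard_normal((4, 3))
        K = kinship_test_retest(["a", "a", "b", "b"]).K
        perm = np.array([2, 0, 3, 1])
        U_perm = permutation_scores(d, K, perm[None, :])[0]
        for v in range(3):
            x = d[perm, v]
            expected = sum(
                x[i] * K[i, j] * x[j] for i in range(4) for j in range(4)
            )
            assert U_perm[v] == pytest.approx(expected, rel=1e-12)

    def test_row_multiset_preserved(self, rng):
        d = rng.standard_normal((5, 2))
        perms = permutation_stream(5, 10, seed=2)
        for p in perms:
            assert np.allclose(np.sort(d[p], axis=0), np.sort(d, axis=0))

    def test_exchangeable_kernel_degeneracy_flagged(self, grid5, rng):
        # K = I makes every permuted statistic identical -> zero variance
        Y = rng.standard_normal((8, 25))
        with pytest.warns(UserWarning):  # singleton-subject degenerate design
            K = kinship_test_retest([f"s{i}" for i in range(8)])
        with pytest.raises(DegenerateDataError):
            run_cleanv(Y, None, grid5, K, variant="massive", B=60, seed=0)


class TestFwerThreshold:
    def test_rank_formula(self):
        T_perm = np.arange(1.0, 101.0)
        assert fwer_threshold(T_perm, 0.05) == 95.0  # ceil(95) = 95th value

    def test_twenty_values(self):
        assert fwer_threshold(np.arange(1.0, 21.0), 0.05) == 19.0

    def test_alpha_near_one_gives_minimum(self):
        T_perm = np.array([5.0, 1.0, 3.0])
        assert fwer_threshold(T_perm, 0.999) == 1.0

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            fwer_threshold(np.ones(10), 1.5)


@pytest.fixture(scope="module")
def null_data(grid10):
    scen = hcp_style_scenarios("null", grid10, n_units=10)
    Y, X, K = simulate_dataset(scen, seed=77)
    return Y, X, K


class TestRunCleanV:
    def test_no_spatial_radius_zero_equals_massive(self, grid10, null_data):
        Y, X, K = null_data
        a = run_cleanv(Y, X, grid10, K, variant="no_spatial", radii=[0], B=80, seed=5)
        b = run_cleanv(Y, X, grid10, K, variant="massive", B=80, seed=5)
        assert np.array_equal(a.Tv, b.Tv)
        assert a.T == b.T and a.t_alpha == b.t_alpha
        assert np.array_equal(a.significant, b.significant)

    def test_full_without_spatial_noise_approaches_massive(self, grid10):
        scen = hcp_style_scenarios("null", grid10, n_units=50, sigma2=0.0)
        Y, X, K = simulate_dataset(scen, seed=9)
        full = run_cleanv(Y, X, grid10, K, variant="full", radii=[0], B=80, seed=6)
        mass = run_cleanv(Y, X, grid10, K, variant="massive", B=80, seed=6)
        assert full.params.sigma2 < 0.05
        assert np.nanmax(np.abs(full.Tv - mass.Tv)) < 0.05

    def test_seeded_rerun_bit_identical(self, grid10, null_data):
        Y, X, K = null_data
        a = run_cleanv(Y, X, grid10, K, B=60, seed=42, radii=[0, 2, 4])
        b = run_cleanv(Y, X, grid10, K, B=60, seed=42, radii=[0, 2, 4])
        assert np.array_equal(a.Tv, b.Tv, equal_nan=True)
        assert np.array_equal(a.T_perm, b.T_perm)
        assert a.T == b.T and a.p_global == b.p_global

    def test_localization_consistent_with_threshold(self, grid10):
        scen = hcp_style_scenarios("test_retest", grid10, theta2=3.0)
        Y, X, K = simulate_dataset(scen, seed=15)
        res = run_cleanv(Y, X, grid10, K, B=100, seed=16, radii=[0, 2, 4])
        rethreshold = np.flatnonzero(
            np.nan_to_num(res.Tv, nan=-np.inf) > res.t_alpha
        )
        assert np.array_equal(res.significant, rethreshold)
        if res.significant.size:
            assert res.T > res.t_alpha

    def test_global_p_and_threshold_decisions_agree(self, grid10, null_data):
        Y, X, K = null_data
        res = run_cleanv(Y, X, grid10, K, variant="massive", B=100, seed=21)
        assert 0 < res.p_global <= 1
        if res.T > res.t_alpha:
            assert res.p_global <= res.config["alpha"]
        elif res.T < res.t_alpha:
            assert res.p_global > res.config["alpha"]

    def test_kernel_diagonal_shift_leaves_inference_unchanged(self, grid10, null_data):
        # replacing K by K - I shifts U by a permutation-invariant constant,
        # so every standardized statistic is identical
        Y, X, K = null_data
        a = run_cleanv(Y, X, grid10, K.K, variant="massive", B=60, seed=8)
        b = run_cleanv(
            Y, X, grid10, K.K - np.eye(K.n_images), variant="massive", B=60, seed=8
        )
        assert np.allclose(a.Tv, b.Tv, atol=1e-8)
        assert a.t_alpha == pytest.approx(b.t_alpha, abs=1e-8)

    def test_config_echo_recorded(self, grid10, null_data):
        Y, X, K = null_data
        res = run_cleanv(Y, X, grid10, K, B=60, seed=1, radii=[0, 3], alpha=0.1)
        assert res.config["variant"] == "full"
        assert res.config["B"] == 60
        assert res.config["alpha"] == 0.1
        assert res.config["radii"] == [0.0, 3.0]

    def test_unknown_variant_rejected(self, grid10, null_data):
        Y, X, K = null_data
        with pytest.raises(ValueError, match="variant"):
            run_cleanv(Y, X, grid10, K, variant="bogus", B=60)


class TestEffectSize:
    def test_null_data_near_zero(self, grid10):
        # the estimator is defined under the vertex-level (non-spatial)
        # model, so the null check generates from that model (sigma2 = 0)
        scen = hcp_style_scenarios("null", grid10, n_units=100, sigma2=0.0)
        Y, X, K = simulate_dataset(scen, seed=3)
        ratio = estimate_effect_size(Y, X, K)
        assert ratio.mean() < 0.05

    def test_theta_equals_tau_gives_half(self, grid10):
        scen = hcp_style_scenarios(
            "test_retest",
            grid10,
            n_units=200,
            theta2=1.0,
            tau2=1.0,
            sigma2=0.0,
            signal_fraction=1.0,
        )
        Y, X, K = simulate_dataset(scen, seed=4)
        ratio = estimate_effect_size(Y, X, K)
        assert ratio.mean() == pytest.approx(0.5, abs=0.05)

    def test_duplicated_images_give_one(self, grid10, rng):
        base = rng.standard_normal((10, 100))
        Y = np.repeat(base, 2, axis=0)
        K = kinship_test_retest(np.repeat(np.arange(10), 2))
        ratio = estimate_effect_size(Y, None, K)
        assert np.allclose(ratio, 1.0)

    def test_design_without_pairs_rejected(self, rng):
        with pytest.warns(UserWarning):
            K = kinship_test_retest(["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="related"):
            estimate_effect_size(rng.standard_normal((4, 5)), None, K)
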