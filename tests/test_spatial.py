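import numpy as np
import pytest
from scipy.linalg import solve

from cleanv import (
    apply_precision,
    blup_spatial,
    exponential_sacf,
    fit_covariance_regression,
    ols_residuals,
)
from cleanv.spatial import ResidualImages, SpatialNoiseParams, covariance_objective


class TestExponentialSacf:
    def test_zero_distance_is_one(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        Phi = exponential_sacf(D, 0.5)
        assert np.all(np.diag(Phi) == 1.0)

    def test_direct_value(self):
        Phi = exponential_sacf(np.array([[0.0, 10.0], [10.0, 0.0]]), 0.1)
        assert Phi[0, 1] == pytest.approx(np.exp(-1), abs=1e-12)
        assert Phi[0, 1] == pytest.approx(0.367879, abs=1e-6)

    def test_monotone_decreasing_in_phi(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        vals = [exponential_sacf(D, p)[0, 1] for p in (0.1, 1.0, 10.0)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-10

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            exponential_sacf(np.zeros((2, 2)), 0.0)


class TestOlsResiduals:
    def test_intercept_only_centers_columns(self, rng):
        Y = rng.standard_normal((8, 5))
        E = ols_residuals(Y, np.ones((8, 1))).E
        assert np.allclose(E, Y - Y.mean(axis=0))

    def test_exact_fit_gives_zero(self, rng):
        X = np.column_stack([np.ones(6), rng.standard_normal(6)])
        beta = rng.standard_normal((2, 4))
        E = ols_residuals(X @ beta, X).E
        assert np.allclose(E, 0, atol=1e-10)

    def test_matches_per_vertex_regression_loop(self, rng):
        X = np.column_stack([np.ones(4), rng.standard_normal(4)])
        Y = rng.standard_normal((4, 2))
        E = ols_residuals(Y, X).E
        for v in range(2):
            coef, *_ = np.linalg.lstsq(X, Y[:, v], rcond=None)
            assert np.allclose(E[:, v], Y[:, v] - X @ coef)

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(ValueError, match="rank deficient"):
            ols_residuals(np.zeros((5, 2)), X)

    def test_residuals_orthogonal_to_design(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal((10, 2))])
        E = ols_residuals(rng.standard_normal((10, 7)), X).E
        assert np.allclose(X.T @ E, 0, atol=1e-9)


class TestCovarianceRegression:
    def test_exact_fit_recovered_to_machine_precision(self, grid10):
        D = grid10.D
        V = 100
        M = 2.0 * exponential_sacf(D, 0.2) + 1.0 * np.eye(V)
        # build residuals whose mean outer product is exactly M
        vals, vecs = np.linalg.eigh(M)
        E = np.sqrt(V) * (vecs * np.sqrt(vals)) @ vecs.T
        params = fit_covariance_regression(E, D, phi_grid=[0.05, 0.2, 0.8])
        assert params.phi == 0.2
        assert params.sigma2 == pytest.approx(2.0, rel=1e-10)
        assert params.tau2 == pytest.approx(1.0, rel=1e-8)
        # objective is assembled from large Frobenius inner products, so the
        # exact-fit zero is recovered only up to their cancellation error
        assert abs(params.objective) < 1e-6 * np.sum(M * M)

    def test_pure_white_noise(self, grid10, rng):
        E = 1.5 * rng.standard_normal((800, 100))
        E -= E.mean(axis=0)
        params = fit_covariance_regression(E, grid10.D)
        assert params.sigma2 < 0.1
        assert params.tau2 == pytest.approx(2.25, rel=0.1)

    def test_grid_sweep_optimality(self, grid10, rng):
        E = rng.standard_normal((50, 100)) + 0.5 * rng.standard_normal((50, 1))
        grid = np.geomspace(0.02, 1.0, 8)
        params = fit_covariance_regression(E, grid10.D, phi_grid=grid)
        best = covariance_objective(
            E, grid10.D, params.sigma2, params.tau2, params.phi
        )
        for phi in grid:
            single = fit_covariance_regression(E, grid10.D, phi_grid=[phi])
            other = covariance_objective(
                E, grid10.D, single.sigma2, single.tau2, phi
            )
            assert best <= other + 1e-9

    def test_all_zero_residuals_rejected(self, grid10):
        with pytest.raises(ValueError, match="zero"):
            fit_covariance_regression(np.zeros((5, 100)), grid10.D)


class TestBlup:
    def test_zero_sigma2_gives_zero_bhat(self, grid10, rng):
        E = rng.standard_normal((6, 100))
        params = SpatialNoiseParams(sigma2=0.0, tau2=1.0, phi=0.1)
        out = blup_spatial(ResidualImages(E=E), params, grid10.D)
        assert np.all(out.Bhat == 0)
        assert np.array_equal(out.Delta, E)

    def test_vanishing_tau2_gives_bhat_close_to_e(self, grid10, rng):
        E = rng.standard_normal((4, 100))
        params = SpatialNoiseParams(sigma2=1.0, tau2=1e-10, phi=0.1)
        out = blup_spatial(ResidualImages(E=E), params, grid10.D)
        assert np.allclose(out.Bhat, E, atol=1e-5)

    def test_three_vertex_toy_matches_dense_solve(self):
        D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        params = SpatialNoiseParams(sigma2=2.0, tau2=0.5, phi=0.3)
        E = np.array([[1.0, -2.0, 0.5]])
        Phi = np.exp(-0.3 * D)
        Sigma = 2.0 * Phi + 0.5 * np.eye(3)
        expected = 2.0 * Phi @ solve(Sigma, E[0])
        out = blup_spatial(ResidualImages(E=E), params, D)
        assert np.allclose(out.Bhat[0], expected, atol=1e-12)
        assert np.allclose(out.E, out.Bhat + out.Delta)

    def test_shrinkage_in_sigma_norm(self, grid10, rng):
        E = rng.standard_normal((10, 100))
        params = SpatialNoiseParams(sigma2=1.0, tau2=0.7, phi=0.2)
        out = blup_spatial(ResidualImages(E=E), params, grid10.D)
        Sigma = exponential_sacf(grid10.D, 0.2) + 0.7 * np.eye(100)
        Sinv = np.linalg.inv(Sigma)
        for i in range(10):
            nb = out.Bhat[i] @ Sinv @ out.Bhat[i]
            ne = E[i] @ Sinv @ E[i]
            assert nb <= ne + 1e-10


class TestApplyPrecision:
    def test_diagonal_covariance(self, rng):
        x = rng.standard_normal(20)
        params = SpatialNoiseParams(sigma2=0.0, tau2=2.0, phi=0.1)
        out = apply_precision(params, np.zeros((20, 20)), x)
        assert np.allclose(out, x / 2.0)

    def test_nngp_full_neighbors_equals_exact(self, rng):
        coords = rng.uniform(0, 10, size=(50, 2))
        D = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        params = SpatialNoiseParams(sigma2=1.3, tau2=0.4, phi=0.25)
        x = rng.standard_normal((50, 3))
        exact = apply_precision(params, D, x, method="exact")
        nngp = apply_precision(params, D, x, method="nngp", m=49)
        assert np.max(np.abs(exact - nngp)) < 1e-10

    def test_nngp_truncated_approximation_error(self, rng):
        coords = np.sort(rng.uniform(0, 40, size=200))  # ordered 1-d sites
        D = np.abs(coords[:, None] - coords[None, :])
        params = SpatialNoiseParams(sigma2=1.0, tau2=0.5, phi=0.15)
        x = rng.standard_normal(200)
        y = apply_precision(params, D, x, method="nngp", m=30)
        Sigma = params.sigma2 * np.exp(-params.phi * D) + params.tau2 * np.eye(200)
        recon = Sigma @ y
        rel_err = np.linalg.norm(recon - x) / np.linalg.norm(x)
        assert rel_err < 0.05

    def test_m_too_large_falls_back(self, rng):
        D = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
        params = SpatialNoiseParams(sigma2=1.0, tau2=1.0, phi=0.5)
        with pytest.warns(UserWarning, match="falling back"):
            out = apply_precision(params, D, np.ones(5), method="nngp", m=10)
        exact = apply_precision(params, D, np.ones(5), method="exact")
        assert np.allclose(out, exact)
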