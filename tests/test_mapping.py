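"""Spatial Bayesian regression, composition-sampling prediction, RF baseline."""

import numpy as np
import pytest

from standmap.mapping import (
    SpatialModelFit,
    fit_ensemble_baseline,
    fit_spatial_regression,
    predict_posterior,
    variogram_check,
)


def sim_grid_coords(n, extent=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, extent, size=(n, 2))


def exp_cov(coords, sigma2, phi):
    d = np.sqrt(
        (coords[:, None, 0] - coords[None, :, 0]) ** 2
        + (coords[:, None, 1] - coords[None, :, 1]) ** 2
    )
    return sigma2 * np.exp(-phi * d)


class TestFitSpatialRegression:
    def test_nonspatial_data_posterior_matches_ols(self):
        # sigma2 ~ 0 truth: the posterior mean of beta should sit on the
        # closed-form OLS estimate within its posterior spread
        rng = np.random.default_rng(1)
        n = 80
        coords = sim_grid_coords(n, seed=2)
        X = np.column_stack([np.ones(n), rng.uniform(0, 10, n)])
        beta_true = np.array([5.0, 2.0])
        y = X @ beta_true + rng.normal(0, 1.0, n)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        fit = fit_spatial_regression(
            y, X, coords, mcmc={"n_iter": 1500, "burn_in": 750, "thin": 3, "seed": 3}
        )
        post_mean = fit.beta.mean(axis=0)
        post_sd = fit.beta.std(axis=0)
        assert np.all(np.abs(post_mean - ols) < 2.0 * post_sd)

    def test_duplicate_coordinates_rejected(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 0.0], [3.0, 1.0]])
        X = np.ones((5, 1))
        y = np.arange(5.0)
        with pytest.raises(ValueError, match="duplicate"):
            fit_spatial_regression(y, X, coords)

    def test_too_few_observations_rejected(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0]])
        X = np.column_stack([np.ones(3), np.arange(3.0)])
        with pytest.raises(ValueError, match="p \\+ 2"):
            fit_spatial_regression(np.arange(3.0), X, coords)

    def test_seeded_mcmc_is_deterministic(self):
        rng = np.random.default_rng(4)
        n = 30
        coords = sim_grid_coords(n, seed=5)
        X = np.column_stack([np.ones(n), rng.uniform(0, 5, n)])
        y = X @ [1.0, 0.5] + rng.normal(0, 1, n)
        mcmc = {"n_iter": 400, "burn_in": 200, "thin": 2, "seed": 11}
        a = fit_spatial_regression(y, X, coords, mcmc=mcmc)
        b = fit_spatial_regression(y, X, coords, mcmc=mcmc)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.phi, b.phi)

    def test_retained_draw_count(self):
        rng = np.random.default_rng(6)
        n = 25
        coords = sim_grid_coords(n, seed=7)
        X = np.ones((n, 1))
        y = rng.normal(10, 2, n)
        fit = fit_spatial_regression(
            y, X, coords, mcmc={"n_iter": 600, "burn_in": 300, "thin": 5, "seed": 1}
        )
        assert fit.n_draws == 60
        assert np.all(fit.sigma2 > 0) and np.all(fit.tau2 > 0)
        assert np.all((fit.phi >= fit.phi_support[0]) & (fit.phi <= fit.phi_support[1]))


def manual_fit(coords, y, beta, sigma2, tau2, phi, n_draws=400):
    """A degenerate posterior concentrated at known parameter values."""
    n = len(y)
    X = np.ones((n, 1))
    w = y - X @ [beta]
    return SpatialModelFit(
        beta=np.full((n_draws, 1), beta),
        sigma2=np.full(n_draws, sigma2),
        tau2=np.full(n_draws, tau2),
        phi=np.full(n_draws, phi),
        w=np.tile(w, (n_draws, 1)),
        coords=coords,
        X=X,
        y=y,
    )


class TestPredictPosterior:
    def test_quantile_ordering(self):
        rng = np.random.default_rng(8)
        coords = sim_grid_coords(20, seed=9)
        y = rng.normal(50, 10, 20)
        fit = manual_fit(coords, y, beta=50.0, sigma2=100.0, tau2=25.0, phi=0.01)
        new = sim_grid_coords(40, seed=10)
        pred = predict_posterior(fit, np.ones((40, 1)), new, seed=1)
        assert np.all(pred.lower <= pred.mean + 1e-9)
        assert np.all(pred.mean <= pred.upper + 1e-9)

    def test_interpolates_observations_when_nugget_vanishes(self):
        # exact GP conditioning at a training location: predictive mean -> y
        rng = np.random.default_rng(11)
        coords = sim_grid_coords(25, seed=12)
        y = rng.normal(100, 20, 25)
        fit = manual_fit(coords, y, beta=100.0, sigma2=400.0, tau2=1e-12, phi=0.005)
        pred = predict_posterior(fit, np.ones((25, 1)), coords, seed=2)
        np.testing.assert_allclose(pred.mean, y, atol=0.1)

    def test_far_field_limit_matches_closed_form(self):
        # phi*d >> 1: mean -> X*E[beta], variance -> E[sigma2] + E[tau2]
        rng = np.random.default_rng(13)
        coords = sim_grid_coords(20, extent=100.0, seed=14)
        y = rng.normal(0, 5, 20)
        sigma2, tau2 = 9.0, 4.0
        fit = manual_fit(coords, y, beta=7.0, sigma2=sigma2, tau2=tau2,
                         phi=0.5, n_draws=3000)
        far = np.array([[1e6 + i * 50.0, 1e6] for i in range(50)])
        pred = predict_posterior(fit, np.ones((50, 1)), far, seed=3)
        assert pred.mean.mean() == pytest.approx(7.0, abs=0.3)
        halfwidth = 0.5 * (pred.upper - pred.lower)
        expected = 1.96 * np.sqrt(sigma2 + tau2)
        assert halfwidth.mean() == pytest.approx(expected, rel=0.1)

    def test_design_mismatch_rejected(self):
        coords = sim_grid_coords(10, seed=15)
        fit = manual_fit(coords, np.zeros(10), 0.0, 1.0, 1.0, 0.01)
        with pytest.raises(ValueError, match="columns"):
            predict_posterior(fit, np.ones((5, 2)), sim_grid_coords(5, seed=16))


class TestEnsembleBaseline:
    def test_learnable_signal_high_oob_r2(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(0, 10, size=(600, 1))
        y = 3.0 * x[:, 0] + 2.0
        out = fit_ensemble_baseline(y, x, seed=1)
        assert out["oob_r2"] > 0.9
        assert out["model"].n_estimators == 500

    def test_permuted_labels_null_oob_r2(self):
        rng = np.random.default_rng(18)
        x = rng.uniform(0, 10, size=(400, 2))
        y = rng.permutation(3.0 * x[:, 0])
        out = fit_ensemble_baseline(y, x, n_trees=300, seed=2)
        assert out["oob_r2"] < 0.15

    def test_predictions_returned_for_new_design(self):
        rng = np.random.default_rng(19)
        x = rng.uniform(0, 10, size=(200, 1))
        y = x[:, 0] ** 2
        out = fit_ensemble_baseline(y, x, X_predict=np.array([[5.0]]), n_trees=100, seed=3)
        assert out["predictions"].shape == (1,)
        assert out["predictions"][0] == pytest.approx(25.0, rel=0.2)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_ensemble_baseline(np.ones(3), np.ones((3, 1)))


def brute_semivariance(res, coords, lo, hi):
    vals = []
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            d = np.hypot(*(coords[i] - coords[j]))
            if lo <= d < hi:
                vals.append((res[i] - res[j]) ** 2)
    return 0.5 * np.mean(vals) if vals else np.nan


class TestVariogram:
    def test_constant_residuals_zero_everywhere(self):
        coords = sim_grid_coords(40, seed=20)
        out = variogram_check(np.full(40, 3.3), coords, np.array([0, 200, 400, 600]))
        valid = ~np.isnan(out["semivariance"])
        assert np.allclose(out["semivariance"][valid], 0.0)

    def test_matches_brute_force_pair_loop(self):
        rng = np.random.default_rng(21)
        coords = sim_grid_coords(45, seed=22)
        res = rng.normal(0, 2, 45)
        bins = np.array([0.0, 250.0, 500.0, 750.0, 1500.0])
        out = variogram_check(res, coords, bins)
        for k in range(4):
            expected = brute_semivariance(res, coords, bins[k], bins[k + 1])
            if np.isnan(expected):
                assert np.isnan(out["semivariance"][k])
            else:
                assert out["semivariance"][k] == pytest.approx(expected, rel=1e-9)

    def test_independent_noise_flat_at_variance(self):
        rng = np.random.default_rng(23)
        coords = sim_grid_coords(400, seed=24)
        v = 4.0
        res = rng.normal(0, np.sqrt(v), 400)
        out = variogram_check(res, coords, np.linspace(50, 900, 6))
        valid = ~np.isnan(out["semivariance"])
        np.testing.assert_allclose(out["semivariance"][valid], v, rtol=0.15)

    def test_gp_residuals_track_exponential_curve(self):
        rng = np.random.default_rng(25)
        n, sigma2, phi = 350, 25.0, 0.01
        coords = sim_grid_coords(n, extent=1000.0, seed=26)
        cov = exp_cov(coords, sigma2, phi) + 1e-8 * np.eye(n)
        res = np.linalg.cholesky(cov) @ rng.standard_normal(n)
        bins = np.array([20.0, 80.0, 140.0, 220.0, 320.0])
        out = variogram_check(res, coords, bins)
        for lag, gamma in zip(out["lag"], out["semivariance"]):
            expected = sigma2 * (1.0 - np.exp(-phi * lag))
            assert gamma == pytest.approx(expected, rel=0.35)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            variogram_check(np.ones(10), sim_grid_coords(10, seed=1), np.array([0, 100]))
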