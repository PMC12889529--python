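"""Gaussian-process engine: kernel, likelihood, posterior, CV scoring.

The posterior checks compare the production path against independent
dense linear-algebra oracles (plain ``np.linalg`` formulas, and
scikit-learn's GP regressor with frozen hyperparameters).
"""

import numpy as np
import pytest

from gridsep import (
    GaussianProcessRegression,
    GPHyperparams,
    GPTuningModel,
    fve,
    make_cv_splits,
    make_folds,
    matern52,
)
from gridsep.binning import BinningSpec
from tests.conftest import make_tuning_curve

SQRT5 = np.sqrt(5.0)


class TestMatern52:
    def test_zero_distance_equals_signal_variance(self):
        b = np.array([[1.0, 2.0, 3.0, 4.0]])
        assert matern52(b, b, [10.0] * 4, 0.3)[0, 0] == pytest.approx(0.3)

    def test_unit_scaled_distance_closed_form(self):
        # single-dimension offset equal to its lengthscale -> d = 1
        b1 = np.array([[0.0, 0.0]])
        b2 = np.array([[10.0, 0.0]])
        expected = 0.3 * (1 + SQRT5 + 5.0 / 3.0) * np.exp(-SQRT5)
        assert matern52(b1, b2, [10.0, 7.0], 0.3)[0, 0] == pytest.approx(expected)

    def test_strictly_decreasing_in_distance(self):
        d = np.linspace(0, 5, 40)[:, None]
        k = matern52(d, np.zeros((1, 1)), [1.0], 1.0).ravel()
        assert np.all(np.diff(k) < 0)

    def test_symmetry_and_ard_scaling(self, rng):
        X = rng.normal(size=(8, 4))
        ls = np.array([1.0, 2.0, 5.0, 0.5])
        K = matern52(X, X, ls, 2.0)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        # rescaling inputs and lengthscales together leaves K unchanged
        K2 = matern52(X * ls, X * ls, ls * ls, 2.0)
        np.testing.assert_allclose(K, K2, atol=1e-12)

    def test_nonpositive_lengthscale_rejected(self):
        with pytest.raises(ValueError):
            matern52(np.zeros((2, 1)), np.zeros((2, 1)), [0.0], 1.0)


class TestFVE:
    def test_perfect_prediction_scores_one(self, rng):
        y = rng.normal(size=20)
        assert fve(y, y) == pytest.approx(1.0)

    def test_constant_mean_prediction_scores_zero(self, rng):
        y = rng.normal(size=50)
        assert fve(np.full(50, y.mean()), y) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # residuals (0, 0, -1): Var_res = 2/9, Var_y = 2/3 -> FVE = 2/3
        assert fve([1.0, 2.0, 4.0], [1.0, 2.0, 3.0]) == pytest.approx(2.0 / 3.0)

    def test_zero_variance_held_out_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(fve([1.0, 2.0], [3.0, 3.0]))


class TestGPRegression:
    def _toy(self, rng, n=30, d=2):
        X = rng.uniform(-50, 50, (n, d))
        y = np.sin(X[:, 0] / 15.0) + 0.5 * np.cos(X[:, -1] / 10.0)
        return X, y

    def test_interpolates_targets_in_small_noise_limit(self, rng):
        X, y = self._toy(rng)
        gp = GaussianProcessRegression(
            X, y, GPHyperparams(lengthscales=np.full(2, 10.0),
                                signal_variance=1.0, noise_variance=1e-10)
        ).fit(optimize=False)
        mu, _ = gp.predict(X)
        assert np.max(np.abs(mu - y)) < 1e-6 * np.ptp(y)

    def test_constant_targets_predict_constant(self, rng):
        X = rng.uniform(-50, 50, (20, 3))
        gp = GaussianProcessRegression(X, np.full(20, 4.2)).fit(optimize=False)
        mu, _ = gp.predict(rng.uniform(-80, 80, (15, 3)))
        np.testing.assert_allclose(mu, 4.2, atol=1e-8)

    def test_1d_toy_matches_dense_oracle(self):
        """Five frozen (input, target) pairs, frozen hyperparameters: the
        posterior mean at held-out inputs must equal the textbook GP
        conditional computed with plain dense linear algebra."""
        X = np.array([[0.0], [0.7], [1.3], [2.1], [3.0]])
        y = np.array([0.1, 0.8, 0.5, -0.4, 0.3])
        hyper = GPHyperparams(lengthscales=np.array([1.0]),
                              signal_variance=1.0, noise_variance=0.01)
        gp = GaussianProcessRegression(X, y, hyper).fit(optimize=False)
        Xs = np.array([[0.4], [1.7], [2.6], [5.0]])
        mu, sd = gp.predict(Xs)

        # independent oracle: explicit inverse, no Cholesky
        def k(a, b):
            d = np.abs(a[:, None] - b[None, :])
            return (1 + SQRT5 * d + 5 / 3 * d**2) * np.exp(-SQRT5 * d)

        K = k(X[:, 0], X[:, 0]) + (0.01 + 1e-6) * np.eye(5)
        Ks = k(Xs[:, 0], X[:, 0])
        Kinv = np.linalg.inv(K)
        mu_o = y.mean() + Ks @ Kinv @ (y - y.mean())
        var_o = 1.0 - np.sum((Ks @ Kinv) * Ks, axis=1)
        np.testing.assert_allclose(mu, mu_o, rtol=1e-8, atol=1e-10)
        np.testing.assert_allclose(sd, np.sqrt(var_o), rtol=1e-8, atol=1e-10)

    def test_posterior_matches_dense_oracle_4d(self, rng):
        """Production posterior (Cholesky path) vs naive-inverse oracle on
        200 random 4D training points, to 1e-8 relative tolerance."""
        X = rng.uniform(-75, 75, (200, 4))
        X[:, 2:] *= 25.0 / 75.0
        y = rng.normal(5.0, 2.0, 200)
        hyper = GPHyperparams(lengthscales=np.array([10.0, 12.0, 8.0, 15.0]),
                              signal_variance=2.0, noise_variance=0.5)
        gp = GaussianProcessRegression(X, y, hyper).fit(optimize=False)
        Xs = rng.uniform(-75, 75, (50, 4))
        mu, sd = gp.predict(Xs)

        K = matern52(X, X, hyper.lengthscales, 2.0)
        K += (0.5 + 1e-6 * 2.0) * np.eye(200)
        Ks = matern52(Xs, X, hyper.lengthscales, 2.0)
        Kinv = np.linalg.inv(K)
        mu_o = y.mean() + Ks @ Kinv @ (y - y.mean())
        sd_o = np.sqrt(2.0 - np.sum((Ks @ Kinv) * Ks, axis=1))
        np.testing.assert_allclose(mu, mu_o, rtol=1e-8)
        np.testing.assert_allclose(sd, sd_o, rtol=1e-8)

    def test_posterior_matches_sklearn(self, rng):
        """Cross-check against scikit-learn's GP with identical frozen
        hyperparameters (zero-mean convention emulated by centring)."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, Matern

        X = rng.uniform(-10, 10, (40, 3))
        y = np.sin(X[:, 0]) + rng.normal(0, 0.1, 40)
        ls = np.array([2.0, 3.0, 4.0])
        hyper = GPHyperparams(lengthscales=ls, signal_variance=1.5,
                              noise_variance=0.05)
        gp = GaussianProcessRegression(X, y, hyper).fit(optimize=False)
        Xs = rng.uniform(-12, 12, (10, 3))
        mu, sd = gp.predict(Xs)

        kern = ConstantKernel(1.5, "fixed") * Matern(length_scale=ls, nu=2.5,
                                                     length_scale_bounds="fixed")
        sk = GaussianProcessRegressor(kernel=kern,
                                      alpha=0.05 + 1e-6 * 1.5, optimizer=None)
        sk.fit(X, y - y.mean())
        mu_sk, sd_sk = sk.predict(Xs, return_std=True)
        np.testing.assert_allclose(mu, mu_sk + y.mean(), rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(sd, sd_sk, rtol=1e-6, atol=1e-8)

    def test_optimisation_does_not_decrease_marginal_likelihood(self, rng):
        X, y = self._toy(rng, n=60)
        y += rng.normal(0, 0.2, 60)
        init = GPHyperparams(lengthscales=np.full(2, 10.0))
        gp = GaussianProcessRegression(X, y, init)
        ll0 = gp.log_marginal_likelihood()
        gp.fit(maxiter=50)
        assert gp.log_marginal_likelihood() >= ll0 - 1e-9

    def test_analytic_gradient_matches_finite_differences(self, rng):
        X, y = self._toy(rng, n=25)
        gp = GaussianProcessRegression(X, y)
        theta = np.log(np.array([8.0, 12.0, 0.5, 0.05]))
        _, g = gp._nll_and_grad(theta)
        num = np.empty_like(theta)
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = 1e-6
            num[i] = (gp._nll_and_grad(theta + e)[0]
                      - gp._nll_and_grad(theta - e)[0]) / 2e-6
        np.testing.assert_allclose(g, num, rtol=1e-5, atol=1e-8)

    def test_permuting_training_points_leaves_predictions_unchanged(self, rng):
        X, y = self._toy(rng, n=40)
        hyper = GPHyperparams(lengthscales=np.full(2, 10.0),
                              signal_variance=1.0, noise_variance=0.1)
        perm = rng.permutation(40)
        Xs = rng.uniform(-60, 60, (12, 2))
        mu1, sd1 = GaussianProcessRegression(X, y, hyper).fit(optimize=False).predict(Xs)
        mu2, sd2 = GaussianProcessRegression(X[perm], y[perm], hyper).fit(optimize=False).predict(Xs)
        np.testing.assert_allclose(mu1, mu2, rtol=1e-9)
        np.testing.assert_allclose(sd1, sd2, rtol=1e-9)

    def test_prior_reversion_far_from_data(self, rng):
        X = rng.uniform(-5, 5, (20, 2))
        y = rng.normal(size=20)
        hyper = GPHyperparams(lengthscales=np.full(2, 1.0),
                              signal_variance=0.7, noise_variance=1e-4)
        gp = GaussianProcessRegression(X, y, hyper).fit(optimize=False)
        _, sd_near = gp.predict(X[:3])
        _, sd_far = gp.predict(np.full((1, 2), 500.0))
        assert sd_far[0] == pytest.approx(np.sqrt(0.7), rel=1e-6)
        assert np.all(sd_near < 0.2 * sd_far[0])

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            GaussianProcessRegression(X, np.arange(4))
        with pytest.raises(ValueError):
            GaussianProcessRegression(X, np.array([1, 2, np.nan, 4, 5.0]))
        with pytest.raises(ValueError):
            GPHyperparams(lengthscales=np.array([-1.0]))


class TestFolds:
    def test_folds_partition_indices(self, rng):
        idx = rng.choice(22500, size=487, replace=False)
        folds = make_folds(idx, 5, seed=3)
        assert len(folds) == 5
        union = np.concatenate(folds)
        assert len(union) == len(set(union)) == 487
        assert set(union) == set(idx)
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_splits_train_excludes_validation_and_respects_cap(self, rng):
        idx = np.sort(rng.choice(22500, size=600, replace=False))
        splits = make_cv_splits(idx, 5, seed=0, max_train=300)
        for train, val in splits:
            assert len(np.intersect1d(train, val)) == 0
            assert len(train) == 300
            assert np.all(np.isin(train, idx)) and np.all(np.isin(val, idx))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.arange(3), 5, 0)


class TestGPTuningModel:
    def test_kfold_on_separable_truth_reconstructs(self, rng):
        """A smooth separable 4D rate observed with mild noise: the CV fit
        should explain most held-out variance and fill all 22,500 bins."""
        spec = BinningSpec()
        cx, cv = spec.pos_centers, spec.vel_centers
        pos = np.exp(-((cx[:, None] - 10) ** 2 + (cx[None, :] + 20) ** 2) / (2 * 30**2))
        vel = 1.0 + 0.01 * np.hypot(cv[:, None], cv[None, :])
        rate = 10.0 * np.multiply.outer(pos, vel)
        noisy = rate + rng.normal(0, 0.3, rate.shape)
        visits = np.where(rng.uniform(size=rate.shape) < 0.05, 100, 0)  # sparse coverage
        tc = make_tuning_curve(noisy, visits=visits)
        model = GPTuningModel(tc, max_train_bins=400, hyper_train_bins=400, maxiter=30)
        res = model.fit(seed=0)
        assert res.fve > 0.5
        assert np.all(np.isfinite(res.mean4d)) and np.all(res.std4d >= 0)
        # uncertainty grows away from the data
        train_sd = res.std4d[tc.mask_high]
        assert np.median(train_sd) < np.median(res.std4d[~tc.mask_high])

    def test_summary_mentions_fve(self, rng):
        spec = BinningSpec()
        rate = rng.uniform(3, 5, spec.shape)
        visits = np.where(rng.uniform(size=spec.shape) < 0.01, 50, 0)
        tc = make_tuning_curve(rate, visits=visits)
        res = GPTuningModel(tc, max_train_bins=150, maxiter=10).fit(seed=1, predict_grid=False)
        text = res.summary()
        assert "FVE" in text and "lengthscales" in text

    def test_too_few_high_occupancy_bins_rejected(self):
        spec = BinningSpec()
        rate = np.full(spec.shape, np.nan)
        rate[0, 0, 0, 0] = 1.0
        tc = make_tuning_curve(rate, visits=np.zeros(spec.shape, int))
        with pytest.raises(ValueError):
            GPTuningModel(tc).fit()
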