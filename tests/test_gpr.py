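"""Kernel exactness, GP posterior correctness and hyperparameter fitting."""

import numpy as np
import pytest

from stabgp.gpr import (
    GaussianProcess,
    KernelParams,
    fit_gpr,
    kernel_matrix,
    matern32,
    matern32_ard,
)


def closed_form_posterior(X, y, Xs, params):
    """Independent oracle: direct linear solve, no Cholesky reuse."""
    K = kernel_matrix(X, X, params) + (
        params.noise_variance + params.jitter
    ) * np.eye(len(X))
    Ks = kernel_matrix(Xs, X, params)
    Kinv = np.linalg.inv(K)
    mean = Ks @ Kinv @ y
    var = (
        params.signal_variance
        - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
        + params.noise_variance
    )
    return mean, np.sqrt(np.maximum(var, 0.0))


class TestKernels:
    def test_zero_distance_gives_signal_variance(self, rng):
        x = rng.normal(size=4)
        assert matern32(x, x, sigma=1.7, l=2.0) == pytest.approx(1.7**2)
        assert matern32_ard(x, x, 1.7, np.ones(4)) == pytest.approx(1.7**2)

    def test_hand_evaluated_value(self):
        # r = 1/sqrt(3), l = 1: k = (1 + 1) * exp(-1)
        val = matern32([0.0], [1.0 / np.sqrt(3.0)], sigma=1.0, l=1.0)
        assert val == pytest.approx(2.0 * np.exp(-1.0), abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=3), rng.normal(size=3)
            l = rng.uniform(0.5, 3.0, size=3)
            assert matern32(a, b, 1.2, 0.8) == pytest.approx(
                matern32(b, a, 1.2, 0.8)
            )
            assert matern32_ard(a, b, 1.2, l) == pytest.approx(
                matern32_ard(b, a, 1.2, l)
            )

    def test_ard_reduces_to_isotropic_when_scales_equal(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert matern32_ard(a, b, 2.0, np.full(5, 1.3)) == pytest.approx(
            matern32(a, b, 2.0, 1.3)
        )

    def test_irrelevance_limit(self, rng):
        a = rng.normal(size=3)
        b = a.copy()
        b[1] += 5.0  # only feature 1 differs
        l = np.array([1.0, 1e9, 1.0])
        assert matern32_ard(a, b, 1.0, l) == pytest.approx(
            matern32_ard(a, a, 1.0, l), abs=1e-9
        )

    def test_termwise_scalar_oracle(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        l = rng.uniform(0.3, 2.0, size=5)
        r = np.sqrt(sum((a[m] - b[m]) ** 2 / l[m] ** 2 for m in range(5)))
        expected = 1.4**2 * (1 + np.sqrt(3) * r) * np.exp(-np.sqrt(3) * r)
        assert matern32_ard(a, b, 1.4, l) == pytest.approx(expected)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            matern32_ard([0.0, 1.0], [0.0, 1.0], 1.0, [1.0, 1.0, 1.0])

    def test_non_finite_input_raises(self):
        with pytest.raises(ValueError, match="finite"):
            matern32([np.inf], [0.0], 1.0, 1.0)

    def test_gram_symmetric_psd(self, rng):
        for _ in range(5):
            X = rng.normal(size=(25, 4))
            params = KernelParams(
                rng.uniform(0.5, 2.0), rng.uniform(0.3, 3.0, size=4)
            )
            K = kernel_matrix(X, X, params)
            assert np.allclose(K, K.T)
            assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestPosterior:
    def test_matches_direct_solve_oracle(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            X = r.normal(size=(50, 5))
            y = np.sin(X[:, 0]) + r.normal(size=50)
            Xs = r.normal(size=(10, 5))
            params = KernelParams(1.3, r.uniform(0.5, 2.0, size=5), 0.05)
            model = GaussianProcess(X, y)
            res = model.fit(params=params)
            mu, sd = res.predict(Xs)
            # oracle works on the standardized targets, as the model does
            mu_o, sd_o = closed_form_posterior(
                X, model.y, Xs, params
            )
            mu_o = mu_o * model.y_scale + model.y_mean
            sd_o = sd_o * model.y_scale
            assert np.allclose(mu, mu_o, atol=1e-8)
            assert np.allclose(sd, sd_o, atol=1e-8)

    def test_noise_free_interpolation(self, rng):
        X = rng.uniform(-2, 2, size=(5, 1))
        y = np.sin(X[:, 0])
        res = fit_gpr(X, y, fixed_noise=0.0, n_restarts=3, seed=0)
        mu, _ = res.predict(X)
        assert np.allclose(mu, y, atol=1e-6)

    def test_prior_reversion_far_from_data(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        params = KernelParams(1.5, np.full(3, 0.7), 0.2)
        res = GaussianProcess(X, y).fit(params=params)
        far = np.full((1, 3), 1e6)
        _, sd = res.predict(far)
        expected = np.sqrt(1.5**2 + 0.2)
        assert sd[0] / res.model.y_scale == pytest.approx(expected, rel=1e-6)

    def test_constant_targets(self):
        X = np.linspace(0, 1, 8).reshape(-1, 1)
        y = np.full(8, 3.5)
        res = fit_gpr(X, y, n_restarts=2, seed=0)
        mu, sd = res.predict(np.array([[0.5], [10.0]]))
        assert np.allclose(mu, 3.5, atol=1e-6)
        assert np.all(sd >= 0)

    def test_variance_never_increases_with_added_point(self, rng):
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        q = rng.normal(size=(1, 2))
        params = KernelParams(1.0, np.ones(2), 0.1)
        res0 = GaussianProcess(X, y).fit(params=params)
        _, sd0 = res0.predict(q, include_noise=False)
        X1 = np.vstack([X, q])
        y1 = np.append(y, 0.3)
        res1 = GaussianProcess(X1, y1).fit(params=params)
        _, sd1 = res1.predict(q, include_noise=False)
        # compare on the standardized scale to cancel y-standardization
        assert (
            sd1[0] / res1.model.y_scale
            <= sd0[0] / res0.model.y_scale + 1e-9
        )

    def test_column_mismatch_named(self, rng):
        import pandas as pd

        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["u", "v"])
        res = fit_gpr(X, rng.normal(size=10), n_restarts=1, seed=0)
        bad = X.rename(columns={"v": "w"})
        with pytest.raises(ValueError, match="w"):
            res.predict(bad)


class TestFitting:
    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=30)
        r1 = fit_gpr(X, y, n_restarts=3, seed=7)
        r2 = fit_gpr(X, y, n_restarts=3, seed=7)
        assert np.array_equal(r1.params.length_scales, r2.params.length_scales)
        assert r1.params.signal_amplitude == r2.params.signal_amplitude
        assert r1.llf == r2.llf

    def test_ard_recovers_active_features(self):
        # 2 active (small true length scale), 3 inert (huge): fitted
        # inverse-length-scale ranking should put the active pair first
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(200 + seed)
            X = r.normal(size=(120, 5))
            y = np.sin(1.5 * X[:, 0]) + np.cos(1.5 * X[:, 1]) + 0.05 * r.normal(size=120)
            res = fit_gpr(X, y, n_restarts=2, seed=seed, maxiter=150)
            top2 = set(np.argsort(res.params.length_scales)[:2])
            hits += top2 == {0, 1}
        assert hits >= 8

    def test_loglike_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = GaussianProcess(X, y)
        theta = np.array([0.2, 0.1, -0.3, 0.4, np.log(0.2)])
        ll, grad = model.loglike_and_grad(theta)
        eps = 1e-6
        for j in range(len(theta)):
            tp = theta.copy()
            tp[j] += eps
            lp, _ = model.loglike_and_grad(tp)
            tm = theta.copy()
            tm[j] -= eps
            lm, _ = model.loglike_and_grad(tm)
            assert grad[j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-6)

    def test_agrees_with_sklearn_at_fixed_hyperparameters(self, rng):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, Matern

        X = rng.normal(size=(40, 3))
        y = np.sin(X[:, 0]) + 0.2 * rng.normal(size=40)
        ls = np.array([0.8, 1.5, 3.0])
        params = KernelParams(1.2, ls, noise_variance=0.1, jitter=0.0)
        model = GaussianProcess(X, y, jitter=0.0)
        res = model.fit(params=params)
        Xs = rng.normal(size=(8, 3))
        mu, sd = res.predict(Xs, include_noise=False)

        sk = GaussianProcessRegressor(
            kernel=ConstantKernel(1.2**2, "fixed")
            * Matern(length_scale=ls, nu=1.5, length_scale_bounds="fixed"),
            alpha=0.1,
            optimizer=None,
            normalize_y=False,
        ).fit(X, model.y)
        mu_sk, sd_sk = sk.predict(Xs, return_std=True)
        assert np.allclose(mu, mu_sk * model.y_scale + model.y_mean, atol=1e-8)
        assert np.allclose(sd, sd_sk * model.y_scale, atol=1e-8)

    def test_serialization_round_trip(self, tmp_path, rng):
        from stabgp.gpr import GPResults

        X = rng.normal(size=(20, 2))
        y = rng.normal(size=20)
        res = fit_gpr(X, y, n_restarts=2, seed=0)
        path = tmp_path / "model.json"
        res.save(path)
        back = GPResults.load(path)
        Xs = rng.normal(size=(5, 2))
        mu1, sd1 = res.predict(Xs)
        mu2, sd2 = back.predict(Xs)
        assert np.allclose(mu1, mu2) and np.allclose(sd1, sd2)

    def test_summary_mentions_fit_quality(self, rng):
        X = rng.normal(size=(15, 2))
        res = fit_gpr(X, rng.normal(size=15), n_restarts=1, seed=0)
        text = res.summary()
        assert "Log marginal lik." in text and "Length scales" in text
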