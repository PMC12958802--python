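"""Tests of the multi-kernel Gibbs sampler against closed-form oracles."""

import numpy as np
import pytest

from gpkern.exceptions import EstimationError, InvalidConfigError, RecordLookupError
from gpkern.kernels import KernelMatrix, identity_kernel, linear_kernel
from gpkern.rkhs import ChainConfig, MultiKernelRKHS, fit_multikernel


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(17)
    n, p = 100, 60
    X = rng.normal(size=(n, p))
    K = linear_kernel(X)
    L = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
    g = L @ rng.standard_normal(n)
    y = g + np.sqrt(0.5) * rng.standard_normal(n)
    return X, K, y


class TestChainConfig:
    def test_default_retained_count(self):
        assert ChainConfig().n_retained == 2000

    def test_invalid_settings_rejected(self):
        with pytest.raises(InvalidConfigError):
            ChainConfig(n_iter=100, burnin=100)
        with pytest.raises(InvalidConfigError):
            ChainConfig(thin=0)


class TestBlupEquivalence:
    def test_fixed_variances_match_closed_form(self, linear_data):
        X, K, y = linear_data
        n = y.size
        model = MultiKernelRKHS(y, {"g": K})
        res = model.fit(n_iter=4000, burnin=1000, thin=2, seed=3,
                        fixed_variances={"g": 1.0, "residual": 0.5}, fixed_mu=0.0)
        lam = 0.5 / 1.0
        blup = K.values @ np.linalg.solve(K.values + lam * np.eye(n), y)
        pred, se = res.predict(with_se=True)
        d = np.abs(pred - blup)
        assert np.mean(d <= 3 * se + 1e-9) >= 0.97  # ~99.7% expected per record
        assert np.all(d <= 4.5 * se + 1e-9)

    def test_matches_marker_ridge_regression(self, linear_data):
        # gBLUP with a linear kernel of codings == ridge regression on the
        # markers themselves (rrBLUP equivalence), via an independent
        # scikit-learn oracle
        from sklearn.linear_model import Ridge

        X, K, y = linear_data
        n = y.size
        c = np.trace(X @ X.T) / n  # kernel normalization constant
        sig2_g, sig2_e = 1.0, 0.5
        lam_marker = sig2_e / (sig2_g / c)
        ridge = Ridge(alpha=lam_marker, fit_intercept=False, solver="cholesky")
        ridge.fit(X, y)
        oracle = X @ ridge.coef_
        model = MultiKernelRKHS(y, {"g": K})
        res = model.fit(n_iter=4000, burnin=1000, thin=2, seed=4,
                        fixed_variances={"g": sig2_g, "residual": sig2_e}, fixed_mu=0.0)
        pred, se = res.predict(with_se=True)
        d = np.abs(pred - oracle)
        assert np.mean(d <= 3 * se + 1e-9) >= 0.97
        assert np.all(d <= 4.5 * se + 1e-9)


class TestSamplerBehavior:
    def test_retained_draw_count(self, linear_data):
        X, K, y = linear_data
        res = fit_multikernel(y, {"g": K}, n_iter=300, burnin=100, thin=5, seed=0)
        assert res.n_retained == ChainConfig(300, 100, 5).n_retained

    def test_noise_shrinks_kernel_variance(self):
        rng = np.random.default_rng(5)
        n = 300
        X = rng.normal(size=(n, 100))
        K = linear_kernel(X)
        y = rng.standard_normal(n)  # pure noise
        # weak variance priors so the likelihood dominates
        res = MultiKernelRKHS(y, {"g": K}, prior_df=2.0).fit(
            n_iter=2000, burnin=500, thin=2, seed=1
        )
        ratio = np.median(res.sig2_draws["g"] / res.sig2_e_draws)
        assert ratio < 0.2

    def test_kernel_order_does_not_change_predictions(self, linear_data):
        X, K, y = linear_data
        K2 = identity_kernel(y.size, labels=K.labels)
        res_ab = fit_multikernel(
            y, {"a": K, "b": K2}, n_iter=3000, burnin=1000, thin=2, seed=9
        )
        res_ba = fit_multikernel(
            y, {"b": K2, "a": K}, n_iter=3000, burnin=1000, thin=2, seed=9
        )
        pa, sa = res_ab.predict(with_se=True)
        pb, sb = res_ba.predict(with_se=True)
        comb = np.sqrt(sa**2 + sb**2)
        assert np.all(np.abs(pa - pb) <= 3 * comb + 1e-9)

    def test_different_seeds_agree_statistically(self, linear_data):
        X, K, y = linear_data
        r1 = fit_multikernel(y, {"g": K}, n_iter=3000, burnin=1000, thin=2, seed=21)
        r2 = fit_multikernel(y, {"g": K}, n_iter=3000, burnin=1000, thin=2, seed=22)
        p1, s1 = r1.predict(with_se=True)
        p2, s2 = r2.predict(with_se=True)
        assert np.mean(np.abs(p1 - p2) <= 3 * np.sqrt(s1**2 + s2**2)) > 0.97


class TestPrediction:
    def test_near_interpolation_with_tiny_residual(self):
        # full-rank kernel (p > n) so the prior can interpolate the data
        rng = np.random.default_rng(12)
        X = rng.normal(size=(60, 150))
        K = linear_kernel(X)
        y = rng.standard_normal(60)
        res = MultiKernelRKHS(y, {"g": K}).fit(
            n_iter=1500, burnin=500, thin=2, seed=2,
            fixed_variances={"g": 5.0, "residual": 1e-4}, fixed_mu=0.0,
        )
        pred = res.predict()
        assert np.max(np.abs(pred - y)) < 0.1

    def test_constant_kernel_predicts_posterior_mean(self):
        rng = np.random.default_rng(8)
        y = rng.normal(loc=2.0, size=50)
        ones = KernelMatrix(np.ones((50, 50)), list(range(50)), "linear")
        res = fit_multikernel(y, {"c": ones}, n_iter=1000, burnin=200, thin=2, seed=0)
        pred = res.predict()
        assert np.ptp(pred) < 1e-8  # all predictions identical

    def test_unknown_record_raises(self, linear_data):
        X, K, y = linear_data
        res = fit_multikernel(y, {"g": K}, n_iter=300, burnin=100, thin=2, seed=0)
        with pytest.raises(RecordLookupError):
            res.predict(["no-such-record"])

    def test_test_records_excluded_from_likelihood(self, linear_data):
        # corrupting test-partition responses must not change training fit
        X, K, y = linear_data
        mask = np.ones(y.size, dtype=bool)
        mask[80:] = False
        y_bad = y.copy()
        y_bad[80:] = 1e6
        r_good = MultiKernelRKHS(y, {"g": K}, train_mask=mask).fit(
            n_iter=800, burnin=200, thin=2, seed=6
        )
        r_bad = MultiKernelRKHS(y_bad, {"g": K}, train_mask=mask).fit(
            n_iter=800, burnin=200, thin=2, seed=6
        )
        np.testing.assert_allclose(
            r_good.predict()[:80], r_bad.predict()[:80], atol=1e-10
        )


class TestVarianceComponents:
    def test_proportions_sum_to_one(self, linear_data):
        X, K, y = linear_data
        res = fit_multikernel(
            y, {"g": K, "e2": identity_kernel(y.size, labels=K.labels)},
            n_iter=600, burnin=200, thin=2, seed=0,
        )
        comp = dict(res.sig2_draws)
        comp["residual"] = res.sig2_e_draws
        total = sum(comp.values())
        props = np.array([(v / total) for v in comp.values()])
        np.testing.assert_allclose(props.sum(axis=0), 1.0, atol=1e-12)

    def test_balanced_recovery(self):
        rng = np.random.default_rng(30)
        n = 400
        X = rng.normal(size=(n, 80))
        K = linear_kernel(X)
        L = np.linalg.cholesky(K.values + 1e-10 * np.eye(n))
        y = L @ rng.standard_normal(n) + rng.standard_normal(n)  # 1:1 variance
        res = fit_multikernel(y, {"g": K}, n_iter=2500, burnin=500, thin=2, seed=2)
        prop = res.variance_components().loc["g", "proportion"]
        assert 0.35 <= prop <= 0.65

    def test_empty_draws_error(self, linear_data):
        X, K, y = linear_data
        res = fit_multikernel(y, {"g": K}, n_iter=300, burnin=100, thin=2, seed=0)
        res.mu_draws = res.mu_draws[:0]
        with pytest.raises(EstimationError):
            res.variance_components()

    def test_summary_mentions_chain_settings(self, linear_data):
        X, K, y = linear_data
        res = fit_multikernel(y, {"g": K}, n_iter=300, burnin=100, thin=2, seed=0)
        text = res.summary()
        assert "burn-in 100" in text and "g" in text
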