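import numpy as np
import pytest
from scipy import stats

from farmsustain import tobit
from farmsustain.synthetic import simulate_tobit


@pytest.fixture(scope="module")
def censored_fit():
    y, X = simulate_tobit(400, beta=[0.8, -0.2, 0.15], sigma=0.15, seed=11)
    return tobit.fit(y, X), y, X


class TestFit:
    def test_uncensored_limit_equals_ols(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 0.5 + 0.05 * X[:, 1] + 0.02 * rng.normal(size=n)  # far from both limits
        fit = tobit.fit(y, X)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma_mle = np.sqrt(np.mean((y - X @ beta_ols) ** 2))
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)
        assert fit.sigma == pytest.approx(sigma_mle, abs=1e-6)
        assert fit.n_left == fit.n_right == 0

    def test_loglik_improves_on_warm_start(self, censored_fit):
        fit, y, X = censored_fit
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma0 = np.sqrt(np.mean((y - X @ beta0) ** 2))
        masks = (
            (y > 1e-9) & (y < 1 - 1e-9),
            y <= 1e-9,
            y >= 1 - 1e-9,
        )
        nll0, _ = tobit._neg_loglik_and_grad(
            np.concatenate([beta0, [np.log(sigma0)]]), y, X, 0.0, 1.0, masks
        )
        assert fit.log_likelihood >= -nll0

    def test_censoring_bookkeeping_is_exact(self, censored_fit):
        fit, y, _ = censored_fit
        assert fit.n_right == int((y >= 1 - 1e-9).sum())
        assert fit.n_left == int((y <= 1e-9).sum())
        assert fit.n_uncensored + fit.n_left + fit.n_right == y.size

    def test_parameter_recovery(self):
        beta_true = np.array([0.8, -0.2, 0.15])
        est = []
        for seed in range(60):
            y, X = simulate_tobit(500, beta_true, sigma=0.15, seed=seed)
            est.append(tobit.fit(y, X).beta)
        np.testing.assert_allclose(np.mean(est, axis=0), beta_true, atol=0.02)

    def test_recovery_improves_with_sample_size(self):
        beta_true = np.array([0.8, -0.2, 0.15])
        rmse = {}
        for n in (100, 2000):
            errs = [
                tobit.fit(*simulate_tobit(n, beta_true, 0.15, seed=s)[::1]).beta - beta_true
                for s in range(25)
            ]
            rmse[n] = np.sqrt(np.mean(np.square(errs)))
        assert rmse[2000] < rmse[100]

    def test_binary_recoding_equivalence(self, rng):
        # Flipping a 0/1 dummy is a reparameterization: same log-likelihood.
        n = 150
        d = (rng.random(n) < 0.5).astype(float)
        X = np.column_stack([np.ones(n), d])
        y = np.clip(0.7 + 0.2 * d + 0.1 * rng.normal(size=n), 0, 1)
        f1 = tobit.fit(y, X)
        f2 = tobit.fit(y, np.column_stack([np.ones(n), 1 - d]))
        assert f1.log_likelihood == pytest.approx(f2.log_likelihood, abs=1e-6)
        assert f1.beta[1] == pytest.approx(-f2.beta[1], abs=1e-5)

    def test_rank_deficiency_names_columns(self, rng):
        n = 50
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(ValueError, match="offending"):
            tobit.fit(np.clip(0.5 + 0.1 * x, 0, 1), X, names=("const", "x", "dup"))

    def test_all_censored_rejected(self):
        X = np.ones((20, 1))
        with pytest.raises(ValueError):
            tobit.fit(np.ones(20), X)


class TestMarginalEffects:
    def test_common_ratio_identity(self, censored_fit):
        fit, _, X = censored_fit
        ratios = fit.ames[1:] / fit.beta[1:]
        np.testing.assert_allclose(ratios, fit.uncensored_share, rtol=1e-12)
        assert 0 < fit.uncensored_share <= 1

    def test_uncensored_limit_ame_equals_beta(self, rng):
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = 0.5 + 0.05 * X[:, 1] + 0.02 * rng.normal(size=n)
        fit = tobit.fit(y, X)
        assert fit.ames[1] == pytest.approx(fit.beta[1], rel=1e-6)

    def test_matches_finite_difference_of_censored_expectation(self, censored_fit):
        fit, _, X = censored_fit
        ame = tobit.average_marginal_effects(fit, X)
        eps = 1e-6
        X_hi, X_lo = X.copy(), X.copy()
        X_hi[:, 1] += eps
        X_lo[:, 1] -= eps
        fd = np.mean(
            tobit._censored_expectation(fit, X_hi) - tobit._censored_expectation(fit, X_lo)
        ) / (2 * eps)
        assert ame[1] == pytest.approx(fd, abs=1e-5)

    def test_discrete_ame_for_dummy(self, rng):
        n = 300
        d = (rng.random(n) < 0.5).astype(float)
        X = np.column_stack([np.ones(n), d])
        y = np.clip(0.7 + 0.2 * d + 0.1 * rng.normal(size=n), 0, 1)
        fit = tobit.fit(y, X)
        dd = tobit.discrete_ames(fit, X, column=1)
        assert np.sign(dd) == np.sign(fit.beta[1])
        assert abs(dd) <= abs(fit.beta[1]) + 1e-9


class TestLRTest:
    def test_identical_models_give_zero(self, censored_fit):
        fit, *_ = censored_fit
        res = tobit.lr_test(fit, fit)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == 1.0

    def test_size_under_null(self):
        rejections = 0
        n_sim = 400
        for seed in range(n_sim):
            y, X = simulate_tobit(100, beta=[0.7, 0.0, 0.0], sigma=0.15, seed=10_000 + seed)
            full = tobit.fit(y, X)
            null = tobit.fit(y, X[:, :1])
            if tobit.lr_test(full, null).p_value < 0.05:
                rejections += 1
        assert 0.025 <= rejections / n_sim <= 0.08

    def test_power_under_alternative(self):
        hits = 0
        for seed in range(30):
            y, X = simulate_tobit(500, beta=[0.8, -0.2, 0.15], sigma=0.15, seed=seed)
            full = tobit.fit(y, X)
            null = tobit.fit(y, X[:, :1])
            if tobit.lr_test(full, null).p_value < 0.01:
                hits += 1
        assert hits >= 29  # >= 95% of seeds

    def test_different_samples_rejected(self, censored_fit):
        fit, _, X = censored_fit
        y2, X2 = simulate_tobit(100, [0.8, -0.2, 0.15], 0.15, seed=99)
        with pytest.raises(ValueError):
            tobit.lr_test(fit, tobit.fit(y2, X2[:, :1]))


class TestDiagnostics:
    def test_vif_orthogonal_regressors(self):
        n = 64
        t = np.arange(n)
        X = np.column_stack([np.ones(n), np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n)])
        vifs = tobit.vif(X)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in vifs.values())

    def test_vif_closed_form_for_correlated_pair(self, rng):
        # Construct two regressors with sample correlation exactly 0.8.
        n = 500
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
        b /= b.std()
        x2 = 0.8 * a + np.sqrt(1 - 0.64) * b
        X = np.column_stack([np.ones(n), a, x2])
        vifs = tobit.vif(X)
        assert vifs["x1"] == pytest.approx(1 / (1 - 0.64), abs=1e-6)

    def test_vif_duplicate_column_flagged_infinite(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([np.ones(100), x, x])
        vifs = tobit.vif(X)
        assert np.isinf(list(vifs.values())).any()

    def test_white_constant_residuals(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        res = tobit.white_test(np.full(50, 0.3), X)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)

    def test_white_matches_statsmodels(self, rng):
        import statsmodels.stats.diagnostic as smd

        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        e = rng.normal(size=n)
        ours = tobit.white_test(e, X)
        lm, lm_p, _, _ = smd.het_white(e, X)
        assert ours.statistic == pytest.approx(lm, abs=1e-6)
        assert ours.p_value == pytest.approx(lm_p, abs=1e-6)

    def test_white_size_under_homoskedasticity(self, rng):
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            n = 100
            X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
            e = rng.normal(size=n)
            if tobit.white_test(e, X).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.08

    def test_white_power_against_variance_in_regressor(self, rng):
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            n = 500
            x = rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            e = rng.normal(size=n) * np.sqrt(0.2 + x**2)
            if tobit.white_test(e, X).p_value < 0.05:
                hits += 1
        assert hits / n_sim >= 0.8
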