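import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit, logit

from bayesdr import (
    ModelSpec,
    ObservationalDataset,
    SeparationError,
    Term,
    fit_outcome,
    fit_propensity,
    kappa_weights,
    predict_counterfactual,
)
from bayesdr.component_models import batched_wls
from bayesdr.simulation_study import DGPParams, generate_sim_dataset

OR_FULL = ModelSpec("identity", ("x",))
PS_SPEC = ModelSpec("logit", ("x",), include_treatment=False)


class TestKappaWeights:
    @pytest.mark.parametrize(
        "d, ps, expected",
        [(1, 0.5, 2.0), (0, 0.2, 1.25), (1, 0.98, 1 / 0.98)],
    )
    def test_arithmetic(self, d, ps, expected):
        out = kappa_weights(np.array([ps]), np.array([d]))
        np.testing.assert_allclose(out, [expected], rtol=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            kappa_weights(np.array([0.0, 0.5]), np.array([1, 0]))

    def test_horvitz_thompson_mass_balance(self):
        # with calibrated scores, kappa puts mass ~n on each arm
        params = DGPParams(n=10_000)
        data = generate_sim_dataset(params, np.random.default_rng(3))
        ps = expit(params.alpha0 + params.alpha1 * data.X[:, 0])
        kap = kappa_weights(ps, data.d)
        assert np.isclose((kap * data.d).sum(), data.n, rtol=0.05)
        assert np.isclose((kap * (1 - data.d)).sum(), data.n, rtol=0.05)


class TestFitOutcome:
    def test_exact_linear_interpolation(self, toy_linear):
        fit = fit_outcome(toy_linear, OR_FULL)
        np.testing.assert_allclose(fit.xi, [1.0, 2.0, 3.0], atol=1e-10)
        assert fit.ee_residual < 1e-8

    def test_weight_scale_invariance(self, dgp_dataset):
        w = np.random.default_rng(0).uniform(0.5, 2.0, dgp_dataset.n)
        f1 = fit_outcome(dgp_dataset, OR_FULL, w)
        f2 = fit_outcome(dgp_dataset, OR_FULL, 17.3 * w)
        np.testing.assert_allclose(f1.xi, f2.xi, rtol=1e-10)

    def test_matches_closed_form_wls_oracle(self, dgp_dataset):
        w = np.random.default_rng(1).uniform(0.2, 5.0, dgp_dataset.n)
        fit = fit_outcome(dgp_dataset, OR_FULL, w)
        D = np.column_stack(
            [np.ones(dgp_dataset.n), dgp_dataset.d, dgp_dataset.X[:, 0]]
        )
        oracle = np.linalg.solve((D * w[:, None]).T @ D, D.T @ (w * dgp_dataset.y))
        np.testing.assert_allclose(fit.xi, oracle, atol=1e-8)
        sm_fit = sm.WLS(dgp_dataset.y, D, weights=w).fit()
        np.testing.assert_allclose(fit.xi, sm_fit.params, atol=1e-8)

    def test_batched_wls_rows_match_single_fits(self, dgp_dataset):
        rng = np.random.default_rng(2)
        W = rng.uniform(0.2, 3.0, (4, dgp_dataset.n))
        D = np.column_stack(
            [np.ones(dgp_dataset.n), dgp_dataset.d, dgp_dataset.X[:, 0]]
        )
        batch = batched_wls(D, dgp_dataset.y, W)
        for l in range(4):
            single = fit_outcome(dgp_dataset, OR_FULL, W[l]).xi
            np.testing.assert_allclose(batch[l], single, atol=1e-8)

    def test_log_link_closed_form(self):
        # y generated exactly as exp(0.5 + 0.3 x): quasi fit recovers it
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        d = (rng.random(200) < 0.5).astype(int)
        d[:2] = [0, 1]
        y = np.exp(0.5 + 0.3 * x)
        data = ObservationalDataset(y, d, x[:, None], ("x",))
        fit = fit_outcome(data, ModelSpec("log", ("x",), include_treatment=False))
        np.testing.assert_allclose(fit.xi, [0.5, 0.3], atol=1e-6)

    def test_kappa_weighting_corrects_omitted_covariate_bias(self):
        # DR property at the fit level: the X-omitting model weighted by
        # kappa from the true assignment mechanism centres on the true effect
        params = DGPParams(n=1000)
        no_x = ModelSpec("identity", ())
        biased, corrected = [], []
        rng = np.random.default_rng(5)
        for _ in range(50):
            data = generate_sim_dataset(params, rng)
            ps = expit(params.alpha0 + params.alpha1 * data.X[:, 0])
            kap = kappa_weights(ps, data.d)
            biased.append(fit_outcome(data, no_x).xi[1])
            corrected.append(fit_outcome(data, no_x, kap).xi[1])
        biased, corrected = np.array(biased), np.array(corrected)
        se = corrected.std(ddof=1) / np.sqrt(len(corrected))
        assert abs(corrected.mean() - 5.0) < 2 * max(se, biased.std(ddof=1) / 7)
        assert abs(biased.mean() - 5.0) > 3 * abs(corrected.mean() - 5.0)


class TestFitPropensity:
    def test_null_model_recovers_marginal_rate(self):
        rng = np.random.default_rng(6)
        n = 20_000
        x = rng.normal(size=n)
        d = (rng.random(n) < 0.3).astype(int)  # independent of x
        data = ObservationalDataset(rng.normal(size=n), d, x[:, None], ("x",))
        fit = fit_propensity(data, PS_SPEC)
        assert abs(fit.alpha[1]) < 0.05
        assert np.isclose(fit.alpha[0], logit(d.mean()), atol=0.05)

    def test_recovers_assignment_coefficients_large_n(self):
        params = DGPParams(n=100_000)
        data = generate_sim_dataset(params, np.random.default_rng(8))
        fit = fit_propensity(data, PS_SPEC)
        np.testing.assert_allclose(fit.alpha, [2.0, 0.2], atol=0.06)

    def test_matches_statsmodels_weighted_logit(self, dgp_dataset):
        w = np.random.default_rng(9).uniform(0.5, 2.0, dgp_dataset.n)
        fit = fit_propensity(dgp_dataset, PS_SPEC, unit_weights=w, clip_eps=0.0)
        Z = np.column_stack([np.ones(dgp_dataset.n), dgp_dataset.X[:, 0]])
        oracle = sm.GLM(
            dgp_dataset.d, Z, family=sm.families.Binomial(), var_weights=w
        ).fit()
        np.testing.assert_allclose(fit.alpha, oracle.params, atol=1e-6)

    def test_perfect_separation_raises(self):
        x = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        d = (x > 0).astype(int)
        data = ObservationalDataset(np.zeros(6), d, x[:, None], ("x",))
        with pytest.raises(SeparationError):
            fit_propensity(data, PS_SPEC)

    def test_clipping_bounds_fitted_scores(self):
        params = DGPParams(alpha0=4.0, alpha1=1.5, n=2000)
        data = generate_sim_dataset(params, np.random.default_rng(10))
        fit = fit_propensity(data, PS_SPEC, clip_eps=0.01)
        assert fit.fitted_ps.min() >= 0.01 and fit.fitted_ps.max() <= 0.99


class TestPredictCounterfactual:
    def test_identity_arithmetic(self, toy_linear):
        fit = fit_outcome(toy_linear, OR_FULL)
        out = predict_counterfactual(fit, np.array([[4.0]]), 1)
        np.testing.assert_allclose(out, [15.0], atol=1e-9)

    def test_identity_contrast_is_treatment_coefficient(self, toy_linear):
        fit = fit_outcome(toy_linear, OR_FULL)
        X = np.linspace(-5, 5, 11)[:, None]
        diff = predict_counterfactual(fit, X, 1) - predict_counterfactual(fit, X, 0)
        np.testing.assert_allclose(diff, 2.0, atol=1e-9)

    def test_log_link_closed_form(self, toy_linear):
        fit = fit_outcome(toy_linear, ModelSpec("log", ("x",)))
        fit.xi = np.array([0.0, np.log(2.0), 0.0])
        out = predict_counterfactual(fit, np.array([[7.0], [-1.0]]), 1)
        np.testing.assert_allclose(out, [2.0, 2.0], rtol=1e-12)


class TestSmoothTerms:
    def test_smooth_outcome_recovers_nonlinear_signal(self):
        rng = np.random.default_rng(11)
        n = 800
        x = rng.uniform(-3, 3, n)
        d = (rng.random(n) < 0.5).astype(int)
        y = 2.0 * d + np.sin(1.5 * x) + rng.normal(0, 0.2, n)
        data = ObservationalDataset(y, d, x[:, None], ("x",))
        spec = ModelSpec("identity", (Term("x", "smooth", 10),))
        fit = fit_outcome(data, spec)
        assert abs(fit.xi[1] - 2.0) < 0.1  # treatment coefficient
        resid = data.y - fit.predict(data.X, data.d)
        assert resid.std() < 0.3  # captured the sinusoid, not just the mean

    def test_smooth_propensity_fit_runs_and_is_calibrated(self):
        data = generate_sim_dataset(DGPParams(n=3000), np.random.default_rng(12))
        spec = ModelSpec("logit", (Term("x", "smooth", 8),), include_treatment=False)
        fit = fit_propensity(data, spec)
        assert np.isclose(fit.fitted_ps.mean(), data.d.mean(), atol=0.02)
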