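import numpy as np
import pytest
from scipy import optimize, special

from mixedlink.inference import (
    ParameterizedModel,
    _initial_theta,
    category_probs,
    fit_mle,
    linear_predictor,
    log_likelihood,
    wald_inference,
)
from mixedlink.model import ModelSpec, SampleTable

from conftest import simulate_table


class TestLinearPredictor:
    def test_reference_model_intercepts_at_zero_covariate(self, risk_model):
        spec, theta = risk_model
        eta = linear_predictor(spec, theta, [[0.0]])
        np.testing.assert_allclose(eta, [[4.023, 4.905]], atol=1e-12)

    def test_zero_theta_gives_zero(self):
        spec = ModelSpec("adjacent", ("logit", "probit"), "npo", d=2)
        eta = linear_predictor(spec, np.zeros(6), [[3.0, -1.0]])
        np.testing.assert_array_equal(eta, [[0.0, 0.0]])

    def test_atrophy_model_dummy_sum(self):
        # adjacent po logit with tnsc + 4 atrophy dummies; the
        # negative-atrophy setting adds its coefficient to both intercepts
        spec = ModelSpec("adjacent", ("logit", "logit"), "po", d=5)
        theta = np.array([-1.859, 0.136, -4.586e-4, -1.144, -2.103, 6.469, 3.663])
        x = [[0.0, 0.0, 0.0, 1.0, 0.0]]
        np.testing.assert_allclose(
            linear_predictor(spec, theta, x),
            [[-1.859 + 6.469, 0.136 + 6.469]],
            atol=1e-12,
        )

    def test_dimension_mismatch_rejected(self, risk_model):
        spec, theta = risk_model
        with pytest.raises(ValueError):
            linear_predictor(spec, theta, [[1.0, 2.0]])


class TestCategoryProbs:
    def test_reference_model_closed_form(self, risk_model):
        # at tnsc = 9515.38 the first linear predictor is ~0, so
        # pi_1 ~ exp(-1); oracle is the direct closed-form composition
        spec, theta = risk_model
        x = 9515.38
        eta1 = 4.023 - 4.228e-4 * x
        eta2 = 4.905 - 4.228e-4 * x
        rho1 = np.exp(-np.exp(-eta1))
        rho2 = special.expit(eta2)
        oracle = [rho1, rho2 - rho1, 1.0 - rho2]
        pi = category_probs(spec, theta, [[x]])
        np.testing.assert_allclose(pi[0], oracle, atol=1e-12)
        np.testing.assert_allclose(pi[0], [0.3679, 0.3394, 0.2927], atol=2e-4)

    def test_zero_theta_baseline_uniform(self):
        spec = ModelSpec("baseline", ("logit", "logit"), "npo", d=1)
        pi = category_probs(spec, np.zeros(4), [[123.0]])
        np.testing.assert_allclose(pi, [[1 / 3, 1 / 3, 1 / 3]], atol=1e-12)

    @pytest.mark.parametrize("structure", ["baseline", "cumulative", "adjacent", "continuation"])
    def test_all_logit_matches_classical_models(self, structure):
        # with every link logit the mixed-link model reduces to the
        # classical multinomial logit family; independent closed forms
        rng = np.random.default_rng(5)
        # equal slopes keep the cumulative curves from crossing
        theta = np.array([0.3, 0.9, -0.25, -0.25])
        spec = ModelSpec(structure, ("logit", "logit"), "npo", d=1)
        X = rng.normal(size=(50, 1))
        eta = theta[[0, 1]] + X * theta[[2, 3]]
        pi = category_probs(spec, theta, X)
        np.testing.assert_allclose(pi, _classical_pi(structure, eta), atol=1e-10)


def _classical_pi(structure, eta):
    """The traditional multinomial logit models, coded independently."""
    e = np.exp(eta)
    if structure == "baseline":
        denom = 1.0 + e.sum(axis=1, keepdims=True)
        return np.column_stack([e / denom, 1.0 / denom[:, 0]])
    if structure == "cumulative":
        gam = special.expit(eta)
        return np.column_stack([gam[:, 0], gam[:, 1] - gam[:, 0], 1.0 - gam[:, 1]])
    if structure == "adjacent":
        # pi_j / pi_{j+1} = exp(eta_j)
        unnorm = np.column_stack([e[:, 0] * e[:, 1], e[:, 1], np.ones(len(e))])
        return unnorm / unnorm.sum(axis=1, keepdims=True)
    haz = special.expit(eta)
    p1 = haz[:, 0]
    p2 = haz[:, 1] * (1 - p1)
    return np.column_stack([p1, p2, 1.0 - p1 - p2])


class TestLogLikelihood:
    def test_single_sample_is_log_prob(self, risk_model):
        spec, theta = risk_model
        data = SampleTable([[9515.38]], [[1, 0, 0]])
        pi = category_probs(spec, theta, [[9515.38]])[0, 0]
        assert log_likelihood(spec, theta, data) == pytest.approx(np.log(pi), abs=1e-12)

    def test_matches_naive_double_loop(self, small_table):
        spec = ModelSpec("continuation", ("probit", "cloglog"), "npo", d=1)
        theta = np.array([1.2, 0.8, -1e-4, -2e-4])
        pi = category_probs(spec, theta, small_table.X)
        naive = 0.0
        for i in range(small_table.m):
            for j in range(small_table.J):
                naive += small_table.Y[i, j] * np.log(pi[i, j])
        assert log_likelihood(spec, theta, small_table) == pytest.approx(naive, abs=1e-10)

    def test_individual_level_loglik_is_negative(self, risk_model, small_table):
        spec, theta = risk_model
        assert log_likelihood(spec, theta, small_table) < 0.0

    def test_infeasible_theta_gives_minus_inf(self):
        # decreasing cumulative intercepts cross the rho ordering
        spec = ModelSpec("cumulative", ("logit", "logit"), "npo", d=1)
        data = SampleTable([[1.0]], [[1, 1, 1]])
        assert log_likelihood(spec, np.array([1.0, -1.0, 0.0, 0.0]), data) == -np.inf


class TestFitMLE:
    def test_intercept_only_recovers_frequencies(self):
        counts = np.array([[30, 40, 54]], dtype=float)
        data = SampleTable(np.zeros((1, 0)), counts)
        spec = ModelSpec("baseline", ("logit", "logit"), "npo")
        fit = fit_mle(spec, data)
        freq = counts[0] / counts.sum()
        np.testing.assert_allclose(fit.predict_proba(np.zeros((1, 0)))[0], freq, atol=1e-8)
        assert fit.loglik == pytest.approx(float(np.sum(counts * np.log(freq))), abs=1e-8)

    @pytest.mark.parametrize("structure", ["baseline", "cumulative", "adjacent", "continuation"])
    @pytest.mark.parametrize("odds", ["po", "npo"])
    def test_matches_derivative_free_optimizer(self, structure, odds, risk_model):
        # 30-row instances: scoring optimum vs Nelder-Mead on the same
        # likelihood from the same start, loglik within 1e-6
        gspec, gtheta = risk_model
        data = simulate_table(gspec, gtheta, n=30, seed=23)
        spec = ModelSpec(structure, ("logit", "logit"), odds, d=1)
        fit = fit_mle(spec, data)

        def neg(th):
            v = log_likelihood(spec, th, data)
            return np.inf if not np.isfinite(v) else -v

        res = optimize.minimize(
            neg, _initial_theta(spec.with_d(1), data), method="Nelder-Mead",
            options={"maxiter": 5000, "xatol": 1e-10, "fatol": 1e-12},
        )
        assert fit.loglik >= -res.fun - 1e-6

    def test_all_logit_agrees_with_statsmodels_mnlogit(self, small_table):
        sm = pytest.importorskip("statsmodels.api")
        spec = ModelSpec("baseline", ("logit", "logit"), "npo", d=1)
        # same data, covariate rescaled identically for both routes
        X = small_table.X / 1000.0
        data = SampleTable(X, small_table.Y)
        fit = fit_mle(spec, data)
        labels = np.argmax(small_table.Y, axis=1)
        ref = sm.MNLogit(labels, sm.add_constant(X)).fit(disp=0, method="newton")
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-5)

    def test_likelihood_trace_is_monotone(self, small_table):
        spec = ModelSpec("cumulative", ("loglog", "logit"), "po", d=1)
        fit = fit_mle(spec, small_table)
        trace = np.asarray(fit.ll_trace)
        assert np.all(np.diff(trace) >= -1e-9 * np.maximum(1.0, np.abs(trace[:-1])))
        assert fit.converged

    def test_slope_recovery_and_significance(self, risk_model):
        spec, theta = risk_model
        data = simulate_table(spec, theta, n=10000, seed=31)
        fit = fit_mle(spec, data)
        se = fit.se()[2]
        assert abs(fit.theta[2] - theta[2]) < 3 * se
        lo, hi, p = wald_inference(fit, "tnsc")
        assert lo < fit.theta[2] < hi
        assert p < 1e-6

    def test_standard_errors_shrink_with_n(self, risk_model):
        spec, theta = risk_model
        se = {}
        for n in (500, 4500):
            fit = fit_mle(spec, simulate_table(spec, theta, n=n, seed=77))
            assert np.all(np.diag(fit.vcov) >= 0.0)
            se[n] = fit.se()[2]
        assert se[4500] < 0.55 * se[500]  # ~ n^{-1/2}

    def test_empty_data_rejected(self, risk_model):
        spec, _ = risk_model
        with pytest.raises(ValueError):
            SampleTable(np.zeros((0, 1)), np.zeros((0, 3)))


class TestWaldInference:
    @staticmethod
    def _dummy_model(theta, vcov):
        spec = ModelSpec("baseline", ("logit", "logit"), "po", d=1)
        return ParameterizedModel(
            spec=spec, theta=np.asarray(theta, float), loglik=-1.0,
            vcov=np.asarray(vcov, float), converged=True, n_iter=1, n=10,
            coef_names=["intercept_1", "intercept_2", "x1"],
        )

    def test_null_estimate(self):
        model = self._dummy_model([0.0, 0.0, 0.0], np.eye(3))
        lo, hi, p = wald_inference(model, 2, level=0.95)
        assert (lo, hi) == pytest.approx((-1.959964, 1.959964), abs=1e-5)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_borderline_estimate(self):
        model = self._dummy_model([0.0, 0.0, 1.96], np.eye(3))
        _, _, p = wald_inference(model, "x1")
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_requires_convergence(self):
        model = self._dummy_model([0.0, 0.0, 1.0], np.eye(3))
        model.converged = False
        with pytest.raises(ValueError):
            wald_inference(model, 2)
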