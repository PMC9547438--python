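import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pkfactor import (
    FactorizationParams,
    IdentifiabilityError,
    ModelSpec,
    ScenarioConfig,
    SchemaError,
    StudyData,
    build_design,
    conditional_variance,
    fit_factorization,
    implied_outcome_correlation,
    neg_log_likelihood,
    simulate_study,
)

from conftest import simulate_from_model


def _study(arms, log_pk, ada, cov=None):
    frame = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(len(arms))],
            "arm": arms,
            "log_pk": log_pk,
            "ada": ada,
        }
    )
    if cov is not None:
        frame["covariate"] = cov
    return StudyData(frame)


class TestBuildDesign:
    def test_treatment_coding(self):
        data = _study(["T", "R"], [1.0, 2.0], [1, 0])
        X_c, X_b, y_c, y_b = build_design(data, ModelSpec())
        np.testing.assert_array_equal(X_c, [[1.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(X_b, [[1.0], [1.0]])
        np.testing.assert_array_equal(y_c, [1.0, 2.0])
        np.testing.assert_array_equal(y_b, [1.0, 0.0])

    def test_unknown_term_is_schema_error(self):
        data = _study(["T", "R"], [1.0, 2.0], [1, 0])
        spec = ModelSpec(continuous_terms=("intercept", "treatment", "weight"))
        with pytest.raises(SchemaError):
            build_design(data, spec)

    def test_covariate_appends_one_column_in_order(self):
        data = _study(["T", "R"], [1.0, 2.0], [1, 0], cov=[0.5, -0.5])
        spec = ModelSpec(
            continuous_terms=("intercept", "treatment", "covariate"),
            binary_terms=("intercept", "covariate"),
        )
        X_c, X_b, *_ = build_design(data, spec)
        assert X_c.shape == (2, 3)
        np.testing.assert_array_equal(X_c[:, 2], [0.5, -0.5])
        np.testing.assert_array_equal(X_b[:, 1], [0.5, -0.5])

    def test_treatment_in_binary_equation_rejected(self):
        with pytest.raises(SchemaError):
            ModelSpec(binary_terms=("intercept", "treatment"))


class TestNegLogLikelihood:
    """Hand-evaluated single-subject values of the joint likelihood."""

    def setup_method(self):
        self.X_c = np.array([[1.0]])
        self.X_b = np.array([[1.0]])
        self.y_c = np.array([0.0])
        self.y_b = np.array([1.0])

    def _params(self, tau):
        return FactorizationParams(
            beta_b=[0.0], beta_c=[0.0], tau=tau, log_sigma_c=0.0
        )

    def test_independent_outcomes(self):
        # 0.5*log(2*pi) for the normal term, -log(0.5) for the probit term
        val = neg_log_likelihood(self._params(0.0), self.X_c, self.X_b, self.y_c, self.y_b)
        assert val == pytest.approx(0.5 * np.log(2 * np.pi) + np.log(2.0), abs=1e-10)
        assert val == pytest.approx(1.6121, abs=5e-5)

    def test_cross_outcome_link(self):
        # residual y_b - Phi(0) = 0.5 enters the squared term: (0 - 0.5)^2/2
        val = neg_log_likelihood(self._params(1.0), self.X_c, self.X_b, self.y_c, self.y_b)
        assert val == pytest.approx(0.5 * np.log(2 * np.pi) + np.log(2.0) + 0.125, abs=1e-10)
        assert val == pytest.approx(1.7371, abs=5e-5)

    def test_tau_zero_separates_into_gaussian_plus_probit(self):
        rng = np.random.default_rng(3)
        data = simulate_from_model([0.2, 0.5], [4.0, -0.05], 0.0, 0.4, 300, rng)
        spec = ModelSpec(binary_terms=("intercept", "covariate"))
        X_c, X_b, y_c, y_b = build_design(data, spec)
        beta_c = np.array([4.1, -0.02])
        beta_b = np.array([0.1, 0.4])
        sigma = 0.45
        params = FactorizationParams(beta_b, beta_c, 0.0, np.log(sigma))
        expected = -np.sum(stats.norm.logpdf(y_c, X_c @ beta_c, sigma))
        prob = stats.norm.cdf(X_b @ beta_b)
        expected -= np.sum(y_b * np.log(prob) + (1 - y_b) * np.log(1 - prob))
        got = neg_log_likelihood(params, X_c, X_b, y_c, y_b)
        assert got == pytest.approx(expected, rel=1e-12)


class TestFitFactorization:
    def test_tau_zero_fit_matches_ols_and_probit(self, small_study):
        """With tau constrained to 0 the joint fit decouples exactly."""
        spec = ModelSpec(binary_terms=("intercept", "covariate"))
        fit = fit_factorization(small_study, spec, tau_fixed=0.0)
        X_c, X_b, y_c, y_b = build_design(small_study, spec)
        ols = sm.OLS(y_c, X_c).fit()
        probit = sm.Probit(y_b, X_b).fit(disp=0)
        assert fit.loglik == pytest.approx(ols.llf + probit.llf, abs=1e-6)
        np.testing.assert_allclose(fit.params.beta_c, ols.params, atol=1e-5)
        np.testing.assert_allclose(fit.params.beta_b, probit.params, atol=1e-5)

    def test_free_fit_never_below_constrained_fit(self, small_study):
        spec = ModelSpec(binary_terms=("intercept", "covariate"))
        full = fit_factorization(small_study, spec)
        constrained = fit_factorization(small_study, spec, tau_fixed=0.0)
        assert full.loglik >= constrained.loglik - 1e-9

    def test_parameter_recovery_on_model_data(self):
        beta_b, beta_c, tau, sigma = [0.3, 0.6], [8.5, -0.05], -0.5, 0.35
        rng = np.random.default_rng(11)
        data = simulate_from_model(beta_b, beta_c, tau, sigma, 10_000, rng)
        fit = fit_factorization(data, ModelSpec(binary_terms=("intercept", "covariate")))
        truth = np.array([*beta_b, *beta_c, tau, np.log(sigma)])
        se = fit.se()
        assert fit.converged
        assert np.all(np.abs(fit.estimates - truth) < 3 * se)

    def test_bias_shrinks_with_n(self):
        """Average absolute error of the estimates decreases along
        n = 200 -> 2,000 -> 20,000 on model-simulated data."""
        beta_b, beta_c, tau, sigma = [0.2, 0.5], [4.0, -0.05], -0.4, 0.4
        truth = np.array([*beta_b, *beta_c, tau, np.log(sigma)])
        spec = ModelSpec(binary_terms=("intercept", "covariate"))
        errs = []
        for j, n in enumerate((200, 2000, 20_000)):
            err = []
            for rep in range(4):
                rng = np.random.default_rng(100 * j + rep)
                fit = fit_factorization(
                    simulate_from_model(beta_b, beta_c, tau, sigma, n, rng), spec
                )
                err.append(np.abs(fit.estimates - truth).mean())
            errs.append(np.mean(err))
        assert errs[0] > errs[1] > errs[2]

    def test_marginal_interpretation(self):
        """E[y_c | arm] from the fitted model equals x_c' beta_c: the mean of
        the fitted marginal prediction matches the arm means because the
        binary residual averages to zero."""
        beta_b, beta_c, tau, sigma = [0.0, 0.7], [4.0, -0.1], -0.8, 0.3
        rng = np.random.default_rng(5)
        data = simulate_from_model(beta_b, beta_c, tau, sigma, 50_000, rng)
        fit = fit_factorization(data, ModelSpec(binary_terms=("intercept", "covariate")))
        frame = data.frame
        for arm, x_t in (("T", 1.0), ("R", 0.0)):
            marginal_pred = fit.params.beta_c[0] + fit.params.beta_c[1] * x_t
            observed = frame.loc[frame["arm"] == arm, "log_pk"].mean()
            assert marginal_pred == pytest.approx(observed, abs=0.02)

    def test_constant_binary_outcome_is_identifiability_error(self):
        data = _study(["T", "T", "R", "R"], [1.0, 1.2, 0.9, 1.1], [1, 1, 1, 1])
        with pytest.raises(IdentifiabilityError, match="tau"):
            fit_factorization(data)

    def test_single_arm_rejected(self):
        data = _study(["T", "T"], [1.0, 1.2], [1, 0])
        with pytest.raises(SchemaError):
            fit_factorization(data)

    def test_wald_se_matches_empirical_sd(self):
        """Reported treatment SE tracks the true sampling SD (10%) over
        replicated scenario data at n = 200."""
        scenario = ScenarioConfig(
            gmr=0.9, cv=0.4, n_total=200, p_T=0.3, p_R=0.3,
            r_pk_ada=-0.5, r_cov_ada=0.1, seed=77,
        )
        spec = ModelSpec(binary_terms=("intercept", "covariate"))
        ests, ses = [], []
        for i in range(400):
            data = simulate_study(scenario, rng=np.random.default_rng(scenario.seed + i))
            fit = fit_factorization(data, spec)
            ests.append(fit.treatment_coef)
            ses.append(fit.treatment_se)
        ratio = np.mean(ses) / np.std(ests, ddof=1)
        assert 0.9 < ratio < 1.1


class TestDiagnostics:
    def test_implied_correlation_values(self):
        params = FactorizationParams([0.0], [0.0, 0.0], 1.0, 0.0)
        # tau=1, sigma=1, eta=0: 1/sqrt(1 + 1/0.25)
        assert implied_outcome_correlation(params, [1.0]) == pytest.approx(
            1 / np.sqrt(5), abs=1e-12
        )
        zero_tau = FactorizationParams([0.0], [0.0, 0.0], 0.0, 0.0)
        assert implied_outcome_correlation(zero_tau, [1.0]) == 0.0
        # sigma -> 0 drives the correlation to sign(tau)
        tight = FactorizationParams([0.0], [0.0, 0.0], -1.0, np.log(1e-9))
        assert implied_outcome_correlation(tight, [1.0]) == pytest.approx(-1.0, abs=1e-6)

    def test_implied_correlation_matches_simulation(self):
        params = FactorizationParams([0.0, 0.0], [0.0, 0.0], 1.0, 0.0)
        rng = np.random.default_rng(8)
        n = 1_000_000
        y_b = (rng.uniform(size=n) < 0.5).astype(float)
        y_c = 1.0 * (y_b - 0.5) + rng.standard_normal(n)
        empirical = np.corrcoef(y_b, y_c)[0, 1]
        assert implied_outcome_correlation(params, [1.0, 0.0]) == pytest.approx(
            empirical, abs=0.005
        )

    def test_conditional_variance(self):
        params = FactorizationParams([0.0], [0.0, 0.0], 2.0, 0.0)
        assert conditional_variance(params, [1.0]) == pytest.approx(2.0, abs=1e-12)
        zero_tau = FactorizationParams([0.0], [0.0, 0.0], 0.0, np.log(0.7))
        assert conditional_variance(zero_tau, [1.0]) == pytest.approx(0.49, abs=1e-12)
        # Phi(1-Phi) is maximal at eta = 0
        off_center = FactorizationParams([1.5], [0.0, 0.0], 2.0, 0.0)
        assert conditional_variance(off_center, [1.0]) < conditional_variance(params, [1.0])
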