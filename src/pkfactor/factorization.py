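"""Factorization joint model for a log-normal PK outcome and a binary
immunogenicity outcome.

The joint density is factorized as f(y_b) * f(y_c | y_b): a probit
marginal for the binary anti-drug-antibody (ADA) outcome,

    probit(E[y_b | x_b]) = x_b' beta_b,

and a conditional normal for log-PK linked through the binary residual,

    y_c | y_b = x_c' beta_c + tau * (y_b - Phi(x_b' beta_b)) + eps,
    eps ~ N(0, sigma_c^2).

Because E[y_b - Phi(x_b' beta_b)] = 0, both coefficient vectors keep their
marginal interpretation; tau measures the cross-outcome dependence and
tau = 0 recovers two independent regressions.  The treatment indicator
enters the continuous (PK) equation only — putting it in the binary
equation would dilute the treatment effect and void the efficiency gain.

Fitting is maximum likelihood over (beta_b, beta_c, tau, log sigma_c) with
analytic gradients; standard errors come from the numerically differenced
observed information at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .datamodel import DomainError, SchemaError, StudyData

__all__ = [
    "ModelSpec",
    "FactorizationParams",
    "FitResult",
    "build_design",
    "neg_log_likelihood",
    "fit_factorization",
    "implied_outcome_correlation",
    "conditional_variance",
]

INTERCEPT = "intercept"
TREATMENT = "treatment"

#: probabilities are clipped to this range inside logs
_PROB_EPS = 1e-12


class IdentifiabilityError(ValueError):
    """The data cannot identify a model parameter (e.g. constant y_b)."""


@dataclass(frozen=True)
class ModelSpec:
    """Term lists for the two regression equations.

    ``continuous_terms`` always contains the intercept and the treatment
    indicator; ``binary_terms`` always contains the intercept and never the
    treatment indicator.  Other names must resolve to covariate columns.
    """

    continuous_terms: tuple[str, ...] = (INTERCEPT, TREATMENT)
    binary_terms: tuple[str, ...] = (INTERCEPT,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "continuous_terms", tuple(self.continuous_terms))
        object.__setattr__(self, "binary_terms", tuple(self.binary_terms))
        if INTERCEPT not in self.continuous_terms or INTERCEPT not in self.binary_terms:
            raise SchemaError("both equations must contain an intercept term")
        if TREATMENT not in self.continuous_terms:
            raise SchemaError("the continuous equation must contain the treatment term")
        if TREATMENT in self.binary_terms:
            raise SchemaError("the binary equation must not contain the treatment term")
        if set(self.continuous_terms) - {INTERCEPT} == set(self.binary_terms) - {INTERCEPT}:
            warnings.warn(
                "continuous and binary equations share the same non-intercept terms; "
                "the factorization model gains no efficiency over separate fits",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class FactorizationParams:
    """Full parameter vector (beta_b, beta_c, tau, log sigma_c)."""

    beta_b: np.ndarray
    beta_c: np.ndarray
    tau: float
    log_sigma_c: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_b", np.atleast_1d(np.asarray(self.beta_b, float)))
        object.__setattr__(self, "beta_c", np.atleast_1d(np.asarray(self.beta_c, float)))

    @property
    def sigma_c(self) -> float:
        return float(np.exp(self.log_sigma_c))

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta_b, self.beta_c, [self.tau, self.log_sigma_c]])

    @classmethod
    def unpack(cls, theta: np.ndarray, k_b: int, k_c: int) -> "FactorizationParams":
        theta = np.asarray(theta, float)
        return cls(
            beta_b=theta[:k_b],
            beta_c=theta[k_b : k_b + k_c],
            tau=float(theta[k_b + k_c]),
            log_sigma_c=float(theta[k_b + k_c + 1]),
        )


@dataclass
class FitResult:
    """Estimates and inference metadata shared by all fitting routines.

    ``dist`` names the reference distribution for Wald confidence
    intervals: ``"z"`` for the factorization model, ``"t"`` (with ``df``
    residual degrees of freedom) for the least-squares comparators.
    """

    method: str
    estimates: np.ndarray
    names: list[str]
    vcov: np.ndarray
    loglik: float
    n_used: int
    converged: bool
    treatment_coef_index: int
    dist: str = "z"
    df: int | None = None
    n_restarts: int = 0
    params: FactorizationParams | None = None
    meta: dict = field(default_factory=dict)

    @property
    def treatment_coef(self) -> float:
        return float(self.estimates[self.treatment_coef_index])

    @property
    def treatment_se(self) -> float:
        return float(np.sqrt(self.vcov[self.treatment_coef_index, self.treatment_coef_index]))

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))

    def to_frame(self):
        """Tidy coefficient table (name, estimate, se) for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {"term": self.names, "estimate": self.estimates, "se": self.se()}
        )

    def to_dict(self) -> dict:
        """Flat export: name -> {estimate, se}."""
        ses = self.se()
        return {
            "method": self.method,
            "loglik": self.loglik,
            "n_used": self.n_used,
            "converged": bool(self.converged),
            "coefficients": {
                name: {"estimate": float(est), "se": float(se)}
                for name, est, se in zip(self.names, self.estimates, ses)
            },
        }


def build_design(data: StudyData, spec: ModelSpec):
    """Assemble aligned design matrices and outcome vectors.

    Treatment is coded 1 for arm T, 0 for arm R.  Returns
    ``(X_c, X_b, y_c, y_b)`` with rows aligned across all four.
    """
    frame = data.frame
    n = len(frame)
    treatment = (frame["arm"].to_numpy() == "T").astype(float)

    def column(term: str) -> np.ndarray:
        if term == INTERCEPT:
            return np.ones(n)
        if term == TREATMENT:
            return treatment
        if term in frame.columns:
            return frame[term].to_numpy(dtype=float)
        raise SchemaError(f"model term {term!r} does not resolve to a column")

    X_c = np.column_stack([column(t) for t in spec.continuous_terms])
    X_b = np.column_stack([column(t) for t in spec.binary_terms])
    y_c = frame["log_pk"].to_numpy(dtype=float)
    y_b = frame["ada"].to_numpy(dtype=float)
    return X_c, X_b, y_c, y_b


def _nll_core(theta, X_c, X_b, y_c, y_b, k_b, k_c):
    """Negative log-likelihood and pieces reused by the gradient."""
    beta_b = theta[:k_b]
    beta_c = theta[k_b : k_b + k_c]
    tau = theta[k_b + k_c]
    log_sigma = theta[k_b + k_c + 1]
    sigma2 = np.exp(2.0 * log_sigma)

    eta_b = X_b @ beta_b
    prob = np.clip(stats.norm.cdf(eta_b), _PROB_EPS, 1.0 - _PROB_EPS)
    resid_b = y_b - prob
    e = y_c - X_c @ beta_c - tau * resid_b

    n = y_c.shape[0]
    nll_cont = 0.5 * n * np.log(2.0 * np.pi * sigma2) + 0.5 * np.dot(e, e) / sigma2
    nll_bin = -np.sum(y_b * np.log(prob) + (1.0 - y_b) * np.log1p(-prob))
    return nll_cont + nll_bin, (eta_b, prob, resid_b, e, sigma2, tau)


def neg_log_likelihood(params: FactorizationParams, X_c, X_b, y_c, y_b) -> float:
    """Negative joint log-likelihood of the factorization model.

    Per subject: the binary contribution is the probit log-likelihood
    y_b log Phi(eta_b) + (1-y_b) log(1 - Phi(eta_b)), and the continuous
    contribution is the normal log-density of y_c at mean
    x_c' beta_c + tau (y_b - Phi(eta_b)) with variance sigma_c^2.
    """
    theta = params.pack()
    if not np.all(np.isfinite(theta)):
        raise DomainError("non-finite parameter value")
    k_b, k_c = params.beta_b.size, params.beta_c.size
    value, _ = _nll_core(theta, X_c, X_b, y_c, y_b, k_b, k_c)
    return float(value)


def _nll_grad(theta, X_c, X_b, y_c, y_b, k_b, k_c):
    value, (eta_b, prob, resid_b, e, sigma2, tau) = _nll_core(
        theta, X_c, X_b, y_c, y_b, k_b, k_c
    )
    phi = stats.norm.pdf(eta_b)
    n = y_c.shape[0]
    # continuous block
    g_beta_c = -(X_c.T @ e) / sigma2
    g_tau = -np.dot(e, resid_b) / sigma2
    g_log_sigma = n - np.dot(e, e) / sigma2
    # binary block + the beta_b pathway through the continuous residual
    w_bin = phi * resid_b / (prob * (1.0 - prob))
    g_beta_b = (tau / sigma2) * (X_b.T @ (e * phi)) - X_b.T @ w_bin
    grad = np.concatenate([g_beta_b, g_beta_c, [g_tau, g_log_sigma]])
    return value, grad


def _starting_values(X_c, X_b, y_c, y_b):
    """Method-of-moments start: probit + least squares + residual covariance."""
    # least squares for the continuous equation
    beta_c, *_ = np.linalg.lstsq(X_c, y_c, rcond=None)
    e_ols = y_c - X_c @ beta_c
    sigma0 = float(np.sqrt(np.mean(e_ols**2)))
    sigma0 = max(sigma0, 1e-6)
    # probit for the binary equation (few Fisher-scoring steps suffice for a start)
    beta_b = _probit_mle(X_b, y_b)
    prob = np.clip(stats.norm.cdf(X_b @ beta_b), _PROB_EPS, 1 - _PROB_EPS)
    r_b = y_b - prob
    var_rb = float(np.var(r_b))
    tau0 = float(np.cov(e_ols, r_b)[0, 1] / var_rb) if var_rb > 0 else 0.0
    return np.concatenate([beta_b, beta_c, [tau0, np.log(sigma0)]])


def _probit_mle(X_b, y_b, max_iter=50, tol=1e-10):
    """Probit MLE by Fisher scoring (used for starting values and the
    tau = 0 separability path)."""
    k = X_b.shape[1]
    beta = np.zeros(k)
    p_bar = np.clip(np.mean(y_b), 1e-6, 1 - 1e-6)
    beta[0] = stats.norm.ppf(p_bar)  # intercept start at the marginal rate
    for _ in range(max_iter):
        eta = X_b @ beta
        prob = np.clip(stats.norm.cdf(eta), _PROB_EPS, 1 - _PROB_EPS)
        phi = stats.norm.pdf(eta)
        w = phi**2 / (prob * (1 - prob))
        score = X_b.T @ (phi * (y_b - prob) / (prob * (1 - prob)))
        info = (X_b * w[:, None]).T @ X_b
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _numerical_hessian(grad_fn, theta):
    """Observed information by central differences of the analytic gradient,
    step = cube-root machine epsilon scaled by parameter magnitude."""
    p = theta.size
    H = np.empty((p, p))
    base_step = np.cbrt(np.finfo(float).eps)
    for j in range(p):
        h = base_step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = grad_fn(tp)
        _, gm = grad_fn(tm)
        H[:, j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _is_pd(H) -> bool:
    try:
        np.linalg.cholesky(H)
        return True
    except np.linalg.LinAlgError:
        return False


def fit_factorization(
    data: StudyData,
    spec: ModelSpec | None = None,
    tau_fixed: float | None = None,
    max_restarts: int = 3,
) -> FitResult:
    """Maximum-likelihood fit of the factorization model.

    Minimizes the joint negative log-likelihood over
    (beta_b, beta_c, tau, log sigma_c) by BFGS with analytic gradients,
    starting from independent probit and least-squares fits.  Up to
    ``max_restarts`` jittered restarts on non-convergence; a fit that still
    fails returns ``converged=False`` rather than raising, so Monte-Carlo
    batches never abort.

    ``tau_fixed`` constrains the cross-outcome coefficient (typically to 0,
    which makes the model separate exactly into a probit fit and a
    least-squares fit).
    """
    spec = spec or ModelSpec()
    X_c, X_b, y_c, y_b = build_design(data, spec)
    n = y_c.shape[0]
    arms = data.arm_counts()
    if TREATMENT in spec.continuous_terms and (arms.get("T", 0) == 0 or arms.get("R", 0) == 0):
        raise SchemaError("both arms required to estimate a treatment effect")
    if y_b.min() == y_b.max():
        raise IdentifiabilityError(
            "binary outcome is constant: tau and the binary equation are not identifiable"
        )
    for name, X in ((("continuous"), X_c), (("binary"), X_b)):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SchemaError(f"rank-deficient {name} design matrix")

    k_b, k_c = X_b.shape[1], X_c.shape[1]
    free_tau = tau_fixed is None

    theta_full = _starting_values(X_c, X_b, y_c, y_b)
    if not free_tau:
        theta_full[k_b + k_c] = tau_fixed

    tau_idx = k_b + k_c

    def grad_fn(theta):
        return _nll_grad(theta, X_c, X_b, y_c, y_b, k_b, k_c)

    if free_tau:
        fun = grad_fn
        x0 = theta_full
    else:
        # optimize over all parameters except tau
        free = np.ones(theta_full.size, bool)
        free[tau_idx] = False

        def fun(theta_free):
            theta = theta_full.copy()
            theta[free] = theta_free
            v, g = grad_fn(theta)
            return v, g[free]

        x0 = theta_full[free]

    def acceptable(res) -> bool:
        # BFGS can stop with "precision loss" at an optimum whose gradient
        # is already far below any practical tolerance
        return bool(res.success or np.max(np.abs(res.jac)) < 1e-5)

    rng = np.random.default_rng(0)  # deterministic restart jitter
    best = None
    n_restarts = 0
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 * rng.uniform(0.8, 1.2, size=x0.size)
        res = optimize.minimize(fun, start, jac=True, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-7})
        if best is None or res.fun < best.fun:
            best = res
        if acceptable(res):
            best = res
            break
        n_restarts = attempt + 1

    if free_tau:
        theta_hat = best.x
    else:
        theta_hat = theta_full.copy()
        theta_hat[free] = best.x

    params = FactorizationParams.unpack(theta_hat, k_b, k_c)
    loglik = -float(best.fun)

    # observed information on the free parameters
    if free_tau:
        H = _numerical_hessian(grad_fn, theta_hat)
    else:
        H = _numerical_hessian(lambda t: fun(t), best.x)

    hess_pd = _is_pd(H)
    try:
        vcov_free = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        vcov_free = np.full_like(H, np.nan)
        hess_pd = False

    names = (
        [f"b[{t}]" for t in spec.binary_terms]
        + [f"c[{t}]" for t in spec.continuous_terms]
        + ["tau", "log_sigma_c"]
    )
    if free_tau:
        vcov = vcov_free
        est = theta_hat
    else:
        # expand vcov with a zero row/column at the fixed tau position
        p = theta_hat.size
        vcov = np.zeros((p, p))
        idx = np.flatnonzero(free)
        vcov[np.ix_(idx, idx)] = vcov_free
        est = theta_hat

    converged = bool(acceptable(best) and hess_pd)
    treat_idx = k_b + spec.continuous_terms.index(TREATMENT)

    # finite-sample calibration: the ML information matrix carries no
    # residual-df correction, which makes equivalence tests slightly
    # liberal at trial-size n.  Scale the covariance by n/(n - p), p the
    # number of conditional-mean parameters of the continuous equation
    # (beta_c plus tau when free), and use a t(n - p) Wald reference —
    # the analogue of the correction that makes the OLS comparator exact.
    p_mean = k_c + (1 if free_tau else 0)
    df = n - p_mean
    if df > 0:
        vcov = vcov * (n / df)

    return FitResult(
        method="factorization",
        estimates=est,
        names=names,
        vcov=vcov,
        loglik=loglik,
        n_used=n,
        converged=converged,
        treatment_coef_index=treat_idx,
        dist="t",
        df=df if df > 0 else None,
        n_restarts=n_restarts,
        params=params,
        meta={"spec": spec, "tau_fixed": tau_fixed},
    )


def _binary_variance(params: FactorizationParams, x_b) -> float:
    eta = float(np.dot(np.atleast_1d(np.asarray(x_b, float)), params.beta_b))
    prob = stats.norm.cdf(eta)
    return prob * (1.0 - prob)


def implied_outcome_correlation(params: FactorizationParams, x_b) -> float:
    """Model-implied correlation between the binary and continuous outcomes
    at covariate value ``x_b``:

        sign(tau) / sqrt(1 + sigma_c^2 / (tau^2 Var(y_b | x_b))),

    and 0 when tau = 0, with Var(y_b | x_b) = Phi(eta_b)(1 - Phi(eta_b)).
    """
    if params.tau == 0.0:
        return 0.0
    v_b = _binary_variance(params, x_b)
    sigma2 = params.sigma_c**2
    return float(np.sign(params.tau) / np.sqrt(1.0 + sigma2 / (params.tau**2 * v_b)))


def conditional_variance(params: FactorizationParams, x_b) -> float:
    """Variance of y_c given covariates (ADA status marginalized out):
    tau^2 Phi(eta_b)(1 - Phi(eta_b)) + sigma_c^2.  The binary mixing makes
    the conditional distribution of y_c a two-component normal mixture,
    bimodal when tau is large relative to sigma_c."""
    return float(params.tau**2 * _binary_variance(params, x_b) + params.sigma_c**2)
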