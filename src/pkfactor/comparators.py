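"""Reference analyses: ANOVA / ANCOVA on log-PK.

The standard primary analysis in a parallel-design PK similarity study is
ordinary least squares of log-PK on treatment (plus optional covariates),
with t-based confidence intervals on n - p residual degrees of freedom.
These fits share the :class:`~pkfactor.factorization.FitResult` contract so
downstream equivalence code treats all methods uniformly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .datamodel import SchemaError, StudyData
from .factorization import INTERCEPT, TREATMENT, FitResult

__all__ = ["fit_anova", "fit_ancova"]


def fit_anova(data: StudyData, extra_terms: Sequence[str] = ()) -> FitResult:
    """OLS of log-PK on intercept + treatment (+ extra covariate terms).

    With no extra terms this is the one-way ANOVA whose treatment
    coefficient is exactly the difference of arm means of log-PK.
    """
    frame = data.frame
    arms = data.arm_counts()
    if arms.get("T", 0) == 0 or arms.get("R", 0) == 0:
        raise SchemaError("both arms required")
    cols = [np.ones(len(frame)), (frame["arm"].to_numpy() == "T").astype(float)]
    names = [f"c[{INTERCEPT}]", f"c[{TREATMENT}]"]
    for term in extra_terms:
        if term not in frame.columns:
            raise SchemaError(f"model term {term!r} does not resolve to a column")
        cols.append(frame[term].to_numpy(dtype=float))
        names.append(f"c[{term}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SchemaError("rank-deficient design matrix")
    y = frame["log_pk"].to_numpy(dtype=float)

    res = sm.OLS(y, X).fit()
    n, p = X.shape
    return FitResult(
        method="ancova" if extra_terms else "anova",
        estimates=np.asarray(res.params),
        names=names,
        vcov=np.asarray(res.cov_params()),
        loglik=float(res.llf),
        n_used=n,
        converged=True,
        treatment_coef_index=1,
        dist="t",
        df=n - p,
    )


def fit_ancova(data: StudyData, extra_terms: Sequence[str]) -> FitResult:
    """ANCOVA: ANOVA plus continuous/indicator covariates."""
    if not extra_terms:
        raise SchemaError("ancova requires at least one covariate term")
    return fit_anova(data, extra_terms=extra_terms)
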