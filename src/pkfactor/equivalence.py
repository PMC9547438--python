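"""Geometric-mean-ratio inference and the average-equivalence decision.

PK similarity is declared when the 90% confidence interval for the
geometric mean ratio (GMR) of test over reference lies within the standard
margin [0.80, 1.25] — operationally identical to two one-sided tests (TOST)
at alpha = 5%.  Margins are treated inclusively.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .factorization import FitResult

__all__ = ["EquivalenceResult", "gmr_interval", "assess_equivalence", "DEFAULT_MARGINS"]

DEFAULT_MARGINS = (0.80, 1.25)
DEFAULT_LEVEL = 0.90


@dataclass(frozen=True)
class EquivalenceResult:
    """GMR point estimate, confidence interval, margins, and the decision."""

    gmr: float
    ci_low: float
    ci_high: float
    level: float = DEFAULT_LEVEL
    margin_low: float = DEFAULT_MARGINS[0]
    margin_high: float = DEFAULT_MARGINS[1]
    passed: bool | None = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.gmr <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0,1)")


def gmr_interval(fit: FitResult, level: float = DEFAULT_LEVEL) -> EquivalenceResult:
    """Two-sided CI for the GMR from a fit's treatment coefficient.

    On the log scale the interval is b +/- q * SE(b) where q is the z
    quantile for factorization fits and the t(df) quantile for the
    least-squares comparators, per the fit's declared reference
    distribution; exponentiation maps it to the ratio scale.
    """
    if not fit.converged:
        raise ValueError("cannot form a confidence interval from a non-converged fit")
    b = fit.treatment_coef
    se = fit.treatment_se
    alpha = 1.0 - level
    if fit.dist == "t":
        q = stats.t.ppf(1.0 - alpha / 2.0, fit.df)
    else:
        q = stats.norm.ppf(1.0 - alpha / 2.0)
    return EquivalenceResult(
        gmr=float(np.exp(b)),
        ci_low=float(np.exp(b - q * se)),
        ci_high=float(np.exp(b + q * se)),
        level=level,
    )


def assess_equivalence(
    interval: EquivalenceResult,
    margin_low: float = DEFAULT_MARGINS[0],
    margin_high: float = DEFAULT_MARGINS[1],
) -> EquivalenceResult:
    """Fill the pass/fail decision: pass iff the CI lies within the margins
    (inclusive at both boundaries)."""
    passed = interval.ci_low >= margin_low and interval.ci_high <= margin_high
    return replace(
        interval, margin_low=margin_low, margin_high=margin_high, passed=bool(passed)
    )
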