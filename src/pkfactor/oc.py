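"""Monte-Carlo operating characteristics: power, type-I error, GMR bias,
and sample-size determination for the factorization model versus ANOVA.

In the equivalence setting "power" and "type-I error" are the same
quantity — the probability that the 90% GMR confidence interval lands
inside [0.80, 1.25] — evaluated at a true GMR inside the margin (0.95) or
on its boundary (0.80) respectively.  Methods are compared on common random
numbers: within a scenario and replicate every method analyzes the same
simulated data set, which sharpens power-dominance comparisons.
Non-converged replicates count as failures to demonstrate equivalence
(conservative); the convergence rate is reported separately.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparators import fit_anova
from .datamodel import StudyData
from .equivalence import DEFAULT_LEVEL, DEFAULT_MARGINS, assess_equivalence, gmr_interval
from .factorization import (
    IdentifiabilityError,
    ModelSpec,
    fit_factorization,
)
from .datamodel import DomainError, SchemaError
from .simulate import (
    InfeasibleScenarioError,
    ScenarioConfig,
    cv_to_sigma,
    simulate_study,
)

__all__ = [
    "OperatingCharacteristics",
    "run_oc",
    "run_grid",
    "sample_size_search",
    "analytic_anova_sample_size",
    "tost_power",
    "power_scenario_grid",
    "type1_scenario_grid",
    "samplesize_scenario_grid",
    "METHODS",
]

logger = logging.getLogger(__name__)

METHODS = ("factorization", "anova", "ancova")

#: default factorization layout used throughout the simulation study:
#: treatment in the PK equation, the baseline covariate in the ADA equation
DEFAULT_FACT_SPEC = ModelSpec(
    continuous_terms=("intercept", "treatment"),
    binary_terms=("intercept", "covariate"),
)


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo summary for one (scenario, method) cell.

    ``pass_rate`` is power when the scenario's true GMR is inside the
    margins and type-I error when it sits on a boundary.  Its denominator
    is all replicates; non-converged fits count as failures.
    """

    method: str
    scenario: ScenarioConfig
    n_reps: int
    pass_rate: float
    mean_gmr: float
    mc_se: float
    convergence_rate: float

    def as_row(self) -> dict:
        row = {f"scenario_{k}": v for k, v in self.scenario.to_dict().items()}
        row.update(
            method=self.method,
            n_reps=self.n_reps,
            pass_rate=self.pass_rate,
            mean_gmr=self.mean_gmr,
            mc_se=self.mc_se,
            convergence_rate=self.convergence_rate,
        )
        return row


def _fit_one(data: StudyData, method: str):
    if method == "factorization":
        return fit_factorization(data, DEFAULT_FACT_SPEC)
    if method == "anova":
        return fit_anova(data)
    if method == "ancova":
        return fit_anova(data, extra_terms=("covariate",))
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _assess_fit(fit, level, margins):
    interval = gmr_interval(fit, level=level)
    return assess_equivalence(interval, *margins)


def run_oc(
    scenario: ScenarioConfig,
    method: str = "factorization",
    n_reps: int = 5000,
    level: float = DEFAULT_LEVEL,
    margins: tuple[float, float] = DEFAULT_MARGINS,
) -> OperatingCharacteristics:
    """Estimate pass rate and mean GMR for one scenario and method.

    Replicate i draws its study from a generator seeded at
    ``scenario.seed + i``, so results are reproducible and replicates are
    shared across methods and across sample sizes (common random numbers).
    """
    passes = 0
    gmrs = []
    converged = 0
    for i in range(n_reps):
        rng = np.random.default_rng(scenario.seed + i)
        data = simulate_study(scenario, rng=rng)
        try:
            fit = _fit_one(data, method)
        except (IdentifiabilityError, SchemaError, np.linalg.LinAlgError):
            continue  # counted as non-converged failure
        if not fit.converged:
            continue
        converged += 1
        result = _assess_fit(fit, level, margins)
        gmrs.append(result.gmr)
        passes += result.passed
    pr = passes / n_reps
    return OperatingCharacteristics(
        method=method,
        scenario=scenario,
        n_reps=n_reps,
        pass_rate=pr,
        mean_gmr=float(np.mean(gmrs)) if gmrs else float("nan"),
        mc_se=float(np.sqrt(pr * (1.0 - pr) / n_reps)),
        convergence_rate=converged / n_reps,
    )


def run_grid(
    scenarios: Iterable[ScenarioConfig | dict],
    methods: Sequence[str] = ("factorization", "anova"),
    n_reps: int = 5000,
    level: float = DEFAULT_LEVEL,
    margins: tuple[float, float] = DEFAULT_MARGINS,
) -> pd.DataFrame:
    """Run every (scenario, method) cell; paired on common simulated data.

    Within a scenario, each replicate's data set is analyzed by every
    method.  Infeasible scenarios (passed as dicts that fail construction)
    become skipped rows carrying the reason.  Returns a tidy long-format
    DataFrame, one row per cell.
    """
    rows = []
    for config in scenarios:
        if isinstance(config, dict):
            try:
                config = ScenarioConfig.from_dict(config)
            except (InfeasibleScenarioError, DomainError) as exc:
                rows.append({"skipped": True, "reason": str(exc), **{
                    f"scenario_{k}": v for k, v in config.items()}})
                continue
        t0 = time.perf_counter()
        stats_per_method = {
            m: {"passes": 0, "gmrs": [], "converged": 0} for m in methods
        }
        for i in range(n_reps):
            rng = np.random.default_rng(config.seed + i)
            data = simulate_study(config, rng=rng)
            for m in methods:
                acc = stats_per_method[m]
                try:
                    fit = _fit_one(data, m)
                except (IdentifiabilityError, SchemaError, np.linalg.LinAlgError):
                    continue
                if not fit.converged:
                    continue
                acc["converged"] += 1
                result = _assess_fit(fit, level, margins)
                acc["gmrs"].append(result.gmr)
                acc["passes"] += result.passed
        for m in methods:
            acc = stats_per_method[m]
            pr = acc["passes"] / n_reps
            oc = OperatingCharacteristics(
                method=m,
                scenario=config,
                n_reps=n_reps,
                pass_rate=pr,
                mean_gmr=float(np.mean(acc["gmrs"])) if acc["gmrs"] else float("nan"),
                mc_se=float(np.sqrt(pr * (1.0 - pr) / n_reps)),
                convergence_rate=acc["converged"] / n_reps,
            )
            rows.append({"skipped": False, "reason": "", **oc.as_row()})
        logger.info(
            "scenario seed=%d done in %.1fs", config.seed, time.perf_counter() - t0
        )
    return pd.DataFrame(rows)


def tost_power(
    n_total: int,
    gmr: float,
    cv: float,
    alpha: float = 0.05,
    margins: tuple[float, float] = DEFAULT_MARGINS,
) -> float:
    """Exact power of the two-one-sided-tests procedure for a 1:1 parallel
    design on the log scale, via noncentral-t tail probabilities.

    The test statistic uses the pooled residual SD on n - 2 degrees of
    freedom; power is P(both one-sided tests reject at level alpha), which
    for non-overlapping rejection regions equals the difference of two
    noncentral-t CDFs.
    """
    sigma = cv_to_sigma(cv)
    n_t = n_total // 2
    n_r = n_total - n_t
    df = n_total - 2
    se = sigma * np.sqrt(1.0 / n_t + 1.0 / n_r)
    t_crit = stats.t.ppf(1.0 - alpha, df)
    ncp_low = (np.log(gmr) - np.log(margins[0])) / se
    ncp_high = (np.log(gmr) - np.log(margins[1])) / se
    power = stats.nct.cdf(-t_crit, df, ncp_high) - stats.nct.cdf(t_crit, df, ncp_low)
    return float(max(power, 0.0))


def analytic_anova_sample_size(
    gmr: float,
    cv: float,
    alpha: float = 0.05,
    power: float = 0.80,
    margins: tuple[float, float] = DEFAULT_MARGINS,
    n_max: int = 100_000,
) -> int:
    """Smallest even total sample size (1:1 parallel design) at which the
    TOST power on log scale reaches the target; power from
    :func:`tost_power`.  The true GMR must lie strictly inside the margins.
    """
    if not margins[0] < gmr < margins[1]:
        raise InfeasibleScenarioError(
            f"gmr {gmr} not strictly inside margins {margins}; equivalence power "
            "cannot reach any target"
        )
    # normal-approximation start, then walk the even grid to the boundary
    sigma = cv_to_sigma(cv)
    delta = min(np.log(gmr) - np.log(margins[0]), np.log(margins[1]) - np.log(gmr))
    z_a = stats.norm.ppf(1.0 - alpha)
    z_b = stats.norm.ppf(power if gmr != 1.0 else 1.0 - (1.0 - power) / 2.0)
    n_guess = int(np.ceil(2.0 * (z_a + z_b) ** 2 * 2.0 * sigma**2 / delta**2))
    n = max(6, n_guess + n_guess % 2)
    while n <= n_max and tost_power(n, gmr, cv, alpha, margins) < power:
        n += 2
    while n > 6 and tost_power(n - 2, gmr, cv, alpha, margins) >= power:
        n -= 2
    if n > n_max:
        raise InfeasibleScenarioError(f"no n <= {n_max} reaches power {power}")
    return n


def sample_size_search(
    template: ScenarioConfig,
    method: str = "factorization",
    target_power: float = 0.80,
    n_reps: int = 2000,
    n_min: int = 12,
    n_max: int = 2000,
    confirm_reps: int | None = None,
    level: float = DEFAULT_LEVEL,
    margins: tuple[float, float] = DEFAULT_MARGINS,
) -> int:
    """Smallest even total sample size with simulated power >= target.

    Bracketed integer bisection on the even-n grid with common random
    numbers across n (the same replicate seeds are reused at every n), a
    local scan of +/-4 subjects to undo bisection noise, then a
    confirmation pass at ``confirm_reps`` (default 2 * n_reps) stepping up
    by 2 until confirmed.
    """
    if target_power <= 0.0:
        return n_min

    cache: dict[tuple[int, int], float] = {}

    def power_at(n: int, reps: int) -> float:
        key = (n, reps)
        if key not in cache:
            cache[key] = run_oc(
                replace(template, n_total=n), method, reps, level, margins
            ).pass_rate
        return cache[key]

    lo = n_min
    if power_at(lo, n_reps) >= target_power:
        hi = lo
    else:
        hi = max(lo + 2, template.n_total - template.n_total % 2)
        while hi <= n_max and power_at(hi, n_reps) < target_power:
            lo = hi
            hi = min(2 * hi, n_max + 2) if hi < n_max else n_max + 2
        if hi > n_max:
            raise InfeasibleScenarioError(
                f"power {target_power} not reached by n_total {n_max} for {method}"
            )
        while hi - lo > 2:
            mid = (lo + hi) // 2
            mid += mid % 2
            if mid in (lo, hi):
                break
            if power_at(mid, n_reps) >= target_power:
                hi = mid
            else:
                lo = mid

    # local scan to undo bisection noise
    best = hi
    for n in range(max(n_min, hi - 4), hi + 6, 2):
        if power_at(n, n_reps) >= target_power:
            best = n
            break

    confirm_reps = confirm_reps or 2 * n_reps
    n = best
    while n <= n_max and power_at(n, confirm_reps) < target_power:
        n += 2
    if n > n_max:
        raise InfeasibleScenarioError(
            f"confirmation failed below n_total {n_max} for {method}"
        )
    return n


# -- reference scenario grids of the simulation study ------------------------

_SEED_STRIDE = 100_000  # disjoint replicate seed ranges per scenario


def power_scenario_grid(seed: int = 0) -> list[ScenarioConfig]:
    """36 power scenarios: GMR 0.95, CV 0.4, n 130; reference-arm ADA rate
    in {20, 40, 60}%, test-arm excess in {0, 5, 10} points; PK-ADA
    correlation in {-0.3, -0.5}; covariate-ADA correlation in {0.1, 0.3}."""
    grid = []
    i = 0
    for p_r in (0.2, 0.4, 0.6):
        for diff in (0.0, 0.05, 0.10):
            for r_pk in (-0.3, -0.5):
                for r_cov in (0.1, 0.3):
                    grid.append(
                        ScenarioConfig(
                            gmr=0.95, cv=0.4, n_total=130,
                            p_T=p_r + diff, p_R=p_r,
                            r_pk_ada=r_pk, r_cov_ada=r_cov,
                            seed=seed + i * _SEED_STRIDE,
                        )
                    )
                    i += 1
    return grid


def type1_scenario_grid(seed: int = 0) -> list[ScenarioConfig]:
    """6 type-I scenarios at the margin boundary: GMR 0.80, CV 0.4, n 200;
    equal ADA rates in {20, 40, 60}%; PK-ADA correlation -0.5 (scenarios
    1-3) then -0.3 (scenarios 4-6); covariate-ADA correlation 0.1."""
    grid = []
    i = 0
    for r_pk in (-0.5, -0.3):
        for p in (0.2, 0.4, 0.6):
            grid.append(
                ScenarioConfig(
                    gmr=0.80, cv=0.4, n_total=200,
                    p_T=p, p_R=p,
                    r_pk_ada=r_pk, r_cov_ada=0.1,
                    seed=seed + i * _SEED_STRIDE,
                )
            )
            i += 1
    return grid


def samplesize_scenario_grid(seed: int = 0) -> list[ScenarioConfig]:
    """12 sample-size scenarios: GMR 0.95; CV in {0.3, 0.4, 0.5, 0.6};
    ADA rate 50% in both arms; PK-ADA correlation in {-0.3, -0.5, -0.6};
    covariate-ADA correlation 0.1."""
    grid = []
    i = 0
    for cv in (0.3, 0.4, 0.5, 0.6):
        for r_pk in (-0.3, -0.5, -0.6):
            grid.append(
                ScenarioConfig(
                    gmr=0.95, cv=cv, n_total=130,
                    p_T=0.5, p_R=0.5,
                    r_pk_ada=r_pk, r_cov_ada=0.1,
                    seed=seed + i * _SEED_STRIDE,
                )
            )
            i += 1
    return grid
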