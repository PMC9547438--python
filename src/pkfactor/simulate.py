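"""Synthetic study generator: correlated log-PK, ADA, and covariate data.

Each arm draws (ADA latent, log-PK latent, covariate) from a trivariate
standard normal with a specified latent correlation matrix; the ADA latent
is dichotomized at its (1 - p)-quantile so that a proportion p of subjects
is ADA positive.  Dichotomizing a bivariate-normal component attenuates its
correlation with any continuous partner: if the latent correlation is rho
and p is the proportion above the cut, the realized (point-biserial)
correlation is

    delta = rho * h / sqrt(p (1 - p)),

with h the standard-normal density at the cut.  The scenario's correlation
targets are interpreted as realized point-biserial values, so the latent
correlations are obtained by inverting this map per arm (an alternate mode
treats them as latent values directly).

The marginal distribution of log-PK in each arm is exactly normal with
mean anchor (+ ln GMR in the test arm) and SD sigma = sqrt(ln(1 + CV^2)),
the log-scale SD of a log-normal with geometric coefficient of variation
CV.  Conditional on ADA status it is a two-component normal mixture —
the structure seen in immunogenic-subgroup PK data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datamodel import DomainError, StudyData

__all__ = [
    "ScenarioConfig",
    "InfeasibleScenarioError",
    "cv_to_sigma",
    "point_biserial_forward",
    "point_biserial_invert",
    "latent_correlation_matrix",
    "simulate_arm",
    "simulate_study",
    "LOG_PK_ANCHOR",
]

#: reference-arm mean of log-PK; an AUC-like magnitude. Inference depends
#: only on arm differences, so the anchor is pure convention.
LOG_PK_ANCHOR = float(np.log(5000.0))

#: fixed latent variable ordering for the Cholesky draw
LATENT_ORDER = ("ada", "log_pk", "covariate")


class InfeasibleScenarioError(ValueError):
    """The requested correlations admit no valid latent normal distribution."""


def cv_to_sigma(cv: float) -> float:
    """Log-scale SD of a log-normal with geometric CV ``cv``:
    sigma = sqrt(ln(1 + cv^2))."""
    if cv <= 0:
        raise DomainError(f"cv must be positive, got {cv}")
    return float(np.sqrt(np.log1p(cv * cv)))


def _dichotomization_ordinate(p: float) -> float:
    """Standard-normal density at the cut leaving proportion p above."""
    if not 0.0 < p < 1.0:
        raise DomainError(f"p must be in (0,1), got {p}")
    return float(stats.norm.pdf(stats.norm.ppf(1.0 - p)))


def point_biserial_forward(rho_latent: float, p: float) -> float:
    """Realized correlation after dichotomizing one member of a bivariate
    normal pair: delta = rho * h / sqrt(p(1-p))."""
    if abs(rho_latent) > 1.0:
        raise DomainError(f"|rho| must be <= 1, got {rho_latent}")
    h = _dichotomization_ordinate(p)
    return rho_latent * h / np.sqrt(p * (1.0 - p))


def point_biserial_invert(delta_target: float, p: float) -> float:
    """Latent correlation that realizes a target point-biserial correlation:
    rho = delta * sqrt(p(1-p)) / h.  Raises when |rho| >= 1 (the target is
    steeper than dichotomization allows)."""
    h = _dichotomization_ordinate(p)
    rho = delta_target * np.sqrt(p * (1.0 - p)) / h
    if abs(rho) >= 1.0:
        raise InfeasibleScenarioError(
            f"target point-biserial correlation {delta_target} at p={p} "
            f"requires latent correlation {rho:.4f} outside (-1, 1)"
        )
    return float(rho)


def latent_correlation_matrix(p: float, r_pk_ada: float, r_cov_ada: float,
                              targets_are_latent: bool = False) -> np.ndarray:
    """3x3 latent correlation matrix in the order (ADA, log-PK, covariate).

    PK and covariate latents are uncorrelated; both correlate with the ADA
    latent.  Must be positive definite.
    """
    if targets_are_latent:
        rho_pk, rho_cov = r_pk_ada, r_cov_ada
        if max(abs(rho_pk), abs(rho_cov)) >= 1.0:
            raise InfeasibleScenarioError("latent correlations must lie in (-1, 1)")
    else:
        rho_pk = point_biserial_invert(r_pk_ada, p)
        rho_cov = point_biserial_invert(r_cov_ada, p)
    corr = np.array(
        [
            [1.0, rho_pk, rho_cov],
            [rho_pk, 1.0, 0.0],
            [rho_cov, 0.0, 1.0],
        ]
    )
    if np.linalg.eigvalsh(corr)[0] <= 0.0:
        raise InfeasibleScenarioError(
            f"latent correlation matrix not positive definite for p={p}, "
            f"r_pk_ada={r_pk_ada}, r_cov_ada={r_cov_ada}"
        )
    return corr


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario for a two-arm parallel PK similarity study.

    Parameters
    ----------
    gmr
        True marginal geometric mean ratio T/R of the PK parameter.
    cv
        Geometric CV of the PK parameter, identical in both arms.
    n_total
        Total sample size; 1:1 allocation (odd totals put the extra
        subject in the reference arm).
    p_T, p_R
        ADA-positive rates by arm.
    r_pk_ada, r_cov_ada
        Target correlations of the binary ADA outcome with log-PK and with
        the baseline covariate (point-biserial by default; latent when
        ``targets_are_latent``).  The covariate is independent of log-PK.
    seed
        Base seed for reproducible generation.
    """

    gmr: float = 0.95
    cv: float = 0.4
    n_total: int = 130
    p_T: float = 0.2
    p_R: float = 0.2
    r_pk_ada: float = -0.5
    r_cov_ada: float = 0.1
    seed: int = 0
    targets_are_latent: bool = False
    log_pk_anchor: float = LOG_PK_ANCHOR

    def __post_init__(self) -> None:
        if self.gmr <= 0:
            raise DomainError("gmr must be positive")
        if self.n_total < 2:
            raise DomainError("n_total must be at least 2")
        cv_to_sigma(self.cv)  # validates cv > 0
        for p in (self.p_T, self.p_R):
            if not 0.0 < p < 1.0:
                raise DomainError(f"ADA rate must be in (0,1), got {p}")
        # reject infeasible correlation targets at construction, never mid-stream
        for p in (self.p_T, self.p_R):
            latent_correlation_matrix(p, self.r_pk_ada, self.r_cov_ada,
                                      self.targets_are_latent)

    @property
    def sigma(self) -> float:
        return cv_to_sigma(self.cv)

    def arm_sizes(self) -> dict[str, int]:
        n_t = self.n_total // 2
        return {"T": n_t, "R": self.n_total - n_t}

    def arm_rate(self, arm: str) -> float:
        return self.p_T if arm == "T" else self.p_R

    def arm_mean(self, arm: str) -> float:
        return self.log_pk_anchor + (np.log(self.gmr) if arm == "T" else 0.0)

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(json.loads(text))


def simulate_arm(
    n: int,
    arm: str,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw one arm: n rows of (subject_id, arm, log_pk, ada, covariate).

    The trivariate latent draw uses the Cholesky factor of the latent
    correlation matrix in the fixed order (ADA, log-PK, covariate); ADA = 1
    when its latent exceeds the (1 - p_arm)-quantile.
    """
    p = config.arm_rate(arm)
    corr = latent_correlation_matrix(
        p, config.r_pk_ada, config.r_cov_ada, config.targets_are_latent
    )
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 3)) @ chol.T
    ada = (z[:, 0] > stats.norm.ppf(1.0 - p)).astype(int)
    log_pk = config.arm_mean(arm) + config.sigma * z[:, 1]
    covariate = z[:, 2]
    return pd.DataFrame(
        {
            "subject_id": [f"{arm}-{i + 1:04d}" for i in range(n)],
            "arm": arm,
            "log_pk": log_pk,
            "ada": ada,
            "covariate": covariate,
        }
    )


def simulate_study(config: ScenarioConfig, rng: np.random.Generator | None = None) -> StudyData:
    """Simulate a full two-arm study: test arm then reference arm, from one
    seeded generator, so output is bit-reproducible at a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = config.arm_sizes()
    frames = [simulate_arm(sizes["T"], "T", config, rng),
              simulate_arm(sizes["R"], "R", config, rng)]
    frame = pd.concat(frames, ignore_index=True)
    return StudyData(frame, meta={"scenario": config.to_dict()})
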