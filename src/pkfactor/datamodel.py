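"""Subject-level data containers and CSV I/O for parallel-design PK studies.

A study holds one row per subject: treatment arm (``T`` test / ``R``
reference), the PK parameter on the natural-log scale, the binary
immunogenicity outcome (anti-drug-antibody status or high/low titer
subgroup), and optional baseline covariates.  All model code operates on
log-PK; the raw PK scale exists only at the I/O boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectRecord",
    "StudyData",
    "MixtureSpec",
    "read_study_csv",
    "write_study_csv",
    "mixture_cdf",
]

logger = logging.getLogger(__name__)

ARMS = ("T", "R")

#: canonical column names for the study CSV layout
CANONICAL_COLUMNS = ("subject_id", "arm", "log_pk", "ada")


class SchemaError(ValueError):
    """A required column or model term is missing or malformed."""


class DomainError(ValueError):
    """A value violates the domain of an operation (e.g. log of 0)."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: arm, log-PK outcome, binary ADA outcome, covariates."""

    subject_id: str
    arm: str
    y_c: float
    y_b: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise DomainError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.y_b not in (0, 1):
            raise DomainError(f"y_b must be 0 or 1, got {self.y_b!r}")
        if not math.isfinite(self.y_c):
            raise DomainError(f"y_c must be finite, got {self.y_c!r}")


class StudyData:
    """Ordered collection of subjects backed by a :class:`pandas.DataFrame`.

    Columns: ``subject_id``, ``arm``, ``log_pk``, ``ada`` plus one column
    per covariate.  Subject ids must be unique.
    """

    def __init__(self, frame: pd.DataFrame, meta: dict | None = None):
        frame = frame.reset_index(drop=True)
        for col in CANONICAL_COLUMNS:
            if col not in frame.columns:
                raise SchemaError(f"missing required column {col!r}")
        if len(frame) > 0:
            bad_arm = ~frame["arm"].isin(ARMS)
            if bad_arm.any():
                raise DomainError(
                    f"invalid arm values: {frame.loc[bad_arm, 'arm'].unique()!r}"
                )
            ada = frame["ada"].to_numpy()
            if not np.isin(ada, (0, 1)).all():
                raise DomainError("ada values must be 0 or 1")
            if not np.isfinite(frame["log_pk"].to_numpy(dtype=float)).all():
                raise DomainError("log_pk values must be finite")
            if frame["subject_id"].duplicated().any():
                raise DomainError("subject ids must be unique")
        self._frame = frame.assign(
            subject_id=frame["subject_id"].astype(str),
            ada=frame["ada"].astype(int) if len(frame) else frame["ada"],
            log_pk=frame["log_pk"].astype(float) if len(frame) else frame["log_pk"],
        )
        self.meta: dict = dict(meta or {})

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyData):
            return NotImplemented
        return self._frame.equals(other._frame)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (treat as read-only)."""
        return self._frame

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self._frame.columns if c not in CANONICAL_COLUMNS]

    @property
    def records(self) -> list[SubjectRecord]:
        covs = self.covariate_names
        return [
            SubjectRecord(
                subject_id=row.subject_id,
                arm=row.arm,
                y_c=row.log_pk,
                y_b=int(row.ada),
                covariates={c: getattr(row, c) for c in covs},
            )
            for row in self._frame.itertuples(index=False)
        ]

    def arm_counts(self) -> dict[str, int]:
        return self._frame["arm"].value_counts().to_dict()

    @classmethod
    def from_records(cls, records: Sequence[SubjectRecord], meta: dict | None = None) -> "StudyData":
        rows = [
            {
                "subject_id": r.subject_id,
                "arm": r.arm,
                "log_pk": r.y_c,
                "ada": r.y_b,
                **dict(r.covariates),
            }
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS) if not rows else None)
        return cls(frame, meta=meta)


def read_study_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    pk_on_log_scale: bool = True,
    covariates: Sequence[str] = (),
) -> StudyData:
    """Read a study CSV into a validated :class:`StudyData`.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Maps canonical names (``subject_id``, ``arm``, ``pk`` or
        ``log_pk``, ``ada``) to the file's column names.  Identity by
        default.
    pk_on_log_scale
        When False the PK column is natural-log transformed on read; the
        raw values must then be strictly positive.
    covariates
        Extra numeric columns to carry along.  Rows with missing values in
        any modeled column are dropped (complete-case) with a logged count.
    """
    column_map = dict(column_map or {})
    pk_key = "log_pk" if pk_on_log_scale else "pk"
    raw = pd.read_csv(path, float_precision="round_trip")

    def col(name: str) -> str:
        return column_map.get(name, name)

    needed = ["subject_id", "arm", pk_key, "ada", *covariates]
    missing = [c for c in needed if col(c) not in raw.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {[col(c) for c in missing]}")

    frame = pd.DataFrame(
        {
            "subject_id": raw[col("subject_id")],
            "arm": raw[col("arm")],
            "log_pk": pd.to_numeric(raw[col(pk_key)], errors="coerce"),
            "ada": raw[col("ada")],
        }
    )
    for c in covariates:
        frame[c] = pd.to_numeric(raw[col(c)], errors="coerce")

    n0 = len(frame)
    frame = frame.dropna()
    if len(frame) < n0:
        logger.info("dropped %d incomplete records of %d", n0 - len(frame), n0)

    if len(frame):
        ada = frame["ada"].to_numpy()
        if not np.isin(ada, (0, 1)).all():
            raise DomainError("ada values must be 0 or 1")
        if not pk_on_log_scale:
            pk = frame["log_pk"].to_numpy(dtype=float)
            if (pk <= 0).any():
                raise DomainError("PK values must be strictly positive to log-transform")
            frame["log_pk"] = np.log(pk)
    return StudyData(frame, meta={"source": str(path)})


def write_study_csv(data: StudyData, path) -> None:
    """Write a study to CSV such that ``read_study_csv(path)`` inverts it.

    Log-PK is written with ``repr`` round-trip precision so the round trip
    is bit-exact.
    """
    data.frame.to_csv(path, index=False, float_format=None)


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component normal mixture for log-PK marginalized over ADA status.

    ``p`` is the ADA-positive probability; conditional on ADA status j the
    outcome is N(mu_j, sigma_j).
    """

    p: float
    mu1: float
    sigma1: float
    mu0: float
    sigma0: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise DomainError(f"p must be in (0,1), got {self.p}")
        if self.sigma1 <= 0 or self.sigma0 <= 0:
            raise DomainError("mixture component sigmas must be positive")

    @property
    def q(self) -> float:
        return 1.0 - self.p


def mixture_cdf(y, spec: MixtureSpec):
    """CDF of the two-component mixture: p*F1(y) + (1-p)*F0(y).

    Vectorized over ``y``; monotone nondecreasing with limits 0 and 1.
    """
    y = np.asarray(y, dtype=float)
    out = spec.p * stats.norm.cdf(y, spec.mu1, spec.sigma1) + spec.q * stats.norm.cdf(
        y, spec.mu0, spec.sigma0
    )
    return float(out) if out.ndim == 0 else out
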