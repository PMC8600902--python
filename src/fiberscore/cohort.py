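"""Per-patient cohort tables: typed container and CSV reader/writer.

A cohort table has one row per patient with:

* ``patient_id`` (unique), ``cohort`` in {training, internal_validation,
  external_validation};
* the disease-free-survival outcome: ``dfs_months`` >= 0 and ``event``
  (1 = recurrence/death observed, 0 = censored);
* categorical clinical covariates (age group, molecular subtype, tumor
  size class, nodal status, clinical stage, histological grade, ER, PR,
  HER2, four therapy flags);
* eight binary collagen-architecture indicators ``tacs_1`` .. ``tacs_8``;
* optionally, aggregated per-patient features ``tcmf_1`` .. ``tcmf_142``
  and precomputed score columns.

Times are months throughout; a "5-year" horizon is 60 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .registry import TCMF_COLUMNS

COHORT_LABELS = ("training", "internal_validation", "external_validation")

#: Categorical clinical covariates with their levels; the first level of each
#: is the reference level used when expanding to indicator contrasts.
CLINICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "age_group": ("<=50", ">50"),
    "subtype": ("luminal_a", "luminal_b", "her2_enriched", "triple_negative"),
    "tumor_size": ("T<=2cm", "T2-5cm", "T>5cm"),
    "nodal_status": ("N0", "N1-3", "N>=4"),
    "stage": ("I", "II", "III"),
    "grade": ("G1", "G2", "G3"),
    "er": ("negative", "positive"),
    "pr": ("negative", "positive"),
    "her2": ("negative", "positive"),
    "chemotherapy": ("no", "yes"),
    "endocrine_therapy": ("no", "yes"),
    "radiation_therapy": ("no", "yes"),
    "targeted_therapy": ("no", "yes"),
}

CLINICAL_COLUMNS = tuple(CLINICAL_LEVELS)
TACS_COLUMNS = tuple(f"tacs_{i}" for i in range(1, 9))
SCORE_COLUMNS = ("tcmf_score", "tacs_score", "cli_score", "tcmf_tacs_score", "full_score")

MANDATORY_COLUMNS = ("patient_id", "cohort", "dfs_months", "event")


class CohortFormatError(ValueError):
    """Raised when a cohort CSV violates the documented schema."""


@dataclass
class PatientRecord:
    patient_id: str
    cohort: str
    dfs_months: float
    event: int
    clinical: dict[str, str]
    tacs: tuple[int, ...]
    roi_features: np.ndarray | None = None  # aggregated 142-vector, if present

    def __post_init__(self) -> None:
        if self.dfs_months < 0:
            raise CohortFormatError(f"{self.patient_id}: dfs_months must be >= 0")
        if self.event not in (0, 1):
            raise CohortFormatError(f"{self.patient_id}: event must be 0 or 1")
        if len(self.tacs) != 8:
            raise CohortFormatError(f"{self.patient_id}: expected 8 TACS indicators")


@dataclass
class CohortTable:
    """Thin validated wrapper around a per-patient DataFrame."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        _validate(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, cohort: str) -> "CohortTable":
        if cohort not in COHORT_LABELS:
            raise ValueError(f"unknown cohort label {cohort!r}")
        return CohortTable(self.df[self.df["cohort"] == cohort].reset_index(drop=True))

    @property
    def has_features(self) -> bool:
        return all(c in self.df.columns for c in TCMF_COLUMNS)

    def feature_matrix(self) -> pd.DataFrame:
        if not self.has_features:
            raise CohortFormatError("cohort table carries no tcmf_* feature columns")
        return self.df[list(TCMF_COLUMNS)]

    def outcomes(self) -> tuple[np.ndarray, np.ndarray]:
        """(time in months, event indicator) arrays."""
        return (
            self.df["dfs_months"].to_numpy(float),
            self.df["event"].to_numpy(int),
        )

    def records(self) -> Iterator[PatientRecord]:
        for _, row in self.df.iterrows():
            feats = None
            if self.has_features:
                feats = row[list(TCMF_COLUMNS)].to_numpy(float)
            yield PatientRecord(
                patient_id=str(row["patient_id"]),
                cohort=str(row["cohort"]),
                dfs_months=float(row["dfs_months"]),
                event=int(row["event"]),
                clinical={c: str(row[c]) for c in CLINICAL_COLUMNS if c in row.index},
                tacs=tuple(int(row[c]) for c in TACS_COLUMNS),
                roi_features=feats,
            )


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing mandatory columns: {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise CohortFormatError(f"duplicate patient_id values: {sorted(set(dup.astype(str)))}")

    bad_rows: list[str] = []
    for i, row in df.iterrows():
        if str(row["cohort"]) not in COHORT_LABELS:
            bad_rows.append(f"row {i}: unknown cohort {row['cohort']!r}")
        try:
            ev = float(row["event"])
        except (TypeError, ValueError):
            ev = np.nan
        if ev not in (0.0, 1.0):
            bad_rows.append(f"row {i}: event must be 0 or 1, got {row['event']!r}")
        try:
            t = float(row["dfs_months"])
        except (TypeError, ValueError):
            t = np.nan
        if not np.isfinite(t) or t < 0:
            bad_rows.append(f"row {i}: dfs_months must be a finite number >= 0, got {row['dfs_months']!r}")
    if bad_rows:
        raise CohortFormatError("invalid rows:\n  " + "\n  ".join(bad_rows))

    for c in TACS_COLUMNS:
        if c in df.columns:
            vals = pd.to_numeric(df[c], errors="coerce")
            if not vals.isin([0, 1]).all():
                raise CohortFormatError(f"column {c} must be binary 0/1")


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort CSV, rejecting ill-typed rows with row numbers reported.

    Optional columns (tcmf features, precomputed scores) are permitted to be
    absent; mandatory columns are not.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    table = CohortTable(df)
    table.df["event"] = table.df["event"].astype(int)
    table.df["dfs_months"] = table.df["dfs_months"].astype(float)
    return table


def write_cohort(table: CohortTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)
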