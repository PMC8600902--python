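"""Patient-level aggregation and training-cohort Z-score normalization.

Per-ROI feature vectors are averaged (uniformly) over each patient's ROIs,
and the resulting per-patient features are standardized with means and
standard deviations estimated on the training cohort only; the stored
parameters are then applied unchanged to validation cohorts. Features that
are constant on the training cohort are dropped (recorded by name) rather
than divided by zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .registry import N_FEATURES, TCMF_COLUMNS, registry_hash
from .texture import TCMFVector


def aggregate_patient(vectors: list[TCMFVector]) -> TCMFVector:
    """Element-wise mean of one patient's per-ROI feature vectors."""
    if not vectors:
        raise ValueError("patient has no ROI feature vectors (exclude upstream)")
    pid = vectors[0].patient_id
    if any(v.patient_id != pid for v in vectors):
        raise ValueError("vectors belong to different patients")
    stacked = np.stack([v.values for v in vectors])
    return TCMFVector(values=stacked.mean(axis=0), roi_id="aggregate", patient_id=pid)


@dataclass
class NormalizationParams:
    means: dict[str, float]
    sds: dict[str, float]          # sample (n-1) standard deviations
    dropped: tuple[str, ...]       # zero-variance features, excluded downstream
    registry: str = field(default_factory=registry_hash)

    @property
    def kept(self) -> tuple[str, ...]:
        return tuple(self.means)

    def to_dict(self) -> dict:
        return {
            "means": self.means,
            "sds": self.sds,
            "dropped": list(self.dropped),
            "registry": self.registry,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            means=dict(d["means"]),
            sds=dict(d["sds"]),
            dropped=tuple(d["dropped"]),
            registry=d["registry"],
        )


def fit_normalizer(
    table: CohortTable, columns: tuple[str, ...] = TCMF_COLUMNS
) -> NormalizationParams:
    """Estimate per-feature standardization on the training rows only."""
    train = table.df[table.df["cohort"] == "training"]
    if train.empty:
        raise ValueError("no rows labeled 'training' to fit the normalizer on")
    means, sds, dropped = {}, {}, []
    for c in columns:
        x = train[c].to_numpy(float)
        sd = float(x.std(ddof=1))
        if sd == 0.0:
            dropped.append(c)
        else:
            means[c] = float(x.mean())
            sds[c] = sd
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance features: {dropped[:5]}...")
    return NormalizationParams(means=means, sds=sds, dropped=tuple(dropped))


def apply_normalizer(params: NormalizationParams, table: CohortTable) -> CohortTable:
    """Standardize any cohort with the stored training parameters.

    Dropped (zero-variance) feature columns are removed from the output.
    """
    if params.registry != registry_hash():
        raise ValueError("normalization parameters were fit under a different feature registry")
    df = table.df.copy()
    missing = [c for c in params.kept if c not in df.columns]
    if missing:
        raise ValueError(f"table lacks feature columns: {missing[:5]}...")
    for c in params.kept:
        df[c] = (df[c].astype(float) - params.means[c]) / params.sds[c]
    df = df.drop(columns=[c for c in params.dropped if c in df.columns])
    return CohortTable(df)


def features_to_table(
    vectors: list[TCMFVector], base: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per patient with tcmf_1..tcmf_142 columns from aggregated vectors."""
    rows = []
    for v in vectors:
        row = {"patient_id": v.patient_id}
        row.update({TCMF_COLUMNS[i]: v.values[i] for i in range(N_FEATURES)})
        rows.append(row)
    feats = pd.DataFrame(rows)
    if base is not None:
        return base.merge(feats, on="patient_id", how="inner")
    return feats
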