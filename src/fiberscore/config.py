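"""Run configuration: every downstream tunable with a documented default.

Serializes to and from a flat ``key = value`` text file so a run can be
reproduced from its logged configuration plus its seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .registry import (
    GABOR_FREQUENCIES,
    GABOR_ORIENTATIONS_DEG,
    GLCM_ANGLES_DEG,
    GLCM_DISPLACEMENTS,
)

log = logging.getLogger("fiberscore")


@dataclass
class RunConfig:
    # segmentation
    threshold_method: str = "otsu"          # between-class-variance criterion
    smoothing_sigma_um: float = 0.4         # Gaussian presmoothing before threshold
    # fiber network tracing
    spur_min_um: float = 3.0                # skeleton spurs shorter than this pruned
    fiber_min_um: float = 5.0               # traced fibers shorter than this discarded
    continuation_angle_deg: float = 20.0    # smooth-continuation merge at crosslinks
    # GLCM texture
    glcm_levels: int = 16
    glcm_displacements: tuple[int, ...] = GLCM_DISPLACEMENTS
    glcm_angles_deg: tuple[int, ...] = GLCM_ANGLES_DEG
    # Gabor bank
    gabor_frequencies: tuple[float, ...] = GABOR_FREQUENCIES
    gabor_orientations_deg: tuple[int, ...] = GABOR_ORIENTATIONS_DEG
    gabor_bandwidth: float = 1.0            # octaves
    mask_texture_to_collagen: bool = False  # texture on the raw ROI by default
    # model fitting
    lasso_cv_folds: int = 10
    lambda_rule: str = "1se"                # or "min"
    # evaluation
    roc_horizon_months: float = 60.0
    bootstrap_reps: int = 1000
    calibration_reps: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_rule not in ("1se", "min"):
            raise ValueError(f"lambda_rule must be '1se' or 'min', got {self.lambda_rule!r}")

    def log_resolved(self) -> None:
        """Log every resolved field (including the seed) for reproducibility."""
        for k, v in asdict(self).items():
            log.info("config %s = %r", k, v)

    def to_text(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value', got {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            default = getattr(cls(), key)
            if isinstance(default, bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(raw)
            elif isinstance(default, float):
                kwargs[key] = float(raw)
            elif isinstance(default, tuple):
                elem = type(default[0])
                kwargs[key] = tuple(elem(x) for x in raw.split(","))
            else:
                kwargs[key] = raw
        return cls(**kwargs)
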