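"""Registry of the 142 per-ROI collagen features.

The feature vector concatenates four families in a fixed order:

* 8 morphological features of the traced fiber network (area fraction,
  fiber number, mean length, mean width, mean straightness, crosslink
  density, crosslink spacing, orientation concentration);
* 6 first-order intensity-histogram statistics;
* 80 gray-level co-occurrence (GLCM) statistics: 4 statistics x 5 pixel
  displacements x 4 directions, names carry full provenance, e.g.
  ``glcm_contrast_d2_a90``;
* 48 Gabor filter-bank responses: 4 frequencies x 6 orientations x
  {mean, sd} of the magnitude response.

Cohort tables store these as columns ``tcmf_1`` .. ``tcmf_142`` in registry
order; :func:`feature_name` / :func:`feature_index` translate between the
positional column names and the descriptive names.
"""

from __future__ import annotations

MORPH_NAMES: tuple[str, ...] = (
    "morph_area_fraction",
    "morph_fiber_number",
    "morph_mean_length_um",
    "morph_mean_width_um",
    "morph_straightness",
    "morph_crosslink_density",
    "morph_crosslink_space_um",
    "morph_orientation_concentration",
)

HIST_NAMES: tuple[str, ...] = (
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_energy",
    "hist_entropy",
)

GLCM_STATS: tuple[str, ...] = ("contrast", "correlation", "energy", "homogeneity")
GLCM_DISPLACEMENTS: tuple[int, ...] = (1, 2, 3, 4, 5)
GLCM_ANGLES_DEG: tuple[int, ...] = (0, 45, 90, 135)

GABOR_FREQUENCIES: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)  # cycles / pixel
GABOR_ORIENTATIONS_DEG: tuple[int, ...] = (0, 30, 60, 90, 120, 150)


def _glcm_names() -> tuple[str, ...]:
    return tuple(
        f"glcm_{stat}_d{d}_a{a}"
        for stat in GLCM_STATS
        for d in GLCM_DISPLACEMENTS
        for a in GLCM_ANGLES_DEG
    )


def _gabor_names() -> tuple[str, ...]:
    return tuple(
        f"gabor_s{i + 1}_a{a}_{stat}"
        for i in range(len(GABOR_FREQUENCIES))
        for a in GABOR_ORIENTATIONS_DEG
        for stat in ("mean", "sd")
    )


GLCM_NAMES: tuple[str, ...] = _glcm_names()
GABOR_NAMES: tuple[str, ...] = _gabor_names()

FEATURE_NAMES: tuple[str, ...] = MORPH_NAMES + HIST_NAMES + GLCM_NAMES + GABOR_NAMES
N_FEATURES: int = len(FEATURE_NAMES)

TCMF_COLUMNS: tuple[str, ...] = tuple(f"tcmf_{i + 1}" for i in range(N_FEATURES))

_NAME_TO_INDEX = {name: i for i, name in enumerate(FEATURE_NAMES)}


def feature_index(name: str) -> int:
    """Zero-based registry position of a descriptive feature name."""
    return _NAME_TO_INDEX[name]


def feature_name(column: str) -> str:
    """Descriptive name for a positional cohort column such as ``tcmf_9``."""
    idx = int(column.removeprefix("tcmf_")) - 1
    return FEATURE_NAMES[idx]


def registry_hash() -> str:
    """Stable digest of the ordered name registry, stored with fitted models."""
    import hashlib

    return hashlib.sha256("\n".join(FEATURE_NAMES).encode()).hexdigest()[:16]
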