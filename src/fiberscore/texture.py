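"""The 134 textural features: histogram, GLCM, and Gabor families.

First-order statistics are computed from the normalized 256-bin intensity
histogram over the image's bit-depth range (observed range for float
images). Co-occurrence matrices are symmetric and normalized, built over a
uniform quantization of the observed min-max range (16 levels by default)
for five pixel displacements and four directions. The Gabor bank convolves
the mean-subtracted image (so the filters are DC-free) with complex
kernels at four frequencies and six orientations, one octave bandwidth,
and records the mean and standard deviation of the magnitude response.

Zero-variance conventions: a constant image has skewness = kurtosis = 0
and GLCM correlation = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel
from scipy.signal import fftconvolve

from .image import SHGImage
from .morphology import MorphFeatures
from .registry import (
    FEATURE_NAMES,
    GABOR_FREQUENCIES,
    GABOR_NAMES,
    GABOR_ORIENTATIONS_DEG,
    GLCM_ANGLES_DEG,
    GLCM_DISPLACEMENTS,
    GLCM_NAMES,
    GLCM_STATS,
    HIST_NAMES,
    N_FEATURES,
)


@dataclass
class TextureBank:
    histogram: np.ndarray  # 6 values, order of registry.HIST_NAMES
    glcm: np.ndarray       # 80 values, order of registry.GLCM_NAMES
    gabor: np.ndarray      # 48 values, order of registry.GABOR_NAMES

    def __post_init__(self) -> None:
        if len(self.histogram) != 6 or len(self.glcm) != 80 or len(self.gabor) != 48:
            raise ValueError("texture bank has wrong family sizes")
        values = self.to_array()
        if not np.all(np.isfinite(values)):
            raise ValueError("texture bank contains non-finite values")

    def to_array(self) -> np.ndarray:
        return np.concatenate([self.histogram, self.glcm, self.gabor])


@dataclass
class TCMFVector:
    """Ordered, named 142-feature record for one ROI (or patient average)."""

    values: np.ndarray
    roi_id: str = ""
    patient_id: str = ""
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if len(self.values) != N_FEATURES or self.names != FEATURE_NAMES:
            raise ValueError(f"feature vector must carry the {N_FEATURES}-name registry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def _intensity_range(image: SHGImage) -> tuple[float, float]:
    if np.issubdtype(image.pixels.dtype, np.integer):
        return 0.0, float(np.iinfo(image.pixels.dtype).max)
    lo, hi = float(image.pixels.min()), float(image.pixels.max())
    return (lo, hi) if hi > lo else (lo, lo + 1.0)


def histogram_features(image: SHGImage, bins: int = 256) -> np.ndarray:
    """Mean, variance, skewness, kurtosis, energy, entropy (in registry order).

    Moments are population moments of the raw intensities; energy and
    entropy are computed from the normalized histogram (entropy in bits).
    """
    x = image.pixels.astype(np.float64).ravel()
    mean = float(x.mean())
    var = float(x.var())
    if var > 0:
        z = (x - mean) / np.sqrt(var)
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = kurt = 0.0
    lo, hi = _intensity_range(image)
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts / counts.sum()
    energy = float(np.sum(p**2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz))) + 0.0
    return np.array([mean, var, skew, kurt, energy, entropy])


def quantize(image: SHGImage, levels: int) -> np.ndarray:
    """Uniform quantization of the observed min-max range to `levels` bins."""
    x = image.pixels.astype(np.float64)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x, dtype=np.uint8)
    q = np.floor((x - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm_matrix(
    quantized: np.ndarray, displacement: int, angle_deg: float, levels: int
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one (d, theta)."""
    p = graycomatrix(
        quantized,
        distances=[displacement],
        angles=[np.radians(angle_deg)],
        levels=levels,
        symmetric=True,
        normed=True,
    )
    return p[:, :, 0, 0]


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    levels = p.shape[0]
    i = np.arange(levels, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum((ii - jj) ** 2 * p))
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + (ii - jj) ** 2)))
    mu_i = float(np.sum(ii * p))
    mu_j = float(np.sum(jj * p))
    var_i = float(np.sum((ii - mu_i) ** 2 * p))
    var_j = float(np.sum((jj - mu_j) ** 2 * p))
    if var_i > 0 and var_j > 0:
        correlation = float(np.sum((ii - mu_i) * (jj - mu_j) * p) / np.sqrt(var_i * var_j))
    else:
        correlation = 0.0
    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
    }


def glcm_features(
    image: SHGImage,
    displacements: tuple[int, ...] = GLCM_DISPLACEMENTS,
    angles_deg: tuple[int, ...] = GLCM_ANGLES_DEG,
    levels: int = 16,
) -> np.ndarray:
    """All GLCM statistics, ordered statistic x displacement x direction."""
    if max(displacements) >= min(image.shape):
        raise ValueError("image smaller than the largest displacement")
    q = quantize(image, levels)
    stats: dict[tuple[int, int], dict[str, float]] = {}
    for d in displacements:
        for a in angles_deg:
            stats[(d, a)] = _glcm_stats(glcm_matrix(q, d, a, levels))
    return np.array(
        [stats[(d, a)][s] for s in GLCM_STATS for d in displacements for a in angles_deg]
    )


def _gabor_magnitude(x: np.ndarray, frequency: float, theta_rad: float, bandwidth: float) -> np.ndarray:
    # complex FFT convolution on a reflect-padded image: equivalent to
    # spatial convolution with reflect boundaries, much faster for the
    # large low-frequency kernels
    kernel = gabor_kernel(frequency, theta=theta_rad, bandwidth=bandwidth)
    pr, pc = kernel.shape[0] // 2, kernel.shape[1] // 2
    pr, pc = min(pr, x.shape[0] - 1), min(pc, x.shape[1] - 1)
    padded = np.pad(x, ((pr, pr), (pc, pc)), mode="symmetric")
    out = fftconvolve(padded, kernel, mode="same")
    return np.abs(out[pr : pr + x.shape[0], pc : pc + x.shape[1]])


def gabor_features(
    image: SHGImage,
    frequencies: tuple[float, ...] = GABOR_FREQUENCIES,
    orientations_deg: tuple[int, ...] = GABOR_ORIENTATIONS_DEG,
    bandwidth: float = 1.0,
) -> np.ndarray:
    """Mean and sd of the magnitude response per (frequency, orientation).

    The image mean is subtracted before filtering, making the effective
    filters DC-free: a constant image responds (numerically) zero.
    """
    if max(frequencies) > 0.5:
        raise ValueError("Gabor frequency above Nyquist (0.5 cycles/pixel)")
    x = image.pixels.astype(np.float64)
    x = x - x.mean()
    out = []
    for f in frequencies:
        for a in orientations_deg:
            mag = _gabor_magnitude(x, f, np.radians(a), bandwidth)
            out.extend([float(mag.mean()), float(mag.std())])
    return np.array(out)


def assemble_tcmf(
    morph: MorphFeatures,
    bank: TextureBank,
    roi_id: str = "",
    patient_id: str = "",
) -> TCMFVector:
    """Concatenate the four families into the ordered 142-feature vector."""
    values = np.concatenate([morph.to_array(), bank.to_array()])
    return TCMFVector(values=values, roi_id=roi_id, patient_id=patient_id)
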