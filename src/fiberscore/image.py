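"""SHG region-of-interest images: container plus TIFF reader/writer.

A region of interest (ROI) is a single-channel intensity image of a fixed
physical field of view. The default geometry is a 150 um x 150 um field
sampled on a 512 x 512 grid (0.293 um per pixel); the simulator and the
feature extractors both honour ``pixel_size_um`` so other samplings are
equally valid.

Conventions: pixel coordinates are 0-based row-major with the origin at the
top-left; fiber orientations are measured counter-clockwise from the +x
axis in degrees on [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

FIELD_OF_VIEW_UM: float = 150.0
DEFAULT_IMAGE_SIZE_PX: int = 512
DEFAULT_PIXEL_SIZE_UM: float = FIELD_OF_VIEW_UM / DEFAULT_IMAGE_SIZE_PX

MIN_SIDE_PX = 16


class ImageFormatError(ValueError):
    """Raised when an input image violates the ROI contract."""


@dataclass
class SHGImage:
    """A single-channel SHG ROI with its physical pixel size.

    Attributes
    ----------
    pixels : 2D float array, non-negative intensities.
    pixel_size_um : edge length of one pixel in micrometres.
    id : ROI identifier.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ImageFormatError(
                f"ROI must be a single-plane grayscale image, got shape {self.pixels.shape}"
            )
        if min(self.pixels.shape) < MIN_SIDE_PX:
            raise ImageFormatError(
                f"ROI must be at least {MIN_SIDE_PX} px per side, got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ImageFormatError("ROI contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ImageFormatError("ROI contains negative intensities")
        if not self.pixel_size_um > 0:
            raise ImageFormatError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical extent (height, width) in micrometres."""
        return (
            self.pixels.shape[0] * self.pixel_size_um,
            self.pixels.shape[1] * self.pixel_size_um,
        )


def read_shg_image(
    path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM, roi_id: str | None = None
) -> SHGImage:
    """Read a grayscale single-plane TIFF as an :class:`SHGImage`.

    Intensities are returned exactly as stored (no rescaling). Multi-channel
    or RGB TIFFs are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pixels = tifffile.imread(path)
    if pixels.ndim != 2:
        raise ImageFormatError(
            f"{path.name}: expected a grayscale single-plane TIFF, got shape {pixels.shape}"
        )
    return SHGImage(
        pixels=pixels.astype(np.float64),
        pixel_size_um=pixel_size_um,
        id=roi_id if roi_id is not None else path.stem,
    )


def write_shg_image(image: SHGImage, path: str | Path, dtype: str = "uint16") -> None:
    """Write an ROI as an 8- or 16-bit grayscale TIFF.

    Intensities are clipped to the dtype range and rounded; callers keeping
    float data for round-trip fidelity should render within that range.
    """
    if dtype not in ("uint8", "uint16"):
        raise ValueError(f"dtype must be uint8 or uint16, got {dtype}")
    info = np.iinfo(dtype)
    data = np.clip(np.round(image.pixels), info.min, info.max).astype(dtype)
    tifffile.imwrite(Path(path), data)
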