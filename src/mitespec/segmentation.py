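"""Leaf/background segmentation: NDVI thresholding plus edge erosion.

Leaves are imaged on a dark, spectrally flat plate, so the normalized
difference vegetation index NDVI = (NIR - Red) / (NIR + Red) separates
vegetation (high NDVI) from background (near zero).  Thresholding the
NDVI image yields a leaf mask; a binary erosion with a square structuring
element then drops the leaf-edge pixels whose spectra mix leaf and
background.  The surviving pixels form the region of interest (ROI).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .cube_io import HyperCube

__all__ = [
    "SegmentationParams",
    "ROI",
    "EmptyROIError",
    "ndvi_map",
    "threshold_mask",
    "erode",
    "make_roi",
    "mask_to_png",
]


class EmptyROIError(ValueError):
    """Raised when segmentation leaves no leaf pixels."""


@dataclass(frozen=True)
class SegmentationParams:
    """NDVI band choice, threshold and erosion size.

    The defaults (red 670 nm, NIR 798 nm, threshold 0.5, 3x3 erosion)
    are canonical NDVI bands that fall on the 502-950 nm / 4 nm grid and
    separate leaf tissue from a dark plate with a wide margin.
    """

    red_nm: float = 670.0
    nir_nm: float = 798.0
    ndvi_threshold: float = 0.5
    erosion_size: int = 3

    def __post_init__(self) -> None:
        if not -1.0 < self.ndvi_threshold < 1.0:
            raise ValueError("ndvi_threshold must lie in (-1, 1)")
        if self.erosion_size < 1 or self.erosion_size % 2 == 0:
            raise ValueError("erosion_size must be odd and >= 1")


@dataclass(frozen=True)
class ROI:
    """Boolean leaf mask after thresholding and erosion."""

    mask: np.ndarray

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def ndvi_map(cube: HyperCube, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Per-pixel NDVI image in [-1, 1]; 0/0 pixels map to 0 by convention."""
    red = cube.band(params.red_nm).astype(np.float64)
    nir = cube.band(params.nir_nm).astype(np.float64)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        ndvi = np.where(denom == 0, 0.0, (nir - red) / np.where(denom == 0, 1.0, denom))
    return ndvi


def threshold_mask(ndvi_image: np.ndarray, t: float) -> np.ndarray:
    """Boolean mask of pixels with NDVI strictly greater than ``t``."""
    if not -1.0 < t < 1.0:
        raise ValueError("threshold must lie in (-1, 1)")
    return np.asarray(ndvi_image) > t


def erode(mask: np.ndarray, size: int = 3) -> np.ndarray:
    """Binary erosion with a size x size all-ones structuring element.

    A pixel survives only if its whole neighbourhood is inside the mask;
    positions outside the image count as background, so a border pixel
    can never survive with size >= 3.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("erosion size must be odd and >= 1")
    if size == 1:
        return np.asarray(mask, dtype=bool).copy()
    structure = np.ones((size, size), dtype=bool)
    return ndimage.binary_erosion(np.asarray(mask, dtype=bool), structure=structure,
                                  border_value=0)


def make_roi(cube: HyperCube, params: SegmentationParams = SegmentationParams()) -> ROI:
    """NDVI threshold followed by erosion; errors out on an empty result."""
    mask = threshold_mask(ndvi_map(cube, params), params.ndvi_threshold)
    eroded = erode(mask, params.erosion_size)
    if not eroded.any():
        raise EmptyROIError(
            "no leaf pixels: NDVI thresholding + erosion produced an empty ROI"
        )
    return ROI(eroded)


def mask_to_png(mask: np.ndarray, path: str | Path) -> Path:
    """Export a boolean mask as an 8-bit PNG (background 0, mask 255)."""
    from PIL import Image

    path = Path(path)
    img = Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))
    img.save(path)
    return path
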