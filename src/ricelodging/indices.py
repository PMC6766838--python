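"""Vegetation indices and index stacks for network input.

Two families of per-pixel band-arithmetic indices are supported:

visible (needs R, G, B)
    ExG = 2g - r - b, ExR = 1.4r - g, ExGR = ExG - ExR (on chromatic
    coordinates r = R/(R+G+B) etc.), VDVI = (2G-R-B)/(2G+R+B), RGRI = R/G,
    NGRDI = (G-R)/(G+R) (on raw band values).

multispectral (needs R, G, NIR)
    NDVI = (NIR-R)/(NIR+R), RVI = NIR/R, NDWI = (G-NIR)/(G+NIR),
    DVI = NIR - R, PVI = (NIR - 10.489 R - 6.604)/sqrt(1 + 10.489^2) with the
    soil-line coefficients a=10.489, b=6.604, and SAVI = (1 + L)(NIR-R)/
    (NIR+R+L) with the soil-adjustment factor L = 0.5.

ExG/ExR/ExGR deliberately use the normalized chromatic coordinates while the
rest use raw band values, following the usual definitions of their sources.
Pixels with a zero denominator yield 0 rather than NaN so stacked inputs stay
finite.  Stacks for the network are depth 3 (ExG, ExR, VDVI or NDVI, RVI,
NDWI) or depth 6 (the full family), each channel min-max normalized to [0, 1]
over the image; unbounded indices such as RVI and DVI need this rescaling for
stable training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .raster_io import BandImage

logger = logging.getLogger(__name__)

__all__ = [
    "IndexStack", "compute_index", "build_stack",
    "VISIBLE_INDICES", "MULTISPECTRAL_INDICES",
    "VISIBLE_TRIPLE", "MULTISPECTRAL_TRIPLE",
]

VISIBLE_INDICES = ("ExG", "ExR", "VDVI", "RGRI", "NGRDI", "ExGR")
MULTISPECTRAL_INDICES = ("NDVI", "RVI", "NDWI", "DVI", "PVI", "SAVI")
VISIBLE_TRIPLE = ("ExG", "ExR", "VDVI")
MULTISPECTRAL_TRIPLE = ("NDVI", "RVI", "NDWI")

_PVI_A = 10.489
_PVI_B = 6.604
_SAVI_L = 0.5


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=out, where=den != 0)
    return out


def _chromatic(image: BandImage):
    r_raw = image.band("R")
    g_raw = image.band("G")
    b_raw = image.band("B")
    total = r_raw + g_raw + b_raw
    return (_safe_div(r_raw, total), _safe_div(g_raw, total),
            _safe_div(b_raw, total))


def compute_index(image: BandImage, name: str) -> np.ndarray:
    """Evaluate one vegetation index per pixel; returns a float64 H x W map."""
    if name in ("ExG", "ExR", "ExGR"):
        r, g, b = _chromatic(image)
        if name == "ExG":
            return 2 * g - r - b
        if name == "ExR":
            return 1.4 * r - g
        return (2 * g - r - b) - (1.4 * r - g)  # ExGR = ExG - ExR
    if name == "VDVI":
        r, g, b = image.band("R"), image.band("G"), image.band("B")
        return _safe_div(2 * g - r - b, 2 * g + r + b)
    if name == "RGRI":
        return _safe_div(image.band("R"), image.band("G"))
    if name == "NGRDI":
        r, g = image.band("R"), image.band("G")
        return _safe_div(g - r, g + r)
    if name == "NDVI":
        nir, r = image.band("NIR"), image.band("R")
        return _safe_div(nir - r, nir + r)
    if name == "RVI":
        return _safe_div(image.band("NIR"), image.band("R"))
    if name == "NDWI":
        g, nir = image.band("G"), image.band("NIR")
        return _safe_div(g - nir, g + nir)
    if name == "DVI":
        return image.band("NIR") - image.band("R")
    if name == "PVI":
        nir, r = image.band("NIR"), image.band("R")
        return (nir - _PVI_A * r - _PVI_B) / np.sqrt(1 + _PVI_A ** 2)
    if name == "SAVI":
        nir, r = image.band("NIR"), image.band("R")
        return (1 + _SAVI_L) * _safe_div(nir - r, nir + r + _SAVI_L)
    raise KeyError(f"unknown vegetation index {name!r}")


@dataclass
class IndexStack:
    """An H x W x D stack of normalized vegetation indices (D = 3 or 6)."""

    pixels: np.ndarray
    index_names: tuple[str, ...]
    norm_bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise ValueError("stack must be H x W x D")
        if len(self.index_names) != self.pixels.shape[2]:
            raise ValueError("one name per stack channel required")
        if len(self.norm_bounds) != len(self.index_names):
            raise ValueError("one (min, max) record per channel required")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def depth(self) -> int:
        return self.pixels.shape[2]


def build_stack(image: BandImage, mode: Literal["three", "six"] = "three"
                ) -> IndexStack:
    """Stack vegetation indices as network input channels.

    The channel family is chosen from the image's bands: R/G/B imagery gets
    the visible family, R/G/NIR imagery the multispectral family.  mode
    "three" selects (ExG, ExR, VDVI) or (NDVI, RVI, NDWI); "six" the full
    family.  Each channel is min-max normalized to [0, 1] over this image and
    the bounds are recorded; a constant channel is set to zeros with a
    warning.
    """
    if mode not in ("three", "six"):
        raise ValueError(f"mode must be 'three' or 'six', got {mode!r}")
    if "NIR" in image.channel_names:
        names = MULTISPECTRAL_TRIPLE if mode == "three" else MULTISPECTRAL_INDICES
    elif "B" in image.channel_names:
        names = VISIBLE_TRIPLE if mode == "three" else VISIBLE_INDICES
    else:
        raise ValueError(
            f"image channels {image.channel_names} fit neither index family")
    chans, bounds = [], []
    for name in names:
        raw = compute_index(image, name)
        lo, hi = float(raw.min()), float(raw.max())
        if hi == lo:
            logger.warning("index %s is constant (%g); channel zeroed", name, lo)
            chans.append(np.zeros_like(raw, dtype=np.float32))
        else:
            chans.append(((raw - lo) / (hi - lo)).astype(np.float32))
        bounds.append((lo, hi))
    return IndexStack(np.stack(chans, axis=2), tuple(names), tuple(bounds))
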