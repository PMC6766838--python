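"""Raster and polygon I/O for canopy imagery.

Conventions
-----------
Arrays are ``(H, W)`` or ``(H, W, C)`` with row 0 at the top.  Polygon
vertices are ``(row, col)`` pairs in pixel-corner coordinates: the pixel at
index ``(r, c)`` covers the square ``[r, r+1) x [c, c+1)`` and its center sits
at ``(r + 0.5, c + 0.5)``.  Rasterization uses strict pixel-center containment.

Images are PNG or TIFF.  8-bit data is kept on the 0-255 scale
(``value_scale="8bit"``); floating-point data must lie in [0, 1]
(``value_scale="unit"``).  Binary masks are written as 8-bit single-channel
PNGs with lodged pixels white (255).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import tifffile
from PIL import Image
from shapely.geometry import Polygon as _ShapelyPolygon

VALID_CHANNELS = ("R", "G", "B", "NIR")

__all__ = [
    "BandImage",
    "BinaryMask",
    "PolygonMark",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "load_marks",
    "save_marks",
    "rasterize_polygon",
]


@dataclass
class BandImage:
    """A multiband raster with named channel semantics.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, C)
        Raster data.  ``uint8`` for 8-bit imagery, floating point in [0, 1]
        for unit-scale imagery.
    channel_names : tuple of str
        Ordered names drawn from {"R", "G", "B", "NIR"}; length must equal C.
    value_scale : {"8bit", "unit"}
        Declared value range: 0-255 integers or the unit interval.
    meta : dict, optional
        Opaque geo-metadata passthrough (not interpreted).
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    value_scale: str = "8bit"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValueError(f"pixels must be (H, W, C), got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must have H >= 1 and W >= 1")
        self.pixels = px
        self.channel_names = tuple(self.channel_names)
        for name in self.channel_names:
            if name not in VALID_CHANNELS:
                raise ValueError(f"unknown channel name {name!r}")
        if len(self.channel_names) != px.shape[2]:
            raise ValueError(
                f"{px.shape[2]} channels but {len(self.channel_names)} names"
            )
        if self.value_scale not in ("8bit", "unit"):
            raise ValueError(f"unknown value_scale {self.value_scale!r}")
        if self.value_scale == "8bit":
            if px.min() < 0 or px.max() > 255:
                raise ValueError("8bit image values must lie in [0, 255]")
        else:
            if px.min() < 0.0 or px.max() > 1.0:
                raise ValueError("unit-scale image values must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]

    def band(self, name: str) -> np.ndarray:
        """Return one channel as float64 on the stored scale."""
        if name not in self.channel_names:
            raise KeyError(f"image has no {name!r} channel ({self.channel_names})")
        return self.pixels[:, :, self.channel_names.index(name)].astype(np.float64)

    def as_unit(self) -> np.ndarray:
        """Pixels as float32 scaled to [0, 1]."""
        px = self.pixels.astype(np.float32)
        if self.value_scale == "8bit":
            px = px / 255.0
        return px


@dataclass
class BinaryMask:
    """An H x W lodging mask with values in {0, 1}; 1 = lodged."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, found {vals[:8]}")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_fraction(self) -> float:
        return float(self.pixels.mean())


@dataclass
class PolygonMark:
    """A closed polygonal region of interest ("mark") in (row, col) coordinates."""

    vertices: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        verts = [(float(r), float(c)) for r, c in self.vertices]
        # drop an explicit closing vertex
        if len(verts) > 1 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len({v for v in verts}) < 3:
            raise ValueError("polygon needs at least 3 distinct vertices")
        poly = _ShapelyPolygon([(c, r) for r, c in verts])  # shapely is (x, y)
        if not poly.is_valid or poly.area == 0.0:
            raise ValueError("degenerate or self-intersecting polygon")
        self.vertices = verts
        self._poly = poly

    @property
    def shapely(self) -> _ShapelyPolygon:
        return self._poly


# ---------------------------------------------------------------------------
# image / mask files


def _to_bandimage(arr: np.ndarray, channel_names, expected_channels, path) -> BandImage:
    if arr.ndim == 2:
        arr = arr[:, :, None]
    n = arr.shape[2]
    if expected_channels is not None and n != expected_channels:
        raise ValueError(
            f"{path}: expected {expected_channels} channels, file has {n}"
        )
    if channel_names is None:
        if n == 3:
            channel_names = ("R", "G", "B")
        elif n == 1:
            channel_names = ("G",)
        else:
            raise ValueError(f"{path}: channel_names required for {n}-channel image")
    if arr.dtype == np.uint8:
        return BandImage(arr, channel_names, "8bit")
    if arr.dtype == np.uint16:
        # 16-bit TIFF: rescale onto the unit interval
        return BandImage(arr.astype(np.float32) / 65535.0, channel_names, "unit")
    if np.issubdtype(arr.dtype, np.floating):
        return BandImage(arr.astype(np.float32), channel_names, "unit")
    raise ValueError(f"{path}: unsupported bit depth / dtype {arr.dtype}")


def read_image(path, expected_channels: int | None = None,
               channel_names: tuple[str, ...] | None = None) -> BandImage:
    """Read a PNG or TIFF multiband image.

    ``channel_names`` defaults to ("R", "G", "B") for 3-channel files; pass
    ``("R", "G", "NIR")`` for RGN imagery.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[0] in (1, 2, 3, 4, 6) and arr.shape[0] < arr.shape[2]:
            arr = np.moveaxis(arr, 0, 2)  # planar TIFF
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"{path}: unsupported format {suffix!r} (PNG/TIFF only)")
    return _to_bandimage(arr, channel_names, expected_channels, path)


def write_image(image: BandImage, path) -> None:
    """Write a BandImage; PNG for 8-bit up to 3 channels, TIFF otherwise."""
    path = Path(path)
    suffix = path.suffix.lower()
    px = image.pixels
    if suffix == ".png":
        if image.value_scale != "8bit":
            raise ValueError("PNG output requires 8-bit data")
        arr = px.astype(np.uint8)
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        Image.fromarray(arr).save(path)
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, px.astype(px.dtype))
    else:
        raise ValueError(f"{path}: unsupported format {suffix!r}")


def write_mask(mask: BinaryMask, path) -> None:
    """Write a binary mask as an 8-bit PNG/TIFF, lodged pixels white (255)."""
    if not isinstance(mask, BinaryMask):
        mask = BinaryMask(mask)
    path = Path(path)
    arr = (mask.pixels * np.uint8(255)).astype(np.uint8)
    if path.suffix.lower() == ".png":
        Image.fromarray(arr, mode="L").save(path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        raise ValueError(f"{path}: unsupported mask format")


def read_mask(path) -> BinaryMask:
    """Read a mask written by :func:`write_mask` (white = lodged)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    return BinaryMask((arr > 127).astype(np.uint8))


# ---------------------------------------------------------------------------
# polygon markers


def save_marks(marks: Sequence[PolygonMark], path) -> None:
    data = {"polygons": [[list(v) for v in m.vertices] for m in marks]}
    Path(path).write_text(json.dumps(data, indent=1))


def load_marks(path) -> list[PolygonMark]:
    """Load polygon marker(s) from a JSON vertex-list file.

    Accepts ``{"polygons": [[[r, c], ...], ...]}``, ``{"vertices": [[r, c], ...]}``
    or a bare list of vertices.
    """
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict) and "polygons" in data:
        rings = data["polygons"]
    elif isinstance(data, dict) and "vertices" in data:
        rings = [data["vertices"]]
    elif isinstance(data, list):
        rings = [data]
    else:
        raise ValueError(f"{path}: unrecognized marker structure")
    return [PolygonMark([tuple(v) for v in ring]) for ring in rings]


def rasterize_polygon(mark: PolygonMark, height: int, width: int) -> BinaryMask:
    """Rasterize a polygon mark onto an ``height x width`` grid.

    A pixel is set when its center ``(r + 0.5, c + 0.5)`` lies strictly inside
    the polygon; parts of the polygon outside the grid are clipped away by
    construction.
    """
    if not isinstance(mark, PolygonMark):
        mark = PolygonMark(mark)
    rows = np.arange(height) + 0.5
    cols = np.arange(width) + 0.5
    cc, rr = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(mark.shapely, cc.ravel(), rr.ravel())
    return BinaryMask(inside.reshape(height, width).astype(np.uint8))
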