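"""Whole-scene inference by sliding-window tiling.

Mosaics are far larger than the training crops and their sides are rarely
multiples of 16, so the scene is traversed with non-overlapping 1280 x 1280
windows (stride = window, no blending).  Windows that run past the image
edge are zero-filled, predicted, and the part beyond the image discarded.
The stitched probability map is thresholded at 0.5 — strictly greater than
0.5 counts as lodged — giving the binary lodging map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indices import IndexStack
from .raster_io import BandImage, BinaryMask
from .training import dice
from .unet import UNet

__all__ = ["TileSpec", "TilePlacement", "plan_tiles", "predict_scene",
           "scene_dice"]


@dataclass(frozen=True)
class TileSpec:
    """Sliding-window policy: window size, zero fill, strict 0.5 threshold."""

    window: int = 1280
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 16 or self.window % 16:
            raise ValueError("window must be a positive multiple of 16")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")


@dataclass(frozen=True)
class TilePlacement:
    """One window anchored at (row0, col0); valid_h/valid_w give the unpadded
    extent (smaller than the window only on bottom/right edge tiles)."""

    row0: int
    col0: int
    valid_h: int
    valid_w: int


def plan_tiles(height: int, width: int, spec: TileSpec = TileSpec()
               ) -> list[TilePlacement]:
    """Non-overlapping window grid covering the image.

    ceil(H/window) x ceil(W/window) placements; every pixel belongs to
    exactly one placement's valid region.
    """
    if height < 1 or width < 1:
        raise ValueError("image dimensions must be positive")
    win = spec.window
    tiles = []
    for r0 in range(0, height, win):
        for c0 in range(0, width, win):
            tiles.append(TilePlacement(
                r0, c0, min(win, height - r0), min(win, width - c0)))
    return tiles


def _scene_array(image) -> np.ndarray:
    """Network-ready (C, H, W) float32 array from a BandImage or IndexStack."""
    if isinstance(image, BandImage):
        px = image.as_unit()
    elif isinstance(image, IndexStack):
        px = image.pixels.astype(np.float32)
    else:
        px = np.asarray(image, dtype=np.float32)
        if px.ndim == 2:
            px = px[:, :, None]
    return px.transpose(2, 0, 1)


def predict_scene(net: UNet, image, spec: TileSpec = TileSpec()
                  ) -> tuple[np.ndarray, BinaryMask]:
    """Segment an arbitrarily sized scene.

    Each window is predicted independently (eval mode); zero fill is applied
    after scaling to the unit interval, so padding is the normalized zero.
    Returns the stitched H x W probability map and its thresholded mask.
    """
    arr = _scene_array(image)
    c, h, w = arr.shape
    if c != net.config.in_channels:
        raise ValueError(
            f"scene has {c} channels but network expects "
            f"{net.config.in_channels}")
    win = spec.window
    prob = np.empty((h, w), dtype=np.float32)
    for tile in plan_tiles(h, w, spec):
        window = np.zeros((1, c, win, win), dtype=np.float32)
        window[0, :, :tile.valid_h, :tile.valid_w] = arr[
            :, tile.row0:tile.row0 + tile.valid_h,
            tile.col0:tile.col0 + tile.valid_w]
        out = net.forward(window, train=False)[0, 0]
        prob[tile.row0:tile.row0 + tile.valid_h,
             tile.col0:tile.col0 + tile.valid_w] = \
            out[:tile.valid_h, :tile.valid_w]
    mask = BinaryMask((prob > spec.threshold).astype(np.uint8))
    return prob, mask


def scene_dice(pred: BinaryMask, gt: BinaryMask) -> float:
    """Dice between a stitched scene prediction and its reference mask."""
    return dice(pred, gt)
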