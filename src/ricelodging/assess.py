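"""Lodging-ratio damage assessment inside a marked field polygon.

A surveyor outlines the field of interest as one or more polygons (the
"mark"); the lodging ratio is the percentage of pixels inside the mark that
the segmentation classifies as lodged.  The ratio feeds damage assessment,
e.g. agricultural-insurance claims.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .raster_io import BinaryMask, PolygonMark, rasterize_polygon

__all__ = ["AssessmentReport", "lodging_ratio", "mark_mask"]


@dataclass(frozen=True)
class AssessmentReport:
    """Lodging assessment of one marked field."""

    field_id: str
    total_pixels: int
    lodged_pixels: int
    lodging_ratio: float  # percent, 2 decimal places

    def __post_init__(self) -> None:
        if self.lodged_pixels > self.total_pixels:
            raise ValueError("lodged_pixels cannot exceed total_pixels")
        if not 0.0 <= self.lodging_ratio <= 100.0:
            raise ValueError("lodging_ratio must be a percentage in [0, 100]")

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def mark_mask(marks: PolygonMark | Sequence[PolygonMark],
              height: int, width: int) -> BinaryMask:
    """Rasterize one mark or the union of several onto the prediction grid.

    Multiple disjoint polygons are allowed (multi-parcel fields); their
    rasterized union is the candidate area.
    """
    if isinstance(marks, PolygonMark):
        marks = [marks]
    if not marks:
        raise ValueError("at least one polygon mark required")
    union = np.zeros((height, width), dtype=np.uint8)
    for m in marks:
        union |= rasterize_polygon(m, height, width).pixels
    return BinaryMask(union)


def lodging_ratio(pred: BinaryMask, marks: PolygonMark | Sequence[PolygonMark],
                  field_id: str = "field") -> AssessmentReport:
    """Percentage of the marked area predicted lodged.

    ratio = 100 * |pred AND mark| / |mark|, reported to two decimal places.
    Pixels outside the mark never affect the result.
    """
    region = mark_mask(marks, *pred.shape).pixels.astype(bool)
    total = int(region.sum())
    if total == 0:
        raise ValueError("mark rasterizes to an empty region")
    lodged = int((pred.pixels.astype(bool) & region).sum())
    return AssessmentReport(field_id, total, lodged,
                            round(100.0 * lodged / total, 2))
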