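"""Row-coordinate conventions and geometric scoring primitives.

Everything in this package lives on the vertical axis of an
anterior-posterior scout view (topogram): row 0 is the most cranial row,
indices increase caudally, and one row covers ``row_spacing_mm``
millimetres (1.0 mm for the cohorts this models, since scout views with
any other pixel spacing are excluded). The pulmonary-trunk band is a
half-open integer interval of rows, ``[start_row, end_row)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ScoutImage",
    "Region",
    "RegionAnnotation",
    "RegionPrediction",
    "AnnotationSource",
    "region_mask",
    "extract_region",
    "region_center",
    "iou_1d",
    "slice_hit",
    "distance_to_region",
    "row_distance_mm",
    "ct_slice_span_to_rows",
]


class AnnotationSource(str, Enum):
    GROUND_TRUTH = "ground_truth"
    PREDICTED = "predicted"


@dataclass(frozen=True)
class Region:
    """Half-open row interval ``[start_row, end_row)``; cranial boundary first."""

    start_row: int
    end_row: int

    def __post_init__(self) -> None:
        if not (0 <= self.start_row < self.end_row):
            raise ValueError(
                f"invalid region [{self.start_row}, {self.end_row}): "
                "need 0 <= start_row < end_row"
            )

    def __len__(self) -> int:
        return self.end_row - self.start_row

    def contains(self, row: int) -> bool:
        return self.start_row <= row < self.end_row


@dataclass(frozen=True)
class RegionAnnotation:
    """A pulmonary-trunk band plus the reference-standard row inside it."""

    region: Region
    reference_row: int
    source: AnnotationSource = AnnotationSource.GROUND_TRUTH

    def __post_init__(self) -> None:
        if not self.region.contains(self.reference_row):
            raise ValueError(
                f"reference_row {self.reference_row} outside region "
                f"[{self.region.start_row}, {self.region.end_row})"
            )


@dataclass
class ScoutImage:
    """2D grayscale projection image, rows indexed cranial (0) to caudal."""

    pixels: np.ndarray
    row_spacing_mm: float = 1.0
    case_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a non-empty 2D array (rows x cols)")
        if not self.row_spacing_mm > 0:
            raise ValueError("row_spacing_mm must be positive")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class RegionPrediction:
    """Per-row scores with the band and centre row derived from them."""

    scores: np.ndarray
    region: Region
    center_row: int
    threshold: float = 0.5

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("scores must be a non-empty 1D vector")
        if self.region != extract_region(scores, self.threshold):
            raise ValueError("region is not derivable from scores at threshold")
        if not self.region.contains(self.center_row):
            raise ValueError("center_row outside region")


def region_mask(annotation: RegionAnnotation, n_rows: int) -> np.ndarray:
    """Binary per-row training target: 1 inside the band, 0 elsewhere."""
    region = annotation.region
    if region.end_row > n_rows:
        raise ValueError(
            f"region [{region.start_row}, {region.end_row}) exceeds {n_rows} rows"
        )
    mask = np.zeros(n_rows, dtype=np.float32)
    mask[region.start_row : region.end_row] = 1.0
    return mask


def _runs_at_or_above(scores: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    above = scores >= threshold
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(above)))
    return runs


def extract_region(scores: Sequence[float] | np.ndarray, threshold: float = 0.5) -> Region:
    """Longest run of rows with score >= threshold.

    Ties on run length go to the run with the higher mean score, then to
    the more cranial start. If no row reaches the threshold the single
    arg-max row is returned (smallest index on ties) so a prediction
    always yields a band.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores must be a non-empty 1D vector")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly between 0 and 1")
    runs = _runs_at_or_above(scores, threshold)
    if not runs:
        peak = int(np.argmax(scores))
        return Region(peak, peak + 1)
    # (length, mean score, -start) lexicographic maximum
    best = max(runs, key=lambda r: (r[1] - r[0], float(scores[r[0] : r[1]].mean()), -r[0]))
    return Region(*best)


def region_center(region: Region) -> int:
    """Centre row of the band, floor of the midpoint of the contained rows."""
    return (region.start_row + region.end_row - 1) // 2


def iou_1d(a: Region, b: Region) -> float:
    """Intersection-over-union of two row intervals, in [0, 1]."""
    inter = min(a.end_row, b.end_row) - max(a.start_row, b.start_row)
    if inter <= 0:
        return 0.0
    union = len(a) + len(b) - inter
    return inter / union


def slice_hit(row: int, region: Region) -> bool:
    """Whether the selected row falls inside the annotated band."""
    if row < 0:
        raise ValueError("row must be non-negative")
    return region.contains(row)


def distance_to_region(row: int, region: Region, row_spacing_mm: float = 1.0) -> float:
    """Distance in mm from a row to the nearest row contained in the band (0 inside)."""
    if row_spacing_mm <= 0:
        raise ValueError("row_spacing_mm must be positive")
    if slice_hit(row, region):
        return 0.0
    if row < region.start_row:
        gap = region.start_row - row
    else:
        gap = row - (region.end_row - 1)
    return gap * row_spacing_mm


def row_distance_mm(row_a: int, row_b: int, row_spacing_mm: float = 1.0) -> float:
    """Absolute distance between two rows in mm."""
    if row_spacing_mm <= 0:
        raise ValueError("row_spacing_mm must be positive")
    return abs(row_a - row_b) * row_spacing_mm


def ct_slice_span_to_rows(
    slice_lo: int,
    slice_hi: int,
    slice_thickness_mm: float = 5.0,
    origin_row: int = 0,
    row_spacing_mm: float = 1.0,
) -> Region:
    """Map an inclusive span of axial CT slices onto scout rows.

    Slice *i* occupies physical height ``[i*t, (i+1)*t)`` mm below the
    origin row; boundaries are rounded half-up to the nearest row.
    """
    if slice_lo > slice_hi:
        raise ValueError("slice_lo must not exceed slice_hi")
    if slice_thickness_mm <= 0 or row_spacing_mm <= 0:
        raise ValueError("thickness and spacing must be positive")
    scale = slice_thickness_mm / row_spacing_mm
    start = origin_row + int(np.floor(slice_lo * scale + 0.5))
    end = origin_row + int(np.floor((slice_hi + 1) * scale + 0.5))
    if end <= start:
        raise ValueError("slice span collapses to an empty region after rounding")
    return Region(start, end)
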