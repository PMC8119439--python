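"""Cohort-level evaluation of slice selections and radiologist judgements.

Four prediction-quality measures are reported for a cohort of selected
bolus-tracking slices: slice-hit accuracy (selected row inside the
annotated pulmonary-trunk band), the error distance to the nearest band
boundary over the missed cases only, the distance to the
reference-standard slice over all cases, and the 1D IoU between
predicted and true bands (only for methods that output a band — human
raters mark a single slice and have no IoU).

Judgement scoring mirrors the blinded radiologist reading: a relative
rank 1-4 per case (ties allowed) and an absolute usefulness grade
(optimal / useful / useless) mapped to +1 / 0 / -1 and averaged.
Reported values use half-up rounding: one decimal for percentages and
ranks, two for usefulness.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .geometry import Region, RegionAnnotation, distance_to_region, iou_1d, row_distance_mm, slice_hit

__all__ = [
    "CohortEvaluation",
    "JudgementRecord",
    "evaluate_predictions",
    "accuracy_from_errors",
    "mean_rank",
    "mean_usefulness",
    "rank_by_distance",
    "round_half_up",
]

USEFULNESS_SCORES = {"optimal": 1, "useful": 0, "useless": -1}


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class JudgementRecord:
    case_id: str
    method: str
    rank: int
    usefulness: str

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= 4:
            raise ValueError(f"rank {self.rank} outside 1..4")
        if self.usefulness not in USEFULNESS_SCORES:
            raise ValueError(f"unknown usefulness grade {self.usefulness!r}")


@dataclass(frozen=True)
class CohortEvaluation:
    """Summary statistics for one method over one cohort.

    Error-distance statistics cover exactly the missed cases and are
    ``None`` when there are no misses (a mean over an empty set is not
    fabricated as zero). IoU statistics are ``None`` for methods without
    predicted bands. Dispersions are sample (n-1) standard deviations.
    """

    n: int
    n_errors: int
    accuracy_pct: float
    error_distance_mm: tuple[float, float] | None
    reference_distance_mm: tuple[float, float]
    iou: tuple[float, float] | None


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def evaluate_predictions(
    cases: Sequence[tuple[int, RegionAnnotation, Region | None]],
    row_spacing_mm: float = 1.0,
) -> CohortEvaluation:
    """Score (selected_row, annotation, predicted_region) triples.

    ``predicted_region`` is ``None`` for single-slice methods such as
    human raters.
    """
    if not cases:
        raise ValueError("cases must be non-empty")
    err_dists: list[float] = []
    ref_dists: list[float] = []
    ious: list[float] = []
    for selected, annotation, predicted in cases:
        region = annotation.region
        if not slice_hit(selected, region):
            err_dists.append(distance_to_region(selected, region, row_spacing_mm))
        ref_dists.append(row_distance_mm(selected, annotation.reference_row, row_spacing_mm))
        if predicted is not None:
            ious.append(iou_1d(predicted, region))
    n = len(cases)
    n_errors = len(err_dists)
    return CohortEvaluation(
        n=n,
        n_errors=n_errors,
        accuracy_pct=accuracy_from_errors(n_errors, n),
        error_distance_mm=_mean_sd(err_dists) if n_errors else None,
        reference_distance_mm=_mean_sd(ref_dists),
        iou=_mean_sd(ious) if ious else None,
    )


def accuracy_from_errors(n_errors: int, n: int) -> float:
    """Percent of hits, one decimal, from an error count."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= n_errors <= n:
        raise ValueError("n_errors must lie in [0, n]")
    return round_half_up(100.0 * (n - n_errors) / n, 1)


def mean_rank(counts: Sequence[int]) -> float:
    """Mean relative rank from a (rank-1, rank-2, rank-3, rank-4) count vector."""
    if len(counts) != 4:
        raise ValueError("counts must have exactly 4 entries (ranks 1..4)")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total < 1:
        raise ValueError("counts must sum to at least 1")
    weighted = sum(r * c for r, c in zip((1, 2, 3, 4), counts))
    return round_half_up(weighted / total, 1)


def mean_usefulness(n_optimal: int, n_useful: int, n_useless: int) -> float:
    """Mean usefulness score with optimal=+1, useful=0, useless=-1; two decimals."""
    if min(n_optimal, n_useful, n_useless) < 0:
        raise ValueError("counts must be non-negative")
    total = n_optimal + n_useful + n_useless
    if total < 1:
        raise ValueError("counts must sum to at least 1")
    return round_half_up((n_optimal - n_useless) / total, 2)


def rank_by_distance(distances: Sequence[float]) -> list[int]:
    """Competition ranks (1, 1, 3, ...) of per-method distances; smaller is better.

    An automatic stand-in for the radiologist's relative ranking, used in
    synthetic benchmarks only.
    """
    if len(distances) < 2:
        raise ValueError("need at least two methods to rank")
    arr = np.asarray(distances, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("distances must be finite")
    return [int(np.sum(arr < d)) + 1 for d in arr]
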