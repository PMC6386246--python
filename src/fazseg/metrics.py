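"""Evaluation machinery: localization success, overlap, correlation,
and circularity-stratified summaries.

Localization follows the centroid-in-mask criterion: an image counts as
correctly localized when the (rounded) centroid of the preliminary
extraction falls on a foreground pixel of the reference segmentation.
Segmentation quality uses the Jaccard index |A∩B|/|A∪B| and, at cohort
level, the Pearson correlation between automatic and reference area
sets.  To study the effect of contour irregularity, records can be
stratified into equal-size low/medium/high circularity tertiles with
per-group correlation and mean overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError
from .image_io import BinaryMask

__all__ = [
    "EvalRecord",
    "TertileGroup",
    "localization_success",
    "jaccard_index",
    "pearson_correlation",
    "circularity_tertiles",
    "summarize_records",
]

SUBGROUPS = ("3mm-superficial", "3mm-deep", "6mm-superficial", "6mm-deep")


@dataclass(frozen=True)
class EvalRecord:
    """Per-image evaluation outcome."""

    image_id: str
    localized: bool
    jaccard: float | None  # None when not localized
    area_auto_mm2: float | None
    area_ref_mm2: float
    circularity: float | None
    subgroup: str

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"subgroup must be one of {SUBGROUPS}")
        if not self.localized and self.jaccard is not None:
            raise ValueError("jaccard is only defined for localized images")


def localization_success(pred: BinaryMask, reference: BinaryMask) -> bool:
    """Centroid-in-mask test of the preliminary extraction.

    True iff the integer-rounded centroid pixel of ``pred`` is foreground
    in ``reference``.  An empty prediction is a failure, not an error.
    """
    if pred.shape != reference.shape:
        raise ValueError("masks must share one pixel grid")
    rr, cc = np.nonzero(pred.pixels)
    if rr.size == 0:
        return False
    r = int(np.clip(round(rr.mean()), 0, pred.height - 1))
    c = int(np.clip(round(cc.mean()), 0, pred.width - 1))
    return bool(reference.pixels[r, c])


def jaccard_index(a: BinaryMask, b: BinaryMask) -> float:
    """Overlap |A∩B| / |A∪B| in [0, 1]; 1 means perfect agreement."""
    if a.shape != b.shape:
        raise ValueError("masks must share one pixel grid")
    union = int((a.pixels | b.pixels).sum())
    if union == 0:
        raise UndefinedMetricError("Jaccard undefined for two empty masks")
    inter = int((a.pixels & b.pixels).sum())
    return inter / union


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson r between two area sets: cov(x,y) / (sd(x) * sd(y))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need two equal-length sets with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("Pearson r undefined for zero variance")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class TertileGroup:
    """One circularity stratum with its summary statistics."""

    level: str  # "low" | "medium" | "high"
    records: tuple[EvalRecord, ...]
    pearson_r: float | None  # None when undefined (size < 3 or no variance)
    mean_jaccard: float | None


def _group_stats(records: Sequence[EvalRecord]) -> tuple[float | None, float | None]:
    loc = [r for r in records if r.localized and r.jaccard is not None]
    mean_j = float(np.mean([r.jaccard for r in loc])) if loc else None
    try:
        r = pearson_correlation(
            [r.area_auto_mm2 for r in loc], [r.area_ref_mm2 for r in loc]
        )
    except (ValueError, UndefinedMetricError):
        r = None
    return r, mean_j


def circularity_tertiles(records: Sequence[EvalRecord]) -> list[TertileGroup]:
    """Split records into equal-size low/medium/high circularity groups.

    Records are stably sorted by increasing circularity and split into
    three groups of equal size; when the count is not divisible by 3 the
    remainder goes to the lower groups first (10 -> 4/3/3).  Ties keep
    their sorted rank.  The groups partition the input.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for tertile grouping")
    key = [(-1.0 if r.circularity is None else r.circularity) for r in records]
    order = np.argsort(key, kind="stable")
    n = len(records)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    groups: list[TertileGroup] = []
    start = 0
    for level, size in zip(("low", "medium", "high"), sizes):
        chunk = tuple(records[i] for i in order[start:start + size])
        r, mean_j = _group_stats(chunk)
        groups.append(TertileGroup(level, chunk, r, mean_j))
        start += size
    return groups


def summarize_records(records: Sequence[EvalRecord]) -> pd.DataFrame:
    """Per-subgroup table: n, localization rate, Pearson r, mean Jaccard."""
    rows = []
    for sub in SUBGROUPS:
        recs = [r for r in records if r.subgroup == sub]
        if not recs:
            continue
        n_loc = sum(r.localized for r in recs)
        r, mean_j = _group_stats(recs)
        rows.append(
            {
                "subgroup": sub,
                "n": len(recs),
                "localized": n_loc,
                "localization_rate": n_loc / len(recs),
                "pearson_r": r,
                "mean_jaccard": mean_j,
            }
        )
    return pd.DataFrame(rows)
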