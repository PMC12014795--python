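"""H-Score computation, polygon areas, expression grouping and aggregation.

The H-Score is the standard semiquantitative immunohistochemistry score: each
cell in a pathologist-defined cancer area carries a staining level in
{0, 1, 2, 3} (no to strong PSMA expression) and

    H = sum_i  i * (100 * n_i / n_total)  =  100 * mean(level),

so H lies in [0, 300].  Areas are grouped into four expression strata
(very low / low / medium / high) by fixed integer H-Score limits, and
combined tumour areas/volumes carry the area-weighted mean and SD of their
constituents' H-Scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPolygon, Polygon

__all__ = [
    "HistoArea",
    "HScoreGroupScheme",
    "DEFAULT_GROUP_SCHEME",
    "WeightedHScore",
    "compute_hscore",
    "polygon_area",
    "assign_group",
    "weighted_hscore",
    "validate_cell_table",
]

CELL_TABLE_COLUMNS = ("area_id", "cell_id", "level")


@dataclass
class HistoArea:
    """A pathologist-defined 2D PCa region on one whole-mount section.

    ``polygon`` is a shapely (Multi)Polygon in section-plane coordinates; the
    coordinate unit defaults to micrometres (``area_unit`` labels it, it is
    not converted).  ``section`` counts from 1 at the prostate base.
    """

    patient_id: str
    section: int
    area_id: str
    polygon: Polygon | MultiPolygon
    label: str = ""
    hscore: float = float("nan")
    area_um2: float = float("nan")
    area_unit: str = "um^2"

    def __post_init__(self) -> None:
        if self.section < 1:
            raise ValueError("section index counts from 1 at the prostate base")
        if np.isnan(self.area_um2):
            self.area_um2 = polygon_area(self.polygon)
        if self.area_um2 <= 0:
            raise ValueError(f"area {self.area_id}: polygon area must be positive")
        if not np.isnan(self.hscore) and not 0 <= self.hscore <= 300:
            raise ValueError(f"area {self.area_id}: H-Score outside [0, 300]")


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the (area_id, cell_id, level) layout and the 0..3 level range."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    levels = cells["level"].to_numpy()
    if len(levels) and (
        not np.issubdtype(np.asarray(levels).dtype, np.integer)
        and not np.all(np.equal(np.mod(levels, 1), 0))
    ):
        raise ValueError("staining levels must be integers")
    if len(levels) and (levels.min() < 0 or levels.max() > 3):
        raise ValueError("staining levels must lie in {0, 1, 2, 3}")
    return cells


def compute_hscore(cells: pd.DataFrame, area_id: str) -> float:
    """H-Score of one area: staining levels weighted by their cell percentages.

    Uses exact cell fractions (not rounded percentages); equals
    ``100 * mean(level)`` algebraically.  Invariant to row order.
    """
    validate_cell_table(cells)
    sub = cells.loc[cells["area_id"] == area_id, "level"]
    if sub.empty:
        raise KeyError(f"no cells for area_id {area_id!r}")
    return float(100.0 * sub.to_numpy(dtype=float).mean())


def polygon_area(polygon: Polygon | MultiPolygon) -> float:
    """Shoelace area of a simple polygon (holes subtracted), in input units."""
    if polygon.is_empty:
        raise ValueError("polygon is empty")
    for ring_poly in getattr(polygon, "geoms", [polygon]):
        if len(ring_poly.exterior.coords) < 4:  # closed ring: n vertices + repeat
            raise ValueError("polygon ring needs at least 3 vertices")
    if not polygon.is_valid:
        raise ValueError(f"invalid (e.g. self-intersecting) polygon: {shapely.is_valid_reason(polygon)}")
    return float(polygon.area)


@dataclass(frozen=True)
class HScoreGroupScheme:
    """Ordered closed integer intervals partitioning [0, 300] with labels.

    Non-integer scores are assigned by extending each interval to the
    half-open real hull ``[lo, hi + 1)`` (the last interval keeps its closed
    upper limit), which preserves the printed integer limits while making
    assignment total on the reals.
    """

    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        labels = [lab for lab, _, _ in self.intervals]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        prev_hi = -1
        for lab, lo, hi in self.intervals:
            if lo != prev_hi + 1:
                raise ValueError(f"group {lab!r}: intervals must be contiguous")
            if hi < lo:
                raise ValueError(f"group {lab!r}: empty interval")
            prev_hi = hi
        if self.intervals[0][1] != 0 or self.intervals[-1][2] != 300:
            raise ValueError("group intervals must partition [0, 300]")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _, _ in self.intervals)


# Equal-occupancy limits used in the source study's four-group stratification.
DEFAULT_GROUP_SCHEME = HScoreGroupScheme(
    (
        ("very_low", 0, 75),
        ("low", 76, 132),
        ("medium", 133, 180),
        ("high", 181, 300),
    )
)


def assign_group(hscore: float, scheme: HScoreGroupScheme = DEFAULT_GROUP_SCHEME) -> str:
    if not 0 <= hscore <= 300:
        raise ValueError(f"H-Score {hscore} outside [0, 300]")
    for i, (lab, lo, hi) in enumerate(scheme.intervals):
        last = i == len(scheme.intervals) - 1
        if (lo <= hscore <= hi) if last else (lo <= hscore < hi + 1):
            return lab
    raise AssertionError("group scheme does not cover [0, 300]")  # pragma: no cover


@dataclass(frozen=True)
class WeightedHScore:
    """Area-weighted mean/SD of H-Scores; ``total_weight`` in the area unit."""

    mean: float
    sd: float
    total_weight: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


def weighted_hscore(
    areas, weights=None, *, ddof: str = "population"
) -> WeightedHScore:
    """Area-weighted mean and SD of H-Scores.

    ``areas`` is either a sequence of ``(hscore, weight)`` pairs or an array
    of H-Scores with ``weights`` given separately.  The SD defaults to the
    population (biased) form ``sqrt(sum w (h - mean)^2 / sum w)``; pass
    ``ddof="reliability"`` for the frequency-weights unbiased form.
    Invariant to ordering and to uniform weight rescaling.
    """
    if weights is None:
        pairs = list(areas)
        if not pairs:
            raise ValueError("weighted_hscore requires at least one area")
        h = np.asarray([p[0] for p in pairs], dtype=float)
        w = np.asarray([p[1] for p in pairs], dtype=float)
    else:
        h = np.asarray(areas, dtype=float)
        w = np.asarray(weights, dtype=float)
    if h.size == 0:
        raise ValueError("weighted_hscore requires at least one area")
    if h.shape != w.shape:
        raise ValueError("H-Scores and weights must align")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    wsum = w.sum()
    mean = float((w * h).sum() / wsum)
    var = float((w * (h - mean) ** 2).sum() / wsum)
    if ddof == "reliability":
        denom = wsum - (w**2).sum() / wsum
        var = float((w * (h - mean) ** 2).sum() / denom) if denom > 0 else 0.0
    elif ddof != "population":
        raise ValueError("ddof must be 'population' or 'reliability'")
    return WeightedHScore(mean, float(np.sqrt(max(var, 0.0))), float(wsum), int(h.size))
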