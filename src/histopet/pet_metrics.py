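"""Sub-voxel PET uptake extraction, threshold GTV surrogate and GTV agreement.

Regions live at sub-voxel resolution (fractional occupancy); statistics are
taken directly on the PET grid without resampling the image.  The voxel
weight of a region is the fraction of the voxel's sub-cells inside it;
SUVmean is the weight-weighted mean, SUVmax the maximum over voxels whose
weight exceeds a configurable floor (default 0: any overlap counts, the
choice that favours small regions), and the in-vivo volume is the summed
fractional volume in ml.

The GTV surrogate is a fixed SUV threshold with small connected components
removed (26-connectivity); *GTV agreement* is the occupancy fraction of a
region lying inside the GTV — Dice-like, but normalized by the region alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import GridRef, RegionMask, ScalarVolume, rasterize_predicate

logger = logging.getLogger("histopet")

__all__ = [
    "UptakeStats",
    "GtvMask",
    "AgreementResult",
    "compute_occupancy",
    "ellipsoid_region",
    "extract_uptake_stats",
    "contour_gtv",
    "gtv_agreement",
]


@dataclass(frozen=True)
class UptakeStats:
    """SUVmean / SUVmax (g/ml) and fractional in-vivo volume (ml) of a region.

    ``volume_ml_voxelized`` counts whole voxels with any overlap, reported
    alongside the fractional default.
    """

    suv_mean: float
    suv_max: float
    volume_ml: float
    volume_ml_voxelized: float

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("region volume must be positive")


@dataclass
class GtvMask:
    """Binary voxel mask of the threshold-surrogate gross tumour volume."""

    mask: np.ndarray
    grid: GridRef
    threshold: float
    min_component_voxels: int = 1

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != tuple(self.grid.shape):
            raise ValueError("GTV mask shape must match its grid")

    def volume_ml(self) -> float:
        return float(self.mask.sum() * self.grid.voxel_volume_mm3 / 1000.0)


@dataclass(frozen=True)
class AgreementResult:
    """Fraction of a region's occupancy lying inside the GTV."""

    agreement: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.agreement <= 1 + 1e-12:
            raise ValueError("agreement must lie in [0, 1]")


def compute_occupancy(
    predicate, grid: GridRef, sub_factor: int, world_lo, world_hi
) -> RegionMask:
    """Rasterize a world-space inside predicate to fractional occupancy.

    Thin wrapper over :func:`histopet.volumes.rasterize_predicate`; regions
    outside the grid yield an empty mask with a warning rather than an error.
    """
    return rasterize_predicate(
        predicate, grid, sub_factor, world_lo, world_hi, on_empty="warn"
    )


def ellipsoid_region(
    center, radii, grid: GridRef, sub_factor: int = 4
) -> RegionMask:
    """Fractional occupancy of an axis-aligned ellipsoid (helper/fixture).

    The voxel support is exact: a voxel whose box intersects the ellipsoid
    always receives positive occupancy ("any overlap counts"), even when the
    sub-sampling grid misses the sliver — grazed voxels the sampler missed
    get half a sub-cell, so SUVmax eligibility is independent of the
    sub-resolution.
    """
    c = np.asarray(center, dtype=float)
    r = np.asarray(radii, dtype=float)

    def inside(pts):
        return np.sum(((pts - c) / r) ** 2, axis=1) <= 1.0

    mask = rasterize_predicate(inside, grid, sub_factor, c - r, c + r)
    s = mask.sub_factor
    w, off = mask.voxel_weights()
    nb = mask.n_voxels
    # exact box-ellipsoid overlap in sphere space (closest box point to centre)
    ax = [
        (np.asarray(off)[d] + np.arange(nb[d])) * grid.spacing_arr[d]
        + grid.origin_arr[d]
        for d in range(3)
    ]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    centers = np.stack([gx, gy, gz], axis=-1)
    half = grid.spacing_arr / 2.0
    closest = np.clip(c, centers - half, centers + half)
    overlaps = np.sum(((closest - c) / r) ** 2, axis=-1) <= 1.0
    missed = overlaps & (w == 0)
    if np.any(missed):
        for vi in np.argwhere(missed):
            # mark the sub-cell of this voxel nearest the ellipsoid centre
            lo = np.asarray(off) + vi - 0.5
            cells = (np.indices((s, s, s)).reshape(3, -1).T + 0.5) / s
            pts = grid.origin_arr + (lo + cells) * grid.spacing_arr
            k = np.argmin(np.sum(((pts - c) / r) ** 2, axis=1))
            fine_idx = tuple(vi * s + np.unravel_index(k, (s, s, s)))
            mask.occupancy[fine_idx] = 0.5
    return mask


def extract_uptake_stats(
    region: RegionMask, pet: ScalarVolume, max_occupancy_floor: float = 0.0
) -> UptakeStats:
    """SUVmean, SUVmax and volume of a fractional region, without resampling.

    ``suv_mean = sum(w_v * SUV_v) / sum(w_v)`` over voxels; ``suv_max`` is
    taken over voxels with weight strictly above ``max_occupancy_floor``
    (floor 0 means any overlap makes a voxel eligible).  SUV values are never
    interpolated.
    """
    if pet.grid != region.grid:
        raise ValueError("region and PET volume must share one grid")
    w, off = region.voxel_weights()
    vals = pet.values[region.bbox_slices()]
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("region has zero total occupancy")
    eligible = w > max_occupancy_floor
    if not np.any(eligible):
        raise ValueError(
            "no voxel exceeds max_occupancy_floor; reduce the floor "
            f"(currently {max_occupancy_floor})"
        )
    mean = float((w * vals).sum() / wsum)
    mx = float(vals[eligible].max())
    vol = float(wsum * region.grid.voxel_volume_mm3 / 1000.0)
    vol_vox = float((w > 0).sum() * region.grid.voxel_volume_mm3 / 1000.0)
    return UptakeStats(mean, mx, vol, vol_vox)


def contour_gtv(
    pet: ScalarVolume, threshold: float, min_component_voxels: int = 1
) -> GtvMask:
    """Threshold-surrogate GTV: voxels >= threshold, small components removed.

    Connected components use 26-connectivity.  An empty GTV is a valid
    outcome (logged as a warning), e.g. in prostates without avid disease.
    """
    if threshold <= 0:
        raise ValueError("GTV threshold must be positive")
    raw = pet.values >= threshold
    if min_component_voxels > 1 and raw.any():
        labels, n = ndimage.label(raw, structure=np.ones((3, 3, 3), dtype=int))
        counts = np.bincount(labels.ravel())
        keep = counts >= min_component_voxels
        keep[0] = False
        raw = keep[labels]
    if not raw.any():
        logger.warning("GTV contour at threshold %.3g g/ml is empty", threshold)
    return GtvMask(raw, pet.grid, float(threshold), int(min_component_voxels))


def gtv_agreement(
    region: RegionMask, gtv: GtvMask, binarized: bool = False
) -> AgreementResult:
    """Occupancy fraction of ``region`` inside the GTV.

    Fractional voxel weights are used by default, consistent with the
    no-resampling extraction; ``binarized=True`` instead counts voxels with
    any occupancy (oracle-comparison mode).
    """
    if gtv.grid != region.grid:
        raise ValueError("region and GTV must share one grid")
    w, _ = region.voxel_weights()
    if binarized:
        w = (w > 0).astype(float)
    g = gtv.mask[region.bbox_slices()].astype(float)
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("region has zero total occupancy")
    if not gtv.mask.any():
        return AgreementResult(0.0)
    return AgreementResult(float(np.clip((w * g).sum() / wsum, 0.0, 1.0)))
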