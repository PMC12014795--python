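"""Axis-aligned scalar volumes and fractional-occupancy region masks.

The world frame is RAS millimetres throughout the package.  A
:class:`ScalarVolume` is an axis-aligned grid; voxel ``(i, j, k)`` has its
centre at ``origin + index * spacing`` and occupies the closed box
``centre ± spacing / 2``.

A :class:`RegionMask` stores a 3D region at sub-voxel resolution: a binary
(or fractional) occupancy array on a fine grid obtained by subdividing each
voxel of a reference grid into ``sub_factor**3`` congruent cells, restricted
to a voxel-aligned bounding box.  This representation lets region statistics
be computed on the PET grid without resampling the image, which is the point:
resampling small regions onto a coarse grid loses them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("histopet")

__all__ = [
    "GridRef",
    "ScalarVolume",
    "RegionMask",
    "rasterize_predicate",
    "union_masks",
    "EmptyRegionError",
]


class EmptyRegionError(ValueError):
    """A region rasterized to empty occupancy (e.g. fully outside the grid)."""


@dataclass(frozen=True)
class GridRef:
    """Geometry of an axis-aligned 3D grid (shape, spacing and origin in mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_arr))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centres for (possibly fractional) indices."""
        return self.origin_arr + np.asarray(idx, dtype=float) * self.spacing_arr

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Continuous voxel-index coordinates of world points."""
        return (np.asarray(pts, dtype=float) - self.origin_arr) / self.spacing_arr

    def voxel_of(self, pts: np.ndarray) -> np.ndarray:
        """Integer voxel index containing each world point (nearest centre)."""
        return np.round(self.world_to_index(pts)).astype(int)


@dataclass
class ScalarVolume:
    """A 3D image with world metadata; PET values are SUV in g/ml."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "g/ml"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ScalarVolume requires a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ScalarVolume values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def grid(self) -> GridRef:
        return GridRef(tuple(self.values.shape), self.spacing, self.origin)

    def sample_nearest(self, pts: np.ndarray, outside: float = 0.0) -> np.ndarray:
        """Value of the voxel containing each point; ``outside`` beyond the grid."""
        idx = self.grid.voxel_of(pts)
        shape = np.asarray(self.values.shape)
        ok = np.all((idx >= 0) & (idx < shape), axis=-1)
        out = np.full(idx.shape[:-1], float(outside))
        if np.any(ok):
            sel = idx[ok]
            out[ok] = self.values[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out


@dataclass
class RegionMask:
    """Fractional occupancy of a region on a fine sub-grid of a reference grid.

    ``occupancy`` has shape ``(nb * s, ...)`` where ``nb`` is the number of
    covered voxels per axis and ``s = sub_factor``; ``voxel_offset`` is the
    reference-grid index of the first covered voxel.
    """

    occupancy: np.ndarray
    sub_factor: int
    voxel_offset: tuple[int, int, int]
    grid: GridRef
    clipped: bool = False

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        s = int(self.sub_factor)
        if s < 1:
            raise ValueError("sub_factor must be >= 1")
        if any(n % s for n in self.occupancy.shape):
            raise ValueError("occupancy shape must be a multiple of sub_factor")
        if self.occupancy.size and (
            self.occupancy.min() < -1e-12 or self.occupancy.max() > 1 + 1e-12
        ):
            raise ValueError("occupancy values must lie in [0, 1]")
        self.voxel_offset = tuple(int(v) for v in self.voxel_offset)

    @property
    def n_voxels(self) -> tuple[int, int, int]:
        s = self.sub_factor
        return tuple(n // s for n in self.occupancy.shape)

    def fine_centers(self, only_occupied: bool = True):
        """World coordinates of fine-cell centres and their occupancy values."""
        s = self.sub_factor
        off = np.asarray(self.voxel_offset, dtype=float)
        if only_occupied:
            idx = np.argwhere(self.occupancy > 0)
            occ = self.occupancy[self.occupancy > 0]
        else:
            idx = np.indices(self.occupancy.shape).reshape(3, -1).T
            occ = self.occupancy.ravel()
        coord = off - 0.5 + (idx + 0.5) / s
        pts = self.grid.origin_arr + coord * self.grid.spacing_arr
        return pts, occ

    def voxel_weights(self) -> tuple[np.ndarray, tuple[int, int, int]]:
        """Per-voxel occupancy fractions over the covered bounding box."""
        s = self.sub_factor
        nb = self.n_voxels
        w = self.occupancy.reshape(nb[0], s, nb[1], s, nb[2], s).mean(axis=(1, 3, 5))
        return w, self.voxel_offset

    def volume_ml(self) -> float:
        """Region volume in ml from summed fine-cell occupancy."""
        cell = self.grid.voxel_volume_mm3 / self.sub_factor**3
        return float(self.occupancy.sum() * cell / 1000.0)

    def bbox_slices(self) -> tuple[slice, slice, slice]:
        nb = self.n_voxels
        return tuple(
            slice(o, o + n) for o, n in zip(self.voxel_offset, nb)
        )  # type: ignore[return-value]


def _voxel_bbox(
    grid: GridRef, world_lo: np.ndarray, world_hi: np.ndarray, pad_voxels: int = 1
):
    """Inclusive voxel-index bounds covering a world box, clipped to the grid."""
    lo = np.floor(grid.world_to_index(world_lo) + 0.5).astype(int) - pad_voxels
    hi = np.floor(grid.world_to_index(world_hi) + 0.5).astype(int) + pad_voxels
    shape = np.asarray(grid.shape)
    lo_c = np.clip(lo, 0, shape - 1)
    hi_c = np.clip(hi, 0, shape - 1)
    clipped = bool(np.any(lo_c != lo) or np.any(hi_c != hi))
    if np.any(hi_c < lo_c) or np.any(hi < 0) or np.any(lo >= shape):
        return None, None, True
    return lo_c, hi_c, clipped


def rasterize_predicate(
    predicate,
    grid: GridRef,
    sub_factor: int,
    world_lo,
    world_hi,
    pad_voxels: int = 1,
    on_empty: str = "raise",
) -> RegionMask:
    """Rasterize an inside/outside predicate to fractional occupancy.

    ``predicate`` receives an ``(N, 3)`` array of world points and returns a
    boolean array.  The mask covers the voxel-aligned bounding box of
    ``[world_lo, world_hi]`` (plus padding), clipped to the grid; a warning is
    logged when clipping occurs and ``on_empty`` controls whether an empty
    result raises :class:`EmptyRegionError` or returns an empty mask.
    """
    world_lo = np.asarray(world_lo, dtype=float)
    world_hi = np.asarray(world_hi, dtype=float)
    lo, hi, clipped = _voxel_bbox(grid, world_lo, world_hi, pad_voxels)
    if lo is None:
        logger.warning("region bounding box lies entirely outside the grid")
        if on_empty == "raise":
            raise EmptyRegionError("region lies outside the image grid")
        empty = np.zeros((sub_factor,) * 3, dtype=float)
        return RegionMask(empty, sub_factor, (0, 0, 0), grid, clipped=True)
    if clipped:
        logger.warning("region bounding box clipped to the grid extent")
    s = int(sub_factor)
    axes = []
    for a in range(3):
        n = (hi[a] - lo[a] + 1) * s
        coord = lo[a] - 0.5 + (np.arange(n) + 0.5) / s
        axes.append(grid.origin_arr[a] + coord * grid.spacing_arr[a])
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.asarray(predicate(pts), dtype=bool)
    occ = inside.reshape(gx.shape).astype(float)
    if occ.sum() == 0 and on_empty == "raise":
        raise EmptyRegionError("region rasterized to an empty mask")
    return RegionMask(occ, s, tuple(int(v) for v in lo), grid, clipped=clipped)


def union_masks(masks: list[RegionMask]) -> RegionMask:
    """Union (cell-wise max) of region masks sharing grid and sub_factor."""
    if not masks:
        raise ValueError("union_masks requires at least one mask")
    grid = masks[0].grid
    s = masks[0].sub_factor
    for m in masks[1:]:
        if m.grid != grid or m.sub_factor != s:
            raise ValueError("masks must share grid and sub_factor")
    los = np.array([m.voxel_offset for m in masks])
    his = np.array([np.add(m.voxel_offset, m.n_voxels) for m in masks])
    lo = los.min(axis=0)
    hi = his.max(axis=0)
    occ = np.zeros(tuple((hi - lo) * s), dtype=float)
    for m in masks:
        a = (np.asarray(m.voxel_offset) - lo) * s
        sl = tuple(slice(a[d], a[d] + m.occupancy.shape[d]) for d in range(3))
        np.maximum(occ[sl], m.occupancy, out=occ[sl])
    return RegionMask(
        occ, s, tuple(int(v) for v in lo), grid, clipped=any(m.clipped for m in masks)
    )
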