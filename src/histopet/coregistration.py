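"""Slab-model co-registration of section polygons into the PET world frame.

Whole-mount sections are cut in 4 mm slabs aligned to a localizer grid;
section ``s`` (numbered from the prostate base) occupies the half-open slab
``[base_z + (s-1)*t, base_z + s*t)`` in the section frame.  Histo-area
polygons are extruded through their slab, pushed through the supplied
transform chain (section -> ex-vivo CT -> in-vivo CT -> PET) and rasterized
to fractional occupancy.

Two pathways build analysis units:

* *tumour volumes* (pathway 1): per-lesion stacks of histo-areas,
  shape-interpolated across unoccupied slabs by signed-distance blending of
  the bounding sections' contours;
* *tumour areas* (pathway 2): per-patient unions of histo-areas sharing one
  H-Score group, with no z-interpolation.

``refine_rigid`` automates the study's final visual position correction: a
deterministic coarse-to-fine grid search (translations up to +-16 mm, small
rotations) maximizing the occupancy-weighted SUVmean of the region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import shapely
from scipy.signal import fftconvolve
from shapely import affinity
from shapely.ops import unary_union

from .histology import (
    DEFAULT_GROUP_SCHEME,
    HistoArea,
    HScoreGroupScheme,
    WeightedHScore,
    assign_group,
    weighted_hscore,
)
from .transforms import Affine, TransformChain
from .volumes import (
    EmptyRegionError,
    GridRef,
    RegionMask,
    ScalarVolume,
    rasterize_predicate,
    union_masks,
)

logger = logging.getLogger("histopet")

__all__ = [
    "SectionGeometry",
    "TumourVolume",
    "TumourArea",
    "RefineResult",
    "transfer_contour",
    "chain_lesions",
    "build_tumour_volume",
    "build_tumour_areas",
    "refine_rigid",
    "transform_mask",
]


@dataclass(frozen=True)
class SectionGeometry:
    """Slab model mapping section indices to z-intervals in the section frame.

    ``um_per_mm`` converts in-plane polygon coordinates (stored in
    micrometres by convention) to frame millimetres.
    """

    base_z: float
    slab_thickness: float = 4.0
    um_per_mm: float = 1000.0

    def __post_init__(self) -> None:
        if self.slab_thickness <= 0 or self.um_per_mm <= 0:
            raise ValueError("slab thickness and scale must be positive")

    def slab_bounds(self, section: int) -> tuple[float, float]:
        z0 = self.base_z + (section - 1) * self.slab_thickness
        return z0, z0 + self.slab_thickness

    def slab_center(self, section: int) -> float:
        z0, z1 = self.slab_bounds(section)
        return 0.5 * (z0 + z1)


def _polygon_mm(area: HistoArea, geom: SectionGeometry):
    f = 1.0 / geom.um_per_mm
    return affinity.scale(area.polygon, xfact=f, yfact=f, origin=(0, 0))


def _forward_bbox(polys_mm, z_lo, z_hi, chain: TransformChain, section: int):
    """World bbox of extruded polygons pushed through the chain (sampled)."""
    pts = []
    for poly in polys_mm:
        for g in getattr(poly, "geoms", [poly]):
            xy = np.asarray(g.exterior.coords)
            for z in (z_lo, z_hi):
                pts.append(np.column_stack([xy, np.full(len(xy), z)]))
    p = np.concatenate(pts, axis=0)
    w = chain.apply(p, section=section)
    return w.min(axis=0), w.max(axis=0)


def transfer_contour(
    area: HistoArea,
    geom: SectionGeometry,
    chain: TransformChain,
    grid: GridRef,
    sub_factor: int = 4,
) -> RegionMask:
    """Extrude one histo-area through its slab and rasterize in the PET frame.

    The polygon is extruded through the full 4 mm slab, mapped through the
    chain and rasterized to fractional occupancy by inverse-mapping fine-cell
    centres.  Out-of-grid parts are clipped with a warning; a fully empty
    result raises :class:`EmptyRegionError`.
    """
    if not chain.covers_section(area.section):
        raise KeyError(f"transform chain does not cover section {area.section}")
    poly = _polygon_mm(area, geom)
    z0, z1 = geom.slab_bounds(area.section)
    wlo, whi = _forward_bbox([poly], z0, z1, chain, area.section)

    def inside(pts):
        q = chain.inverse_apply(pts, section=area.section)
        in_slab = (q[:, 2] >= z0) & (q[:, 2] < z1)
        out = np.zeros(len(pts), dtype=bool)
        if np.any(in_slab):
            out[in_slab] = shapely.contains_xy(poly, q[in_slab, 0], q[in_slab, 1])
        return out

    return rasterize_predicate(inside, grid, sub_factor, wlo, whi)


def chain_lesions(areas: list[HistoArea]) -> list[list[HistoArea]]:
    """Group histo-areas into longitudinal lesions by in-plane overlap.

    Areas on consecutive sections whose polygons overlap in the section plane
    belong to one lesion (transitively); disjoint stacks are never bridged.
    """
    n = len(areas)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = areas[i], areas[j]
            if abs(a.section - b.section) != 1:
                continue
            if a.polygon.intersects(b.polygon) and a.polygon.intersection(b.polygon).area > 0:
                parent[find(i)] = find(j)
    groups: dict[int, list[HistoArea]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(areas[i])
    out = list(groups.values())
    out.sort(key=lambda g: (min(a.section for a in g), g[0].area_id))
    return out


@dataclass
class TumourVolume:
    """Pathway-1 unit: a z-interpolated lesion with its weighted H-Score."""

    constituent_ids: tuple[str, ...]
    mask: RegionMask
    hscore: WeightedHScore
    patient_id: str


@dataclass
class TumourArea:
    """Pathway-2 unit: same-group histo-areas combined, no z-interpolation."""

    group: str
    constituent_ids: tuple[str, ...]
    mask: RegionMask
    hscore: WeightedHScore
    patient_id: str
    area_um2: float = 0.0


def _signed_distance(poly, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    pts = shapely.points(x, y)
    d = shapely.distance(poly.boundary, pts)
    inside = shapely.contains_xy(poly, x, y)
    return np.where(inside, -d, d)


def build_tumour_volume(
    areas: list[HistoArea],
    geom: SectionGeometry,
    chain: TransformChain,
    grid: GridRef,
    sub_factor: int = 4,
) -> TumourVolume:
    """Interpolate one lesion's histo-areas into a longitudinal tumour volume.

    Within an occupied slab the extruded contour is used directly; slabs
    between two occupied sections are filled by linear blending of the
    bounding contours' in-plane signed distance functions (shape-based
    interpolation).  A single section yields its slab extrusion only — no
    extrapolation beyond the outermost occupied slabs.
    """
    if not areas:
        raise ValueError("build_tumour_volume requires at least one histo-area")
    patients = {a.patient_id for a in areas}
    if len(patients) > 1:
        raise ValueError(f"constituent areas span several patients: {sorted(patients)}")
    by_section: dict[int, list] = {}
    for a in areas:
        by_section.setdefault(a.section, []).append(_polygon_mm(a, geom))
    polys = {s: unary_union(ps) for s, ps in by_section.items()}
    sections = sorted(polys)
    z_lo = geom.slab_bounds(sections[0])[0]
    z_hi = geom.slab_bounds(sections[-1])[1]
    centers = {s: geom.slab_center(s) for s in sections}
    wlo, whi = _forward_bbox(list(polys.values()), z_lo, z_hi, chain, sections[0])

    gap_pairs = [
        (sa, sb)
        for sa, sb in zip(sections[:-1], sections[1:])
        if sb > sa + 1
    ]

    def inside(pts):
        q = chain.inverse_apply(pts, section=sections[0])
        x, y, z = q[:, 0], q[:, 1], q[:, 2]
        out = np.zeros(len(pts), dtype=bool)
        in_occupied = np.zeros(len(pts), dtype=bool)
        for s in sections:
            z0, z1 = geom.slab_bounds(s)
            m = (z >= z0) & (z < z1)
            in_occupied |= m
            if np.any(m):
                out[m] = shapely.contains_xy(polys[s], x[m], y[m])
        for sa, sb in gap_pairs:
            m = (~in_occupied) & (z >= geom.slab_bounds(sa)[1]) & (z < geom.slab_bounds(sb)[0])
            if not np.any(m):
                continue
            t = (z[m] - centers[sa]) / (centers[sb] - centers[sa])
            sdf = (1 - t) * _signed_distance(polys[sa], x[m], y[m]) + t * _signed_distance(
                polys[sb], x[m], y[m]
            )
            out[m] = sdf <= 0
        return out

    mask = rasterize_predicate(inside, grid, sub_factor, wlo, whi)
    whs = weighted_hscore([(a.hscore, a.area_um2) for a in areas])
    ids = tuple(sorted(a.area_id for a in areas))
    return TumourVolume(ids, mask, whs, areas[0].patient_id)


def build_tumour_areas(
    areas: list[HistoArea],
    scheme: HScoreGroupScheme = DEFAULT_GROUP_SCHEME,
    *,
    geom: SectionGeometry,
    chain: TransformChain,
    grid: GridRef,
    sub_factor: int = 4,
) -> list[TumourArea]:
    """Combine one patient's histo-areas per H-Score group (pathway 2).

    Each occupied group yields one :class:`TumourArea` whose mask is the
    union of the constituents' slab extrusions (no interpolation) and whose
    H-Score is the area-weighted mean/SD of the constituents.
    """
    if not areas:
        return []
    patients = {a.patient_id for a in areas}
    if len(patients) > 1:
        raise ValueError(f"areas span several patients: {sorted(patients)}")
    grouped: dict[str, list[HistoArea]] = {}
    for a in areas:
        grouped.setdefault(assign_group(a.hscore, scheme), []).append(a)
    out = []
    for label in scheme.labels:
        if label not in grouped:
            continue
        members = []
        masks = []
        for a in grouped[label]:
            try:
                masks.append(transfer_contour(a, geom, chain, grid, sub_factor))
                members.append(a)
            except EmptyRegionError:
                logger.warning(
                    "area %s maps entirely outside the image; dropped from group %s",
                    a.area_id, label,
                )
        if not masks:
            logger.warning("group %s has no in-image constituents; skipped", label)
            continue
        mask = union_masks(masks)
        whs = weighted_hscore([(a.hscore, a.area_um2) for a in members])
        out.append(
            TumourArea(
                group=label,
                constituent_ids=tuple(sorted(a.area_id for a in members)),
                mask=mask,
                hscore=whs,
                patient_id=members[0].patient_id,
                area_um2=float(sum(a.area_um2 for a in members)),
            )
        )
    return out


def transform_mask(region: RegionMask, transform: Affine) -> RegionMask:
    """Resample a region mask under a rigid/affine world transform.

    New occupancy at a fine cell is the occupancy of the inverse-mapped cell
    (nearest fine cell); exact for translations by whole fine cells.
    """
    s = region.sub_factor
    grid = region.grid
    off = np.asarray(region.voxel_offset)
    nb = np.asarray(region.n_voxels)
    corners_idx = np.array(list(product(*[(off[d] - 0.5, off[d] + nb[d] - 0.5) for d in range(3)])))
    corners = grid.index_to_world(corners_idx)
    moved = transform.apply(corners)
    wlo, whi = moved.min(axis=0), moved.max(axis=0)
    inv = transform.inverse()
    origin = grid.origin_arr
    spacing = grid.spacing_arr

    def inside(pts):
        src = inv.apply(pts)
        fine = ((src - origin) / spacing - (off - 0.5)) * s - 0.5
        fi = np.round(fine).astype(int)
        shape = np.asarray(region.occupancy.shape)
        ok = np.all((fi >= 0) & (fi < shape), axis=1)
        vals = np.zeros(len(pts), dtype=bool)
        if np.any(ok):
            sel = fi[ok]
            vals[ok] = region.occupancy[sel[:, 0], sel[:, 1], sel[:, 2]] > 0.5
        return vals

    return rasterize_predicate(inside, grid, s, wlo, whi, on_empty="warn")


@dataclass
class RefineResult:
    """Outcome of the automated rigid position correction."""

    transform: Affine
    mask: RegionMask
    trace: list = field(default_factory=list)
    flat_objective: bool = False

    @property
    def translation(self) -> np.ndarray:
        return self.transform.matrix[:3, 3].copy()


def _tie_break_best(cands: np.ndarray, scores: np.ndarray, spacing: np.ndarray):
    """Max score; ties resolved toward smallest displacement, then lexicographic."""
    best = scores.max()
    tol = 1e-9 * max(1.0, abs(best))
    sel = np.flatnonzero(scores >= best - tol)
    norms = np.linalg.norm(cands[sel] * spacing, axis=1)
    order = sorted(
        range(len(sel)), key=lambda i: (norms[i], tuple(cands[sel[i]]))
    )
    return cands[sel[order[0]]], best


def refine_rigid(
    region: RegionMask,
    pet: ScalarVolume,
    max_shift_mm: float = 16.0,
    max_rot_deg: float = 5.0,
    coarse_step_mm: float = 2.0,
    fine_step_mm: float = 0.5,
    rot_step_deg: float = 0.5,
) -> RefineResult:
    """Automated surrogate of the visual position correction.

    Maximizes the occupancy-weighted SUVmean of the region over rigid
    perturbations, deterministic coarse-to-fine: (1) whole-voxel translations
    via FFT cross-correlation of the voxel-weight map with the PET volume,
    (2) per-axis rotation sweep about the region centroid, (3) sub-voxel
    translation refinement.  Ties break toward the smallest displacement,
    then lexicographic axis order.  A flat objective (e.g. uniform PET)
    returns the identity with ``flat_objective=True``.
    """
    if pet.grid != region.grid:
        raise ValueError("region and PET must share one grid")
    spacing = region.grid.spacing_arr
    trace: list = []

    w, off = region.voxel_weights()
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("region has zero occupancy")

    # stage 1: integer-voxel translations via cross-correlation
    corr = fftconvolve(pet.values, w[::-1, ::-1, ::-1], mode="full") / wsum
    m = np.asarray(w.shape)
    offv = np.asarray(off)
    ranges = [np.arange(-int(max_shift_mm // spacing[d]), int(max_shift_mm // spacing[d]) + 1) for d in range(3)]
    cands = np.array(list(product(*ranges)))
    keep = np.linalg.norm(cands * spacing, axis=1) <= max_shift_mm + 1e-9
    cands = cands[keep]
    k = cands + offv + m - 1
    shape_c = np.asarray(corr.shape)
    ok = np.all((k >= 0) & (k < shape_c), axis=1)
    cands, k = cands[ok], k[ok]
    scores = corr[k[:, 0], k[:, 1], k[:, 2]]
    if scores.size == 0:
        raise ValueError("no feasible translation candidates")
    if np.ptp(scores) <= 1e-9 * max(1.0, abs(scores.max())):
        logger.warning("refine_rigid: flat objective, returning identity")
        return RefineResult(Affine.identity(), region, trace, flat_objective=True)
    t_vox, best = _tie_break_best(cands, scores, spacing)
    t_coarse = t_vox * spacing
    trace.append(("coarse_translation", tuple(t_coarse), float(best)))

    # point-sampled objective for the fine stages
    pts0, occ = region.fine_centers(only_occupied=True)
    occ_sum = occ.sum()
    centroid = (pts0 * occ[:, None]).sum(axis=0) / occ_sum
    rel = pts0 - centroid

    def objective(rot: Affine | None, t: np.ndarray) -> float:
        p = rel @ (rot.matrix[:3, :3].T if rot is not None else np.eye(3))
        p = p + centroid + t
        vals = pet.sample_nearest(p, outside=0.0)
        return float((occ * vals).sum() / occ_sum)

    # stage 2: per-axis rotation sweep about the centroid
    best_angles = [0.0, 0.0, 0.0]
    axes = np.eye(3)
    for ax in range(3):
        angles = np.arange(-max_rot_deg, max_rot_deg + 1e-9, rot_step_deg)
        sc = []
        for ang in angles:
            trial = list(best_angles)
            trial[ax] = ang
            rot = _euler(axes, trial, centroid)
            sc.append(objective(rot, t_coarse))
        sc = np.asarray(sc)
        tol = 1e-9 * max(1.0, abs(sc.max()))
        sel = np.flatnonzero(sc >= sc.max() - tol)
        pick = sel[np.argmin(np.abs(angles[sel]))]
        best_angles[ax] = float(angles[pick])
        trace.append((f"rotation_axis{ax}", best_angles[ax], float(sc[pick])))
    rot = _euler(axes, best_angles, centroid)

    # stage 3: sub-voxel translation refinement around the coarse optimum
    offs = np.arange(-coarse_step_mm, coarse_step_mm + 1e-9, fine_step_mm)
    fine_c = np.array(list(product(offs, offs, offs)))
    fine_t = t_coarse + fine_c
    keep = np.linalg.norm(fine_t, axis=1) <= max_shift_mm + 1e-9
    fine_t = fine_t[keep]
    sc = np.array([objective(rot, t) for t in fine_t])
    t_best, best = _tie_break_best(fine_t / spacing, sc, spacing)
    t_best = t_best * spacing
    trace.append(("fine_translation", tuple(t_best), float(best)))

    final = Affine.translation(t_best) @ rot
    if final.is_identity:
        return RefineResult(Affine.identity(), region, trace, flat_objective=False)
    refined = transform_mask(region, final)
    return RefineResult(final, refined, trace, flat_objective=False)


def _euler(axes: np.ndarray, angles_deg, center) -> Affine:
    out = Affine.identity()
    for ax, ang in zip(axes, angles_deg):
        if ang != 0.0:
            out = Affine.rotation(ax, ang, center) @ out
    return out
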