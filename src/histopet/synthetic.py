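"""Synthetic prostate/PET phantoms with full ground truth.

Each phantom patient is an ellipsoidal prostate containing non-overlapping
spherical lesions.  Every lesion carries a staining-level distribution over
{0..3} drawn from a Dirichlet prior; per-section cell tables are sampled from
it and define the histo-area H-Scores *exactly* (truth equals what the
histology module computes).  Lesion cross-sections at the 4 mm slab centres
become the histo-area polygons, and the true uptake volume is piecewise
constant over the extruded polygons:

    SUV_true = background + slope * H-Score(area),

a linear through-origin uptake model (offset by background).  PET simulation
applies a Gaussian PSF of configurable FWHM in world mm, then i.i.d.
additive Gaussian noise clipped at 0; the partial volume effect emerges from
the blur alone.  A threshold-surrogate GTV is contoured on the noisy volume,
and an optional rigid misregistration (translation magnitude in a configured
range, rotation within +-5 deg) is appended to the transform chain, with the
truth recorded for recovery experiments.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage, stats
from scipy.special import erf
from shapely import affinity
from shapely.geometry import Point

from .coregistration import SectionGeometry
from .histology import HistoArea, compute_hscore
from .pet_metrics import GtvMask, contour_gtv
from .transforms import Affine, TransformChain
from .volumes import GridRef, RegionMask, ScalarVolume

logger = logging.getLogger("histopet")

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "Phantom",
    "LesionTruth",
    "CohortScenario",
    "PlacementError",
    "generate_cell_table",
    "simulate_pet",
    "apply_misregistration",
    "sample_misregistration",
    "generate_phantom",
    "make_cohort",
    "level_alpha_for_hscore",
    "FWHM_TO_SIGMA",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PlacementError(RuntimeError):
    """Non-overlapping lesion placement failed within the attempt budget."""


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic patient.

    Defaults follow the imaging protocol the pipeline emulates: 2 mm
    isotropic SUV voxels, 4.8 mm PSF FWHM, 4 mm sections, misregistration
    range 1-16 mm.  ``staining_alpha`` is a Dirichlet concentration over
    staining levels 0..3, either one 4-vector shared by all lesions or one
    row per lesion.
    """

    prostate_half_axes: tuple[float, float, float] = (22.0, 18.0, 20.0)
    n_lesions: int = 3
    lesion_radius_range: tuple[float, float] = (4.0, 9.0)
    section_thickness: float = 4.0
    staining_alpha: tuple = (1.0, 1.0, 1.0, 1.0)
    n_cells_per_area: int = 400
    uptake_slope: float = 0.09
    uptake_background: float = 0.5
    noise_sd: float = 0.3
    psf_fwhm: float = 4.8
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    misregistration_range: tuple[float, float] = (1.0, 16.0)
    misregistration_max_rot_deg: float = 5.0
    gtv_threshold: float = 4.0
    gtv_min_component_voxels: int = 4
    uptake_sub_factor: int = 4
    grid_margin_mm: float = 10.0
    min_cross_section_radius: float = 0.8
    area_unit: str = "um^2"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.prostate_half_axes):
            raise ValueError("prostate half-axes must be positive")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be nonnegative")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ValueError("lesion radius range must be positive and ordered")
        if self.section_thickness <= 0:
            raise ValueError("section thickness must be positive")
        alpha = np.asarray(self.staining_alpha, dtype=float)
        if alpha.ndim == 1:
            if alpha.shape != (4,):
                raise ValueError("staining_alpha must have 4 entries per lesion")
        elif alpha.ndim == 2:
            if alpha.shape != (self.n_lesions, 4):
                raise ValueError("per-lesion staining_alpha needs one row per lesion")
        else:
            raise ValueError("staining_alpha must be a 4-vector or (n_lesions, 4)")
        if np.any(alpha <= 0):
            raise ValueError("staining concentrations must be strictly positive")
        if self.n_cells_per_area < 1:
            raise ValueError("n_cells_per_area must be >= 1")
        if self.uptake_slope < 0 or self.uptake_background < 0:
            raise ValueError("uptake parameters must be nonnegative")
        if self.noise_sd < 0 or self.psf_fwhm < 0:
            raise ValueError("noise_sd and psf_fwhm must be nonnegative")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        mlo, mhi = self.misregistration_range
        if not 0 <= mlo <= mhi:
            raise ValueError("misregistration range must be ordered and nonnegative")
        if self.gtv_threshold <= 0:
            raise ValueError("gtv_threshold must be positive")

    def lesion_alpha(self, lesion_index: int) -> np.ndarray:
        alpha = np.asarray(self.staining_alpha, dtype=float)
        return alpha if alpha.ndim == 1 else alpha[lesion_index]


def level_alpha_for_hscore(target_hscore: float, concentration: float = 100.0) -> tuple:
    """Dirichlet concentration targeting an expected H-Score.

    Uses the Binomial(3, H/300) level profile, whose mean staining level is
    ``H/100`` exactly, scaled to the requested total concentration.
    """
    if not 0 <= target_hscore <= 300:
        raise ValueError("target H-Score must lie in [0, 300]")
    t = min(max(target_hscore / 300.0, 1e-4), 1 - 1e-4)
    pmf = stats.binom.pmf(np.arange(4), 3, t)
    return tuple(np.maximum(pmf, 1e-6) * concentration)


@dataclass(frozen=True)
class LesionTruth:
    center: tuple[float, float, float]
    radius: float
    level_probs: tuple[float, float, float, float]


@dataclass
class PhantomTruth:
    """Ground truth for one phantom patient."""

    lesions: list[LesionTruth]
    area_hscores: dict[str, float]
    area_polygons: dict[str, object]
    uptake_true: ScalarVolume
    misregistration: Affine
    gtv: GtvMask


@dataclass
class Phantom:
    """One synthetic patient bundle (inputs of the analysis pipeline)."""

    patient_id: str
    spec: PhantomSpec
    geom: SectionGeometry
    areas: list[HistoArea]
    cells: pd.DataFrame
    chain: TransformChain
    pet: ScalarVolume
    gtv: GtvMask
    truth: PhantomTruth
    cohort: str = "I"


def generate_cell_table(
    level_probs, n_cells: int, seed, area_id: str = "A1"
) -> pd.DataFrame:
    """Multinomial cell table over staining levels 0..3 for one area."""
    p = np.asarray(level_probs, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or p.sum() <= 0:
        raise ValueError("level_probs must be 4 nonnegative values with positive sum")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("level_probs must be normalized to 1")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, p)
    levels = np.repeat(np.arange(4), counts)
    return pd.DataFrame(
        {
            "area_id": area_id,
            "cell_id": np.arange(n_cells),
            "level": levels.astype(int),
        }
    )


def _integrated_gaussian_kernel(sigma_vox: float) -> np.ndarray:
    """Separable blur kernel for box-valued voxels: Phi((m+1/2)/s) - Phi((m-1/2)/s).

    A voxel image is a piecewise-constant density, so the exact sample of its
    Gaussian convolution is a discrete convolution with the Gaussian
    integrated over each voxel extent (a plain sampled Gaussian at sigma near
    one voxel mis-weights the centre by several percent and distorts
    recovery-coefficient behaviour).  Normalized to unit sum: constants and
    total activity are preserved exactly.
    """
    half = max(int(np.ceil(4.0 * sigma_vox + 0.5)), 1)
    m = np.arange(-half, half + 1)
    denom = sigma_vox * np.sqrt(2.0)
    k = 0.5 * (erf((m + 0.5) / denom) - erf((m - 0.5) / denom))
    return k / k.sum()


def _gaussian_blur_world(vals: np.ndarray, sigma_vox: np.ndarray) -> np.ndarray:
    out = vals
    for ax, s in enumerate(sigma_vox):
        if s > 0:
            out = ndimage.correlate1d(
                out, _integrated_gaussian_kernel(float(s)), axis=ax, mode="nearest"
            )
    return out


def simulate_pet(
    true_uptake: ScalarVolume, psf_fwhm: float, noise_sd: float, seed
) -> ScalarVolume:
    """Gaussian PSF blur in world mm plus additive noise, clipped at 0.

    The per-axis sigma is ``fwhm * FWHM_TO_SIGMA / spacing`` in voxel units
    (anisotropic spacing handled per axis); the blur uses the integrated
    (voxel-aperture) Gaussian kernel, which preserves constants exactly and
    conserves interior activity.
    """
    if psf_fwhm < 0 or noise_sd < 0:
        raise ValueError("psf_fwhm and noise_sd must be nonnegative")
    vals = true_uptake.values
    if psf_fwhm > 0:
        sigma_vox = psf_fwhm * FWHM_TO_SIGMA / np.asarray(true_uptake.spacing)
        vals = _gaussian_blur_world(vals, sigma_vox)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
        vals = np.clip(vals, 0.0, None)
    return ScalarVolume(vals, true_uptake.spacing, true_uptake.origin, true_uptake.unit)


def sample_misregistration(
    range_mm: tuple[float, float],
    rng: np.random.Generator,
    center=(0.0, 0.0, 0.0),
    max_rot_deg: float = 5.0,
) -> Affine:
    """One random rigid misregistration; degenerate (0, 0) range -> identity."""
    lo, hi = range_mm
    if not 0 <= lo <= hi:
        raise ValueError("misregistration range must be ordered and nonnegative")
    if hi == 0:
        return Affine.identity()
    mag = float(rng.uniform(lo, hi))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = mag * direction
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = float(rng.uniform(-max_rot_deg, max_rot_deg))
    return Affine.translation(t) @ Affine.rotation(axis, angle, center)


def apply_misregistration(
    regions: list[RegionMask], range_mm: tuple[float, float], seed,
    center=(0.0, 0.0, 0.0), max_rot_deg: float = 5.0,
) -> tuple[list[RegionMask], Affine]:
    """Displace regions by one shared random rigid transform; truth returned."""
    from .coregistration import transform_mask

    if not regions:
        raise ValueError("apply_misregistration requires at least one region")
    rng = np.random.default_rng(seed)
    rigid = sample_misregistration(range_mm, rng, center, max_rot_deg)
    if rigid.is_identity:
        return list(regions), rigid
    return [transform_mask(r, rigid) for r in regions], rigid


def _place_lesions(spec: PhantomSpec, rng: np.random.Generator, max_attempts: int = 2000):
    half = np.asarray(spec.prostate_half_axes)
    placed: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.n_lesions):
        ok = False
        for _ in range(max_attempts):
            r = float(rng.uniform(*spec.lesion_radius_range))
            shrunk = half - r
            if np.any(shrunk <= 0):
                continue
            u = rng.uniform(-1, 1, size=3)
            if np.sum(u**2) > 1.0:
                continue
            c = u * shrunk
            if all(np.linalg.norm(c - c2) > r + r2 + 1.0 for c2, r2 in placed):
                placed.append((c, r))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place {spec.n_lesions} non-overlapping lesions "
                f"of radius {spec.lesion_radius_range} inside half-axes {tuple(half)}"
            )
    return placed


def _phantom_grid(spec: PhantomSpec) -> GridRef:
    half = np.asarray(spec.prostate_half_axes) + spec.grid_margin_mm
    sp = np.asarray(spec.voxel_spacing)
    shape = tuple(int(np.ceil(2 * h / s)) for h, s in zip(half, sp))
    origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, sp))
    return GridRef(shape, tuple(sp), origin)


def generate_phantom(
    spec: PhantomSpec, seed: int, patient_id: str = "P001", cohort: str = "I"
) -> Phantom:
    """Generate one synthetic patient bundle with full ground truth.

    Deterministic given (spec, seed).  The section frame coincides with the
    aligned PET world frame; the returned transform chain is the identity
    plus the sampled misregistration (if the spec's range is nonzero), whose
    truth is recorded for recovery experiments.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, spec.rng_seed & 0x7FFFFFFF])
    grid = _phantom_grid(spec)
    geom = SectionGeometry(
        base_z=-float(spec.prostate_half_axes[2]),
        slab_thickness=spec.section_thickness,
    )
    lesions = _place_lesions(spec, rng)

    areas: list[HistoArea] = []
    cell_frames: list[pd.DataFrame] = []
    lesion_truths: list[LesionTruth] = []
    area_hscores: dict[str, float] = {}
    area_polygons: dict[str, object] = {}
    area_records: list[tuple[int, object, float]] = []  # (section, poly_mm, hscore)

    n_sections = int(np.ceil(2 * spec.prostate_half_axes[2] / spec.section_thickness))
    for j, (c, r) in enumerate(lesions):
        probs = rng.dirichlet(spec.lesion_alpha(j))
        lesion_truths.append(LesionTruth(tuple(c), r, tuple(probs)))
        for s in range(1, n_sections + 1):
            zc = geom.slab_center(s)
            dz = zc - c[2]
            if abs(dz) >= r:
                continue
            rho = float(np.sqrt(r**2 - dz**2))
            if rho < spec.min_cross_section_radius:
                continue
            poly_mm = Point(c[0], c[1]).buffer(rho, quad_segs=24)
            poly_um = affinity.scale(
                poly_mm, xfact=geom.um_per_mm, yfact=geom.um_per_mm, origin=(0, 0)
            )
            area_id = f"{patient_id}:L{j}:S{s}"
            table = generate_cell_table(
                probs,
                spec.n_cells_per_area,
                rng.integers(0, 2**31 - 1),
                area_id=area_id,
            )
            h = compute_hscore(table, area_id)
            areas.append(
                HistoArea(
                    patient_id=patient_id,
                    section=s,
                    area_id=area_id,
                    polygon=poly_um,
                    label=f"lesion_{j}",
                    hscore=h,
                    area_unit=spec.area_unit,
                )
            )
            cell_frames.append(table)
            area_hscores[area_id] = h
            area_polygons[area_id] = poly_um
            area_records.append((s, poly_mm, h))

    # true uptake: a voxel carries the area's value when any of its in-plane
    # sub-samples falls inside the polygon — the same footprint the
    # sub-voxel extraction sees, so the blur-free phantom is exactly linear
    # and the PSF blur is the sole source of partial-volume effects.
    vals = np.full(grid.shape, spec.uptake_background, dtype=float)
    sf = int(spec.uptake_sub_factor)
    ax = [grid.origin_arr[d] + np.arange(grid.shape[d]) * grid.spacing_arr[d] for d in range(3)]
    fine_ax = [
        grid.origin_arr[d]
        + (np.arange(grid.shape[d] * sf) + 0.5) / sf * grid.spacing_arr[d]
        - 0.5 * grid.spacing_arr[d]
        for d in range(2)
    ]
    fx, fy = np.meshgrid(fine_ax[0], fine_ax[1], indexing="ij")
    for s, poly_mm, h in area_records:
        z0, z1 = geom.slab_bounds(s)
        kz = np.flatnonzero((ax[2] >= z0) & (ax[2] < z1))
        if kz.size == 0:
            continue
        fine = shapely.contains_xy(poly_mm, fx.ravel(), fy.ravel()).reshape(fx.shape)
        footprint = (
            fine.reshape(grid.shape[0], sf, grid.shape[1], sf).any(axis=(1, 3))
        )
        for k in kz:
            vals[:, :, k][footprint] = spec.uptake_background + spec.uptake_slope * h
    uptake_true = ScalarVolume(vals, grid.spacing, grid.origin, "g/ml")

    pet = simulate_pet(
        uptake_true, spec.psf_fwhm, spec.noise_sd, rng.integers(0, 2**31 - 1)
    )
    gtv = contour_gtv(pet, spec.gtv_threshold, spec.gtv_min_component_voxels)

    misreg = sample_misregistration(
        spec.misregistration_range,
        rng,
        center=(0.0, 0.0, 0.0),
        max_rot_deg=spec.misregistration_max_rot_deg,
    )
    chain = TransformChain.identity() if misreg.is_identity else TransformChain([misreg])

    cells = (
        pd.concat(cell_frames, ignore_index=True)
        if cell_frames
        else pd.DataFrame({"area_id": [], "cell_id": [], "level": []})
    )
    truth = PhantomTruth(
        lesions=lesion_truths,
        area_hscores=area_hscores,
        area_polygons=area_polygons,
        uptake_true=uptake_true,
        misregistration=misreg,
        gtv=gtv,
    )
    return Phantom(
        patient_id=patient_id,
        spec=spec,
        geom=geom,
        areas=areas,
        cells=cells,
        chain=chain,
        pet=pet,
        gtv=gtv,
        truth=truth,
        cohort=cohort,
    )


@dataclass(frozen=True)
class CohortScenario:
    """Two-tracer cohort layout with per-cohort overrides.

    Cohort II's default uptake slope is twice cohort I's, with its GTV
    threshold scaled accordingly and the sharper scanner PSF, emulating the
    roughly twofold tumour-area SUV scale between the tracers.
    """

    n_cohort_i: int
    n_cohort_ii: int
    base_spec: PhantomSpec = PhantomSpec()
    cohort_i_overrides: dict = field(
        default_factory=lambda: {"uptake_slope": 0.09, "psf_fwhm": 4.8, "gtv_threshold": 4.0}
    )
    cohort_ii_overrides: dict = field(
        default_factory=lambda: {"uptake_slope": 0.18, "psf_fwhm": 4.2, "gtv_threshold": 8.0}
    )

    def __post_init__(self) -> None:
        if self.n_cohort_i < 1 or self.n_cohort_ii < 1:
            raise ValueError("cohort sizes must be >= 1")


def make_cohort(scenario: CohortScenario, seed: int) -> list[Phantom]:
    """Generate the two tracer cohorts; deterministic given (scenario, seed)."""
    ss = np.random.SeedSequence(int(seed))
    n_total = scenario.n_cohort_i + scenario.n_cohort_ii
    child_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_total)]
    out: list[Phantom] = []
    idx = 0
    for cohort, n, overrides in (
        ("I", scenario.n_cohort_i, scenario.cohort_i_overrides),
        ("II", scenario.n_cohort_ii, scenario.cohort_ii_overrides),
    ):
        spec = replace(scenario.base_spec, **overrides) if overrides else scenario.base_spec
        for _ in range(n):
            idx += 1
            out.append(
                generate_phantom(
                    spec, child_seeds[idx - 1], patient_id=f"P{idx:03d}", cohort=cohort
                )
            )
    return out
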