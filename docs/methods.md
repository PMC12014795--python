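# Methods

`histopet` reimplements, as a tested library, a quantification chain that
links immunohistochemical PSMA expression on whole-mount prostate sections
to PSMA-PET uptake: H-Score computation over pathologist-defined cancer
areas, slab-model co-registration of those areas into the PET frame,
sub-voxel extraction of SUV statistics and PET-GTV overlap, and the
nonparametric statistical analysis connecting them.  Because no patient
imaging or annotation data accompany the protocol, a synthetic phantom
generator with full ground truth is a first-class component: every
quantitative claim the package makes is a parameter-recovery or
partial-volume experiment on phantoms.

## The model

**H-Score.** Each cell in a cancer area carries a staining level
$i \in \{0,1,2,3\}$; the area's score is
$H = \sum_i i \cdot (100\, n_i / n)$, algebraically $100 \times$ the mean
staining level, so $H \in [0, 300]$.  Exact cell fractions are used rather
than integer-rounded percentages.  Areas are stratified into four
expression groups with closed integer limits — very low (0–75), low
(76–132), medium (133–180), high (181–300).  Non-integer scores (possible
on synthetic data) are assigned by extending each interval to its half-open
real hull $[lo, hi{+}1)$, the last interval staying closed; the printed
integer limits are preserved and assignment is total on $[0,300]$.

**Uptake model.** The phantom posits a linear through-origin relation offset
by background,
$\mathrm{SUV}_{\text{true}} = b + s \cdot H$, with default slope
$s = 0.09$ g/ml per H-Score unit (the scale of the SUVmean relation the
protocol reports) and background $b = 0.5$ g/ml.  Cohort II (the second
tracer) defaults to twice cohort I's slope with a proportionally scaled GTV
threshold and the sharper scanner PSF (4.2 vs 4.8 mm FWHM), a qualitative
emulation of the roughly twofold SUV scale between the tracers.
Nonlinearity of real tracer binding is out of scope.

**Phantom geometry.** A patient is an ellipsoidal prostate (half-axes
22 × 18 × 20 mm) containing non-overlapping spherical lesions placed by
rejection sampling (bounded attempts; failure raises a placement error).
Sections are 4 mm slabs perpendicular to z, numbered from the base; each
lesion's cross-section at a slab centre becomes a histo-area polygon
(64-gon, coordinates stored in µm).  Cross-sections with radius under
0.8 mm are dropped as sub-voxel slivers.  Each lesion draws a staining
distribution from a Dirichlet prior (flat by default; per-lesion
concentrations can target specific H-Scores via the Binomial(3, H/300)
profile), and each histo-area gets its own multinomial cell table — so the
recorded truth H-Score *is* the H-Score the histology module computes from
the table, exactly.

**Uptake digitization.** A voxel carries an area's uptake value when any of
its in-plane sub-samples (default 1/4-voxel spacing) falls inside the
polygon, restricted to the area's slab.  This "footprint" digitization
matches the support the sub-voxel extraction sees, so in the blur-free
noiseless phantom the extracted SUVmean of a region equals $b + sH$ exactly
and the PSF blur is the *sole* source of partial-volume effects.  A
centre-sampling or volume-averaging digitization would couple boundary-voxel
values with fractional occupancy weights and bias region SUVmean low by
up to ~10% for 4–8 mm lesions, conflating digitization with PVE.

**PET simulation.** The PSF is an isotropic world-space Gaussian
($\sigma = \mathrm{FWHM}/2\sqrt{2\ln 2}$), applied per axis in voxel units
as a separable *integrated* Gaussian kernel
$k[m] = \Phi\!\big(\tfrac{m+1/2}{\sigma_{\mathrm{vox}}}\big) -
\Phi\!\big(\tfrac{m-1/2}{\sigma_{\mathrm{vox}}}\big)$ — the exact sample of
the voxel (box) image convolved with the Gaussian.  At PET resolution the
kernel σ is about one voxel, where a plain sampled-Gaussian kernel
overweights the centre by several percent and distorts recovery
coefficients; the integrated kernel matches a 0.25 mm numerical-convolution
oracle to well under 2%.  The kernel is normalized to unit sum: constants
and total activity are preserved exactly (boundary mode "nearest").  The
effective PSF therefore includes the 2 mm voxel aperture, as in a real
sampled system.  Noise is i.i.d. additive Gaussian on voxel SUV, clipped at
0 — a controllability choice, not a reconstruction model; its magnitude is
a config knob.  The GTV surrogate thresholds the noisy volume (defaults
4 g/ml cohort I, 8 g/ml cohort II, motivated by the 0–5 / 0–10 SUV display
windows used for manual contouring) and removes connected components below
4 voxels (26-connectivity).  It is a surrogate, never asserted as the
manual consensus method.

**Misregistration.** One rigid transform per patient: translation magnitude
uniform in the configured range (default 1–16 mm, the protocol's position
correction range), random direction, rotation uniform in ±5° about a random
axis through the prostate centre.  A degenerate (0, 0) range means "no
misregistration" and returns the exact identity.  The truth transform is
recorded for recovery experiments.

## Co-registration

Polygons are extruded through their half-open slab
$[z_0 + (s{-}1)t,\; z_0 + st)$, mapped through the transform chain
(section → ex-vivo CT → in-vivo CT → PET; rigid/affine 4×4 matrices plus
optional dense displacement fields inverted by fixed-point iteration) and
rasterized by inverse-mapping fine-cell centres at 1/4 of the PET spacing.
Masks are fractional occupancy on that sub-grid, restricted to a
voxel-aligned bounding box; parts outside the image are clipped with a
warning and a fully empty result is an error.

*Pathway 1 (tumour volumes).* Histo-areas are grouped into longitudinal
lesions by an adjacency rule: areas on consecutive sections whose polygons
overlap in-plane are chained transitively; disjoint stacks are never
bridged.  Gaps between occupied slabs are filled by shape-based
interpolation — the in-plane signed distance functions of the two bounding
contours (computed exactly with shapely) are blended linearly in z between
the slab centres and thresholded at zero.  Identical contours therefore
interpolate to a cylinder; a single section yields its slab extrusion only.
Interpolation runs between occupied sections only; extending volumes
towards base/apex is deliberately not done (the protocol's "base to apex"
phrasing is ambiguous on this point).

*Pathway 2 (tumour areas).* One patient's histo-areas in the same H-Score
group are united (cell-wise max of occupancies) with no z-interpolation;
each tumour area carries the area-weighted mean and SD of its constituents'
H-Scores.  The weighted SD uses the population (biased) form — the
protocol does not state its estimator — with a reliability-weights
alternative switchable in `weighted_hscore`.

*Rigid refinement.* The automated stand-in for the visual position
correction maximizes the occupancy-weighted SUVmean of a region over rigid
perturbations (±16 mm translation, ±5° rotation), deterministically:
(1) whole-voxel translations scored for all candidates at once by FFT
cross-correlation of the voxel-weight map with the PET volume; (2) per-axis
rotation sweep (0.5° steps) about the region centroid; (3) sub-voxel
translation refinement (0.5 mm steps within ±2 mm).  Ties break toward the
smallest displacement, then lexicographic axis order.  A flat objective
(uniform PET) returns the identity with a flag.  SUVmean rather than SUVmax
is the objective to limit noise sensitivity.

## PET metrics

Region statistics are computed on the PET grid without resampling the
image: voxel weight = fraction of its sub-cells inside the region,
$\mathrm{SUV}_{\text{mean}} = \sum w_v \mathrm{SUV}_v / \sum w_v$, volume =
$\sum w_v \cdot v_{\text{vox}}$ (fractional; a voxelized any-overlap count
is reported alongside), and $\mathrm{SUV}_{\text{max}}$ over voxels with
weight above a floor, default 0 — any overlap counts, the convention that
favours small regions.  SUV values are never interpolated.  *GTV agreement*
is the occupancy fraction of a region inside the GTV — Dice-like but
normalized by the region alone; fractional weights by default, a binarized
mode for oracle comparisons.

Numerical notes: centre-sampling rasterization at sub-factor 4 has a
worst-case per-voxel weight error of ~1/16 on boundary voxels (aggregate
error an order of magnitude smaller); region SUVmean converges to a sub-16
oracle within 0.5%.  For ellipsoidal helper regions the voxel support is
computed exactly (closest-box-point test in sphere space) so that SUVmax
eligibility does not depend on the sub-resolution.

## Statistics

Spearman correlations use average-rank tie handling with the standard
large-sample p approximation; the 95% CI is a seeded percentile bootstrap
(10,000 resamples, vectorized) by default, with a Fisher-z interval
(Bonett–Wright SE) as the cheap alternative — the protocol does not state
its CI method.  Kruskal–Wallis is the tie-corrected H with a χ² p (k−1 df);
all-identical data returns H = 0, p = 1.  Dunn's post-hoc z uses the pooled
tie-corrected rank variance; the default applies *no* multiplicity
adjustment, mirroring the protocol's stated practice, with Holm/Bonferroni
selectable.  The fixed-intercept regression reports
$\hat s = \sum xy / \sum x^2$, its SE with n−1 df, and the *uncentered*
$R^2 = 1 - \mathrm{RSS} / \sum y^2$ (the only well-defined convention
through the origin; printed in all outputs).  Independent correlations are
compared by the Fisher-z test — again a method choice, labelled as an
interpretation.  All randomness sits behind a single master seed in the
analysis config.

`run_study` executes both pathways per patient (optionally refining each
region), then emits tidy tables: per-unit metrics; correlations over the
subsets all / per-cohort / size-filtered (volumes > 1 ml, areas > 400 in
the histology area unit, patients with GTV > 5 ml — the protocol's
thresholds as defaults); group comparisons of SUVmean/SUVmax/agreement
across the four expression groups and the two cohorts; through-origin
regressions; and the cohort correlation comparison.  Patients missing an
input layer are skipped with a logged reason, never silently.

On the area unit: the protocol's own area statistics (median tens of µm²)
are implausibly small for whole-mount cancer regions, likely a units slip
for mm².  The generator labels its unit (`area_unit`, µm² by default,
mm-scale polygons, so synthetic areas are ~10⁷–10⁸ µm²) and does not
resolve the discrepancy; the 400 µm² filter is a pass-through subset on
synthetic data.

## Canonical experiments

`histopet.experiments` freezes the study conditions so the test suite and
`scripts/acceptance.py` run one protocol:

* **Linear phantom** (slope recovery): 8 patients × 3 lesions (radii
  4–9 mm), per-lesion staining priors targeting H ≈ 40/150/260 (3,000
  cells/area), background 0, no blur, no noise, aligned.  The
  through-origin fit over the ~24 tumour areas recovers s = 0.09 g/ml to
  well under 1% and Spearman ρ ≈ 1.
* **PVE cohort** (size dependence, group ordering): 100 seeded cohorts of
  20 patients × 4 lesions (radii 1.5–10 mm), flat staining prior, 4.8 mm
  FWHM, 1.0 g/ml noise, GTV threshold 4 g/ml, aligned.  Cohort size was
  fixed at design time by a power analysis: the size-tertile correlation
  contrast (ρ over the largest third of areas vs the smallest) needs ~60
  areas per cohort to be detectable in ≥95% of cohorts.  The same cohorts
  yield the group-ordering result: pooled median GTV agreement rises
  monotonically across very low → high, and the very_low-vs-high Dunn
  comparison rejects at α = 0.05 in ≈100% of cohorts.
* **Registration recovery**: 100 single-lesion, low-noise (0.1 g/ml)
  phantoms with an injected 1–16 mm misregistration; the refined transform
  must land within one PET voxel (2 mm) of the truth inverse at the region
  centroid (≈98% success, median error ≈0.3 mm).
* **Calibration**: Kruskal–Wallis null rejection rate over 10,000
  replicates of 3×20 standard normals (≈0.046), and bootstrap CI coverage
  for ρ over 1,000 replicates of independent normals at n = 76 (≈0.95).

The aligned state of the first two experiments represents the analyses the
protocol performs *after* its position correction; recovery of the
correction itself is the third experiment.

## What the phantoms do and do not show

The generator emulates the statistical structure the analysis assumes —
heterogeneous per-area expression, linear uptake, Gaussian PSF at device
FWHM, 2 mm SUV voxels, threshold GTVs, rigid residual misregistration — but
not: deformable ex-vivo shrinkage (supplied displacement fields are
applied, never estimated), anatomically realistic prostate or lesion
shapes, reconstruction noise correlations, attenuation/scatter, tracer
kinetics, or inter-observer contouring variability.  Passing tests
therefore demonstrate that the *pipeline* recovers known parameters under
its stated model, not that the model captures every property of patient
data.  Problem sizes (cohort counts, seeds, grid extents) are the package's
default experiment scale, chosen to make the recovery statistics stable.

## Known limitations

* Lesion identity across sections uses in-plane polygon overlap on
  consecutive sections; lesions that skip a section are split.
* The rotation search is a per-axis sweep, not a joint optimization; for
  the ≤5° range used it is within the translation tolerance.
* NIfTI/NRRD support is restricted to axis-aligned orientations; anything
  else is a hard error rather than a silent re-orientation.
* Non-integer H-Score group boundaries are a convention of this package;
  the printed limits only constrain integers.
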