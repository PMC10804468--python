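# Methods

This note documents the models, algorithms and numerical choices behind
`apteval`, a desk-scale evaluation pipeline for CBCT-guided offline
adaptive intensity-modulated proton therapy (IMPT) of head-and-neck
cancer. The pipeline has five stages: synthetic anatomy, deformable
registration and synthetic-CT (sCT) construction, proton dose
calculation, robust planning and weekly re-planning, and quantitative
evaluation (gamma, DSC, DVH, NTCP, statistics).

## Synthetic anatomy

Patients are replaced by axial-cylindrical digital phantoms: an
elliptical soft-tissue body (≈40 HU, default semi-axes 75 × 62 mm) in
air, a bony spine (700 HU) with a spinal-cord core, a mandible arc
(1200 HU) with an optional dental-artifact region (streaks alternating
+1500/−900 HU), an airway cavity, larynx (with air core), pharyngeal
constrictor arc, bilateral parotids, an esophagus, and a spherical tumor
carrying up to three nested CTVs (primary ⊆ secondary ⊆ tertiary;
default prescriptions 70/63/56 Gy in 35 fractions, within the standard
56–70 Gy / 30–35-fraction range). The tertiary CTV extends inferiorly,
so a phantom variant with a tight axial CBCT field of view reproduces
the situation where elective target extends beyond the imaged volume.
The default grid is 2 mm isotropic, 96 × 96 × 64 voxels; study drivers
and tests use geometrically scaled phantoms and/or 4 mm grids.

Weekly anatomy change is an *analytic* pull-back displacement field
(`deformed(x) = planning(x + u(x))`): an in-plane radial scaling about
the body axis (weight loss; the weekly shrink fraction is the fractional
radius reduction per week) windowed smoothly to zero at the grid edge,
plus a Gaussian-windowed radial scaling about the tumor centre (growth
or shrinkage). Because the field is analytic, the exact deformation —
and therefore exact deformed contours and a near-exact inverse — is
available to every downstream oracle test. Fields are validated against
a per-voxel Jacobian row-sum bound (< 0.95) that guarantees fixed-point
invertibility; violating trajectories are rejected rather than silently
folded. Trajectory amplitudes are free parameters: the cohort defaults
(2%/week body shrink, ±3%/week tumor radius change) are plausible
magnitudes for the severe anatomy change the adaptation question is
about, not fits to any dataset.

The CBCT degradation model adds a radial low-frequency cupping bias
(default amplitude 60 HU, depressed at the centre), seeded Gaussian HU
noise (default σ = 15 HU), and a limited axial field of view; voxels
outside the FOV are flagged invalid. It deliberately contains no
projection/reconstruction physics or scatter simulation — only the three
image-quality features the sCT workflow must be robust to (bias, noise,
truncation).

What passing tests on these phantoms show — and what they do not: the
pipeline's algorithms behave correctly against known ground truth under
CBCT-like degradation and realistic-magnitude anatomy change; they say
nothing about registration accuracy on real anatomical detail (there is
none), nor about absolute clinical dose accuracy.

## Registration, sCT and contours

Deformable registration is a multi-resolution B-spline free-form
deformation (SimpleITK `ImageRegistrationMethod`): three pyramid levels,
control-point spacing 64/32/16 mm, LBFGS2 with a fixed iteration cap,
and dense regular-grid metric sampling at 10% with a fixed seed — fully
reproducible, no random initialisation. The default similarity is a
locally normalised cross-correlation (ANTS neighbourhood correlation,
radius 2 voxels), chosen because it is insensitive to the CBCT cupping
bias; SSD after an explicit low-pass bias pre-correction (σ = 30 mm) is
available. The metric is evaluated only inside the CBCT FOV. Smoothness
is controlled by the hierarchical control-point spacing rather than an
explicit bending-energy term; the `smoothness_weight` config field is
retained for compatibility and documents this mapping. The phantom has
no setup error by default; a known rigid pre-alignment can be supplied
as a translation composed with the B-spline result.

The DVF lives on the CBCT grid in the pull-back convention, so the sCT
is built by direct resampling: the planning CT — with the dental
artifact overridden to soft tissue (40 HU) *before* warping, so the
overridden value is what gets transferred — is warped trilinearly onto
the CBCT grid; outside the FOV, voxels are copied bitwise from the
unwarped override-applied planning CT (hard switch at the seam, with a
provenance map recorded). The gold standard for HU and dose is the
noise-free deformed CT registered to the same CBCT (the repeat-CT role).
Contours are propagated by warping mask indicators trilinearly and
thresholding at 0.5; "physician-corrected" contours are operationalised
as the ground-truth deformed masks, "uncorrected" contours as whatever
the registration propagates.

DVF inversion uses the fixed-point iteration `v(x) ← −u(x + v(x))`
(trilinear sampling, edge-clamped), stopping when the composition
residual `max|u(x+v(x)) + v(x)|` falls below 0.05 mm (cap 60
iterations); non-convergence raises with the worst residual.

## Proton dose engine

A water-equivalent-thickness (WET) indexed analytic pencil-beam model
stands in for a commercial dose algorithm. HU map to relative stopping
power through a piecewise-linear calibration (water anchor fixed at
(0 HU, 1.0); default anchors span air to dense bone). WET depth maps are
exact cumulative sums for axis-aligned beams; oblique axial beams
rotate-resample the RSP volume (padded so no path is clipped),
accumulate, and rotate back.

The depth dose is a peak-normalised analytic Bragg curve: a Gaussian
peak at the nominal range R riding on a slowly rising proximal plateau
(entrance ≈ 27% of peak) that is switched off sigmoidally at the peak,
tapered linearly to exactly zero between R + 5σ and R + 6σ. The distal
width is σ(R) = √((0.012 R^0.935)² + (0.025 R)²) + 0.8 mm — range
straggling plus a 2.5% beamline energy spread. The energy-spread term is
a deliberate design choice: it keeps adjacent energy layers (6 mm WET
apart by default) overlapping smoothly, which real synchrotron/cyclotron
lines achieve and which worst-case robust optimization requires. Lateral
spread is Gaussian with σ(d) = 4 mm + 0.03·d, normalised so integrated
lateral dose is depth-independent. Doses are RBE-weighted by the
constant factor 1.1 throughout.

Spots are placed per beam on a lateral grid (8 mm default) over the
field-specific target — the union of the CTVs expanded isotropically by
the 3 mm setup margin — with energy layers (6 mm WET) spanning each
lateral position's WET extent expanded by the ±3% range margin. Spot
positions additionally cover a 4 mm lateral penumbra margin beyond the
field target so the optimizer can edge-enhance under setup shifts; the
field-target mask itself is not widened. Spots whose entrance ray
crosses the chin/teeth avoidance region before reaching the target are
removed. Default beams: two lateral-opposed fields along ±x — in the
clinic angles are chosen per tumor anatomy, so none is canonical;
axis-aligned beams make WET maps exact and cheap, and any axial angle
is supported.

Uncertainty scenarios re-evaluate the same spots with (a) the dose
pattern rigidly shifted in the patient frame (the WET depth of a voxel
along a parallel beam is shift-invariant, so only the lateral
coordinates move — a shift along the beam axis correctly leaves the dose
in the anatomy almost unchanged) and (b) every nominal range scaled by
0.97 or 1.03. Influence matrices are sparse (entries below 10⁻⁴ of each
spot's maximum dropped — this cutoff bounds DVH errors at well below the
0.5% quantization of interest), stored float32/int32, and total dose is
linear in the spot weights.

## Robust planning

The scenario set is the Cartesian product of the six signed 3 mm
cardinal shifts with the two range scales — 12 scenarios — plus the
nominal. Objectives are generated by fixed rules (the stand-in for the
commercial DVH-prediction model): per CTV a robust minimum-dose
objective at prescription (weight 1000) and a robust maximum at 103% of
prescription (weight 10); per OAR one objective at 90% of its clinical
constraint (weight 3; the whole-body hotspot objective ×5), non-robust.
Constraint table: body Dmax < 115% of prescription, brainstem Dmax < 54,
cochlea Dmean < 40, constrictor Dmean < 50, larynx Dmean < 50, mandible
Dmax < 75, oral cavity Dmean < 50, spinal cord Dmax < 48, parotid
Dmean < 26 and V20Gy < 50%, esophagus Dmean < 40, eye Dmax < 45, optic
nerve/chiasm Dmax < 50, submandibular Dmean < 39 (Gy, %).

The optimizer minimises a sum of one-sided quadratic penalties
(normalised by the squared dose level) over non-negative spot weights
with L-BFGS-B (bounds, uniform initialisation scaled so the first
target's mean dose starts at prescription, 120-iteration cap —
deterministic). Target penalties are aggregated as the worst case over
the 12 scenarios plus nominal (configurable to include/exclude nominal
and to use expectation instead); OAR penalties are nominal-only,
matching "targets only" robustness. DVH-point objectives penalise the
excess voxels just above the dose level. The implementation performs one
matvec per influence matrix per iteration and pulls gradients back with
transposed matvecs, keeping the 2 mm default problem under ~3 GB.

Normalisation rescales all weights so that exactly 95% of primary-CTV
voxels (m = ⌈0.95 N⌉, ties toward coverage) receive the full
prescription — V100 = 95% up to the 100/N voxel quantization.
Idempotent by construction. Robust evaluation reports each CTV's V95
under every scenario and passes when the worst case exceeds 95%.

Weekly adaptation is a cold-start re-run of the entire chain (spot
placement → objectives → optimization → normalization) on the weekly
sCT with the ground-truth weekly contours; no warm start, so the two
arms differ only in the anatomy the optimizer sees.

## Evaluation

* **Indices** — Dmean, single-voxel Dmax (no near-max percentile), VxGy
  as the percentage of structure voxels at or above x Gy (inclusive),
  V95/V100 relative to each structure's own prescription.
* **Gamma** — 3D global gamma with dose-difference and DTA criteria,
  normalised by the primary prescription by default (global-max
  available), restricted to reference voxels above 10% of the
  normalisation dose. The minimum is searched over offsets on a grid of
  step ⅓·DTA (tests use the 0.1·DTA step their brute-force oracle also
  uses) within a radius of 2·DTA, with trilinear interpolation of the
  evaluated dose; γ ≤ 1 counts as a pass (inclusive).
* **Accumulation** — weekly full-course doses are warped to the planning
  CT through the inverse of the DVF that built each week's sCT and
  averaged with fraction weights (fractions 1, 6, 11, … blocks; the last
  block absorbs the remainder), making the accumulated dose commensurate
  with the planned full-course dose.
* **NTCP** — gEUD (Σvᵢdᵢ^{1/n})ⁿ fed into the LKB model
  Φ((gEUD − TD50)/(m·TD50)). The shipped parameter table
  (`apteval/data/ntcp_params.yaml`) contains clearly-labelled literature
  stand-in defaults per endpoint (laryngeal edema n=0.45 m=0.27
  TD50=46.3; dysphagia, xerostomia, esophagitis as mean-dose models) and
  is user-editable; no EQD2 conversion is applied.
* **Statistics** — two-sided paired t-test across the cohort;
  zero-variance differences are flagged with p reported as 1.0 rather
  than raised.

## Problem sizes and determinism

Unit tests run on half-scale phantoms (48 × 48 × 32 at 2 mm) and toy
grids; the study drivers and cohort-level checks use the full-size
anatomy on a 4 mm grid (48 × 48 × 32) with 3 weekly samples, and the
plan-normalisation check additionally runs the default 2 mm phantom.
Every stage is deterministic under a fixed master seed: phantom seeds
derive from it by a counter scheme, CBCT noise is seeded per
phantom-week, the registration samples its metric on a fixed-seed
regular grid, and the optimizer has no stochastic component.

## Known limitations

No scatter/projection physics in the CBCT model; no nuclear halo, beam
divergence, or Monte Carlo transport in the dose engine; no
patient-derived anatomy, so absolute dosimetric and NTCP magnitudes are
illustrative (the larynx sits close to the target in the default
phantom, giving NTCP values in the steep part of the LKB curve);
lateral-opposed default beams are a simple choice, not a clinical
arrangement; DSC is the only contour metric (no surface distances); and
the fixed-point inversion requires displacement Jacobians below unity,
which the generator enforces but arbitrary imported DVFs might violate.
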