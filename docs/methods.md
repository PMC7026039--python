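# Methods

This note documents the models and numerical choices behind atlasforge: what
each stage computes, the parameters that matter, what the synthetic phantoms
do and do not emulate, and the known limitations.

## Image model and conventions

A `Volume` is a 3D scalar grid with per-axis spacing in mm, a voxel-to-world
affine (RAS, NIfTI-1), and a modality tag (`MR`/`CT`). Displacement fields
live on the fixed grid with components in **voxel units**; conversion to mm
happens only at I/O (fields are written as 4D NIfTI with the vector
dimension last). All warping is pull-back: `out(x) = in(x + d(x))`, linear
interpolation, constant fill outside the domain (0 for MR, −1000 HU for CT).
Affine transforms are stored in the same pull-back convention,
`x_moving = L x_fixed + t`, with `t` in voxel units of the fixed grid; the
pipeline operates on 1 mm isotropic resampled volumes, where voxel units and
mm coincide. `flip_x` reverses the first voxel axis on a fixed grid, so
content is mirrored about the grid mid-plane; the affine is kept, which is
what the symmetrization average requires (both summands on one grid).

## Registration

**Rigid/affine.** Deterministic Powell search over an explicit parameter
vector (translations; Euler angles; log-scales and shears for affine) on a
3-level image pyramid (downsampling 4, 2, 1 with pre-smoothing σ = factor/2).
The translation is initialized from the centers of mass. Two safeguards
address flat or multimodal similarity landscapes:

- capture-range bounds (|t| ≤ extent/6, |angle| ≤ 45°, |log-scale|, |shear|
  ≤ 0.5): inputs are always roughly pre-aligned in this pipeline, and the
  bounds exclude pathological optima such as the point reflection that fits
  any centrally symmetric object;
- a mild multiplicative penalty (≤ ~5% at the bounds) preferring the
  smallest transform inside a flat valley. Near sharp optima the penalty is
  orders of magnitude below the metric curvature and does not bias recovery
  (translations recover to < 0.5 voxel, rotations to < 1°, scales to < 2% on
  phantoms).

Similarity metrics: SSD (intramodal default), negated normalized
cross-correlation, and 32×32-bin joint-histogram mutual information
(intermodal). All optimization is deterministic; there is no stochastic
sampling anywhere in the package.

**Diffeomorphic.** A stationary-velocity demons scheme: per iteration, the
demons force `−diff·∇w/(|∇w|² + diff²)` (computed on range-normalized
images) is smoothed with σ_update, scaled by the step length, added to the
velocity, and the velocity is smoothed with σ_field. The displacement is the
group exponential of the velocity via scaling and squaring, so smooth
velocities always yield invertible maps; in addition every step is accepted
only if the Jacobian determinant of (identity + displacement) stays strictly
positive and the cost does not increase (otherwise the step is halved, up to
four times). The metric trace is therefore non-increasing within each
resolution level. The schedule is (30, 50, 20) maximum cycles at factors
(4, 2, 1); slice-to-slice 2D work uses the scaled-down (15, 25, 10).

Defaults σ_update = 1.5, σ_field = 1.0, step = 1.0 voxel were fixed by
requiring the expanding-sphere benchmark (radius 8 → 12) to reach Dice >
0.95 with a positive Jacobian; heavier regularization (e.g. σ_field = 1.5,
step 0.5) is smoother but under-resolves that deformation at desk scale.
The inverse transform is the exponential of the negated velocity;
`invert_field` provides fixed-point inversion for arbitrary diffeomorphic
fields (residual < 0.5 voxel contract).

**Intermodal (MI) mode.** The diffeomorphic stage reduces the intermodal
problem to an intramodal one: every 10 iterations the moving image is
remapped through the conditional mean of the fixed intensity given the
moving intensity (64-bin estimate on the current overlap), and demons runs
on the remapped image. This inherits MI's invariance to monotone intensity
remaps without needing MI gradients.

## Registration-based slice interpolation

Adjacent axial slices s0, s1 are registered in 2D (velocity v with
`warp(s1, exp(v)) ≈ s0`); the slice at fraction t is

    out = (1−t)·warp(s0, exp(−t·v)) + t·warp(s1, exp((1−t)·v)),

the symmetric two-sided blend along the correspondence trajectories. At
t ∈ {0,1} the exponential of the zero field is exactly zero, so acquired
slices are reproduced bit-exactly. Whether one-sided or symmetric transport
is used is a free design choice; the symmetric form avoids direction bias
and meets the endpoint contract without special-casing. In-plane resampling
to the target spacing is plain linear interpolation (the in-plane data is
already at or near target resolution). Output slice count follows the
physical positions: `floor((N−1)·Δz_in/Δz_out) + 1`. Each adjacent pair is
registered once and cached; for CT the pipeline interpolates skull-stripped
data only (outside-mask voxels at −1000 HU).

## CT brain extraction

Per axial slice: Gaussian smoothing with variance 4 px² (σ = 2 px),
threshold 0–100 HU, binary erosion (disk radius 1), largest 8-connected
component, binary dilation (disk radius 1). Stacked slices are then
hole-filled with an iterative majority-voting filter (face-connected
neighborhood of radius 1, strict majority, ≤ 10 iterations; foreground is
never unset). The strict majority is what keeps the filter from creeping
along gently concave surfaces while still closing enclosed holes in one
pass. The smoothing-induced boundary retreat is a fixed ~3 px against
±1000 HU neighbors, so overlap quality is resolution-dependent: at the
study-like 0.4–0.5 mm in-plane pixel size (brain ≈ 150+ px across) Dice
against ground truth exceeds 0.95, while on coarse toy grids the same
algorithm scores lower for purely geometric reasons. Tests therefore run at
study-like in-plane resolution.

## Groupwise template construction

Initialization picks a random reference subject (seeded RNG), rigidly
aligns all subjects to it, and averages. Each of the (default 4) iterations
then:

1. registers every subject to the current template (affine, then
   diffeomorphic on the affinely resampled subject);
2. averages the warped subjects voxelwise — each subject is brought to the
   template with the **composite** affine∘diffeo transform in a single
   interpolation pass (repeated resampling measurably blurs the average at
   desk scale);
3. warps the intensity average by `damping ×` the mean of the subjects'
   inverse displacement fields (the shape update toward the cohort's
   deformation barycenter), composed with
4. the symmetric stretch of the mean inverse subject affine — the polar
   decomposition removes rotation and the translation is dropped entirely,
   which is what keeps the template from drifting across iterations.

`shape_update_damping` defaults to 0.8 (1.0 reproduces the plain
mean-inverse rule; damping guards oscillation on 2–3 subject cohorts).
Subject averaging is the arithmetic mean with no trimming. Intensity
normalization (MR on, CT off by default) is a two-point linear map sending
each warped subject's robust background level (1st percentile) and robust
foreground mean (10–90% core of voxels above 5% of the range) to those of
the **initial** template. Anchoring at the background keeps the dominant
background population from being smeared across histogram bins, and
anchoring to the initial template (rather than the evolving one) avoids a
feedback loop in which template intensity drift compounds over iterations.
The map exactly inverts affine intensity remaps, so a subject equal to
`2·reference + 5` is restored to the reference's mean and sd.

Non-converged subject registrations are dropped for that iteration with a
warning; if more than 20% drop, the iteration fails.

## Post-processing

**Symmetrization.** The x-flipped template is affinely registered to the
native one and both copies are moved *halfway* along that transform (via its
principal matrix square root) before averaging. This midpoint construction
matters: averaging after a *full* deformable alignment is a no-op (the
aligned flip reproduces the native template), while averaging with no
alignment ghosts any pose asymmetry. The half-transform puts the average in
a mirror-consistent midspace, removing pose- and scale-induced left-right
bias while mirrored anatomical differences blend away. An optional `diffeo`
mode shares a deformable alignment half-and-half on top; `resample` mode is
the plain flip average (exactly grid-symmetric, pose errors ghost). The
asymmetry index is mean |v − flip(v)| / intensity range.

**Laplacian sharpening.** `out = v − strength·∇²v` with the 6-neighbor
stencil and reflective boundaries; flat regions (hence calibrated HU
plateaus) are untouched and the global mean is preserved. Default strength
0.5 (no published coefficient exists; 0.5 visibly steepens edges without
ringing on phantom plateaus).

**Bias correction.** A deliberately simple log-domain homomorphic
corrector, not an N4 reimplementation: the field is the broad Gaussian
low-pass (default σ = 15 voxels; desk-scale tests use σ = 10 against
brain-radius-16 phantoms, roughly 0.6× the object radius) of log-intensities
within the mask, estimated by normalized convolution over parenchyma-like
voxels only (within ±0.5 log-units of the in-mask median — ventricles and
residual bone would otherwise imprint anatomy onto the field), with two
residual-refinement passes to compensate low-pass attenuation and mask-edge
one-sidedness. The field is normalized to unit geometric mean and divided
out inside the mask; the mask mean is preserved to within 1%. Limitation:
intensity structure as smooth as the bias field itself (e.g. a gentle
radial tissue gradient) is partially absorbed — inherent to any
prior-free homomorphic corrector.

**Intermodal co-registration.** Affine (MI metric) then diffeomorphic (MI
mode above); the one final resampling of the CT template uses a separable
Lanczos-windowed sinc kernel with a = 3 (order unreported in the method
being followed; a = 3 is the common default), with weight renormalization so
flat regions stay flat.

## Entropy metric

`H = −Σ pᵢ ln pᵢ` over 256 equal-width bins (nats). Default binning spans
the data (min–max) with background included; both the bin range and
background handling are configurable because the published binning domain
for atlas entropies is not stated. H is invariant under affine intensity
remaps with min–max binning and bounded by ln 256 ≈ 5.545.

## Phantoms: what they emulate, what they do not

Phantoms are smoothed ellipsoids with a low-frequency sinusoidal boundary
ripple (something for registration to latch onto), two interior ellipsoidal
"lateral ventricles" scaled by a single atrophy proxy, an optional high-HU
skull shell (CT), a low-order multiplicative bias field, and additive
Gaussian noise. MR phantoms get 0.7 px partial-volume edge smoothing (as in
real acquisitions); CT phantoms stay crisp so the three tissue classes keep
exact HU plateaus (background −1000, brain 20–40, skull 1000). Cohorts
jitter radii, ventricle scale, and rigid pose, with every draw split from
one seed (bit-reproducible). Anisotropy is simulated by through-plane box
averaging (3–5 mm slices from 1 mm data).

They do **not** model tissue microstructure, MR sequence physics, CT beam
hardening, lesions, or realistic cortical folding. Consequently, passing
tests demonstrate that the algorithms implement their contracts (topology
preservation, convergence to the cohort mean shape, HU retention,
diffeomorphism guarantees, determinism) — not that atlas quality on real
clinical data is reproduced.

## Problem sizes and experiment design

Test suites and the acceptance script run on 32³–48³ phantom grids with
2–4 subjects and 1–4 build iterations, and CT extraction at study-like
in-plane resolution (160² at 0.5 mm). Two scale effects are worth noting,
both documented above: extraction overlap depends on in-plane resolution,
and pose recovery below ~1° needs enough voxels for the anatomy's rotational
signal to exceed the voxelization noise floor (the registration benchmarks
use 48³). The sharpness-ordering experiment uses cohorts with substantial
shape variance (radii ±12%, ventricle scale 0.5–1.5), since that is the
variation groupwise alignment exists to remove; with near-identical shapes
the rigid mean is already as sharp as any template can be.

## Known limitations

- The demons engine is not a numerical replica of other diffeomorphic
  optimizers; only the contracts (invertibility, metric descent, schedule)
  are shared.
- The conditional-mean MI reduction assumes an approximately functional
  intensity relation between modalities; it is not a full MI gradient flow.
- The bias corrector is a homomorphic simplification (see above), not N4.
- MR skull stripping and mesh-based mask editing are out of scope; the CT
  extractor is the only automated brain-extraction path.
- Slice interpolation assumes adjacent-slice correspondences exist (no
  through-plane motion correction, no super-resolution).
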