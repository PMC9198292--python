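# Methods

## Model

`npvreg` registers a floating image F onto a reference R by maximizing
normalized mutual information,

    NMI(R, F; T) = (H(R) + H(F)) / H(R, F),

estimated from a joint gray-level histogram over a regular sample grid of
floating-frame lattice points. A transform T maps floating-frame points into
the reference frame (the direction in which the histogram is accumulated);
`warp_image` uses backward-warping semantics consistent with this choice, and
phantom floating images are generated by backward warping with the true
transform, so ground truth always lies exactly in the model family the
registrar fits.

### Histogram accumulation (PV / NPV)

Each in-bounds sample p contributes unit mass, split over the integer
reference-lattice neighbors n of q = T(p) with separable kernel weights
`prod_axes f(n_axis - q_axis)`. A kernel is admissible iff it is nonnegative
and its integer translates sum to one for every fractional offset (partition
of unity); both conditions are verified numerically at construction (101
offsets, 1e-12). Admissibility implies exact mass conservation: accumulated
mass equals the number of in-bounds samples. Samples whose full neighborhood
leaves the reference are skipped and counted, never clamped.

Three kernels are provided:

| kind            | support | f(0) | notes |
|-----------------|---------|------|-------|
| `linear`        | 1       | 1    | classical PV (bilinear/trilinear weights) |
| `cubic_hermite` | 1       | 1    | default NPV kernel, 2\|x\|³−3\|x\|²+1 |
| `cubic_bspline` | 2       | 2/3  | non-interpolating, strongest smoothing |

The default NPV kernel is the cubic Hermite smoothstep — the degree-3 even
kernel on |x| < 1 with f(0) = 1 satisfying both admissibility conditions. It
is C¹ in the transform parameters, which removes the kinks the linear kernel
imprints on the NMI surface while keeping the histogram interpolating
(on-lattice samples still produce a sharp diagonal). The support-2 cubic
B-spline kernel suppresses grid artifacts more aggressively — on pairs whose
true shift is half a voxel it strictly reduces the total variation and the
local-extrema count of the NMI-vs-translation curve — but, being
non-interpolating, it disperses each sample over 4^ndim neighbors and so
carries systematically lower raw NMI values at the same alignment; NMI values
are therefore only comparable between runs that use the same kernel.
`npv_accumulate` with the linear kernel reproduces `pv_accumulate`
bit-exactly, and both accumulators add contributions in sample-major order so
they equal a per-sample reference loop bit-for-bit.

Gray values in [0, levels) map to B equal-width bins (default B = 64, a
variance/speed compromise; levels default 256).

### Transform hierarchy

*Affine stage.* A homogeneous matrix, parameterized with the linear block
acting about the image center so rotation/scale decouple from translation.
The stage is initialized by aligning the two intensity centroids (the
gray-value center of mass) and runs up to two passes: a capture pass with a
low-dimensional model (rigid, in 2-D) on a coarse 16-bin histogram, then a
refinement pass with the full requested model on the full-resolution
histogram. The coarse-histogram capture pass plays the role a resolution
pyramid would play elsewhere; no image pyramid is used.

*FFD stage.* A cubic B-spline free-form deformation: control points every
λ voxels (λ must divide the image extent; default λ = 16 on 64² images),
padded by one control point per side so every image point has a full 4^ndim
support. Displacement at x is the tensor-product blend of the 4^ndim
surrounding control displacements with the standard cubic B-spline basis
(B0..B3, partition of unity verified to 1e-12). Local fractions are
lattice-normalized, u = x/λ − ⌊x/λ⌋. The fine transform is the additive
global+local form T(p) = A(p) + D(p) with D evaluated at the original point;
this keeps the FFD domain fixed and composes cleanly with any affine.

### Optimization

Both stages minimize −NMI with a DFP quasi-Newton scheme: inverse-Hessian
H updated by the rank-two DFP formula, skipped whenever the curvature
condition s·y > 0 fails; Armijo backtracking (ratio δ = 0.5, slope factor
σ = 0.1, at most 30 backtracks) chooses the step. Gradients are central
finite differences; the objective has no closed-form derivative.

Three robustness measures matter in practice and are deliberate design
choices:

- **Scaled parameters.** Each stage optimizes z-parameters where one unit
  equals one natural step of that parameter type (0.5 voxel for
  translations, 0.01 for linear-block entries, 0.02 rad for the rigid
  angle, 0.25 voxel for control displacements). This conditions the
  identity-like H₀ and makes a single finite-difference step (h = 1 in
  z-space) meaningful for every coordinate.
- **Auto-scaled H₀.** NMI gradients are numerically small, so H₀ is scaled
  to make the first step roughly unit length in z-space
  (`h0_auto_scale=1`); plain `dfp_minimize` defaults to the identity.
- **Restart and simple-decrease fallback.** On a failed line search the
  curvature estimate (built from noisy secant gradients) is discarded once
  and the search restarts from scaled steepest descent; if sufficient
  decrease is still unattainable, the largest backtracked step that merely
  decreases f is taken before giving up. The f-trace remains monotone.

The objective returns +inf when fewer than half the samples stay in bounds,
preventing the optimizer from inflating NMI by shrinking the overlap region.

Stage defaults: affine — 100 iterations max per pass, stride-2 sample grid;
FFD — 30 iterations max, stride-1 grid, ε = 1e-4 on the z-space gradient
norm. On one CPU a full 64² two-stage registration takes roughly 20 s,
dominated by the FFD stage's finite-difference gradient (2 evaluations per
control parameter per iteration).

## Preprocessing

Gray normalization maps min→0, max→levels−1 with rounding (idempotent).
Optional background stripping zeroes voxels below a threshold (default: 1st
percentile of nonzero values) and can keep only the largest connected
component; it is off by default for phantoms, which have clean backgrounds.
The threshold+component rule is this package's own stand-in for scanner
mask/bed removal — no standard procedure exists.

## The phantom generator

`make_shape_phantom` draws an eccentric, randomly oriented, off-center outer
ellipse plus large off-center interior blobs, each a distinct gray class on a
zero background. The deliberate asymmetry matters: near-rotationally-
symmetric anatomy leaves rotation almost unobservable to any intensity-based
similarity, and early concentric designs produced NMI landscapes whose
optimum did not constrain the rotation angle. `simulate_modality` permutes
the class intensities (a bijective, generally non-monotone remap — the
relationship only information-theoretic measures can exploit) and adds
clipped Gaussian noise (default σ = 2 gray levels, a mild degradation
consistent with 8-bit clinical slices). `make_registration_case` composes
phantom, remap, an analytic ground-truth warp (translation / rigid / affine /
FFD with control offsets uniform in ±magnitude / rigid+FFD), and noise;
warps that push content within 2 voxels of the border are rejected.

What the phantoms do **not** emulate: acquisition physics (bias fields,
partial-volume tissue mixing, modality-specific noise spectra), realistic
anatomy, or occlusion/missing-field-of-view effects. Passing recovery tests
therefore demonstrates correctness of the estimation machinery under the
stated model, not clinical performance.

## Evaluation

`evaluate_case` reports parameter-level errors (translation at the image
center; rotation angle from the polar decomposition of the linear block) and
dense-field errors |T̂(p) − T_true(p)| over the anatomy (mean and max).
`translation_sweep` probes the NMI surface along a translation axis for
smoothness analysis. Fusion is a green/magenta overlay (reference green,
warped floating magenta), min–max scaled per image, 8-bit RGB.

## Numerical choices and degenerate inputs

- Log base 2 (bits) throughout; NMI is base-invariant. Zero-probability
  cells contribute zero entropy by the limit convention.
- A single-occupied-cell histogram has H_RF = 0; NMI returns 2 by
  continuity.
- Cubic kernel evaluation clamps at zero: polynomial cancellation at
  |x| ≈ 1 can otherwise produce ≈ −1e-19 weights and poison histogram
  cells.
- Constant images, empty sample sets, zero-mass histograms, all-zero
  images (centroid), and non-dividing FFD spacings raise typed errors.
- FFD control indexing clamps to the padded storage so edge and
  out-of-domain queries (which arise during displacement-field inversion)
  extrapolate from the boundary cell.
- Resampling into the reference frame inverts affines analytically and
  non-rigid transforms by fixed-point iteration on the displacement field
  (10 iterations) — adequate for the small smooth deformations the FFD
  stage estimates, and used only for display/fusion, never inside the
  objective.

## Known limitations

- No multi-resolution image pyramid: the capture range is set by centroid
  initialization, the coarse sample stride and the coarse-histogram pass.
  Initial misalignments far beyond ~10° / several voxels may not be
  captured.
- Finite-difference FFD gradients cost 2·(#control parameters) objective
  evaluations per iteration; large 3-D grids get expensive.
- Registration runs on voxel lattices; anisotropic spacing is carried as
  metadata but not resampled into physical space.
- The rigid capture pass is 2-D; 3-D coarse registration uses the full
  affine model directly.
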