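# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `atlasforge`. Everything quantitative stated here is computed
by the test suite or the acceptance script; nothing is quoted from external
data.

## Data model and conventions

Volumes are dense 3-D scalar grids with a 4×4 voxel-to-world affine; world
space is RAS+ in millimetres (x left→right, y posterior→anterior,
z inferior→superior) and the affine is the only source of geometry. Label
maps are non-negative integers with 0 reserved for background; masks are
binary. No operation resamples silently: inter-image operations require
geometry agreement and callers resample explicitly. Deformation fields store
world-mm displacement vectors on a stated reference grid and are serialized
as 4-D NIfTI with the vector dimension last. Intensities are computed in
float (32-bit storage, 64-bit arithmetic); labels stay integer end to end
and are only ever interpolated with nearest-neighbour.

## Synthetic cohort

The phantom is a nest of axis-aligned ellipsoids whose geometry is known in
closed form: a brain ellipsoid (half-axes ≈ 0.42/0.50/0.30 of the half
field of view along x/y/z, echoing adult head proportions with
width/length ≈ 0.84) containing a CSF-analog shell, a GM-analog cortical
band, a WM-analog core, a central ventricle-analog, and one
hippocampus-analog per hemisphere. Tissue means are T1-like (CSF 40, GM 90,
WM 140, arbitrary units); the hippocampus-analog is deliberately rendered
*bright* (185) — at desk-scale grids a GM-isointense structure carries no
registerable edge, and the structure exists to be found, not to be
photometrically realistic. A smooth multiplicative texture (default ±5%)
gives tissue interiors nonzero gradients.

Ageing is linear by construction: ventricle-analog volume grows 2% of its
age-18 volume per year, the cortical band thins 0.4%/year, and the
hippocampus-analog shrinks 0.4%/year. These rates are chosen so a desk-scale
cohort (default 48³ voxels at 1 mm) carries a clearly recoverable trend
while staying within plausible proportions; they define the study conditions
for every test.

Each simulated scanner applies a fixed monotone affine intensity map
(`ge` = 1.6·I + 30), so histogram matching can undo the scanner effect
exactly up to binning. Noise is additive Gaussian of known σ (default 3,
i.e. foreground SNR ≈ 30; Rician optional). Per subject, a random
12-parameter affine jitter (translations ±2 mm, rotations ±0.04 rad,
log-scales ±0.03, shears ±0.02) and a random smooth warp are applied to the
canonical age-specific anatomy and recorded as ground truth. The warp is
Gaussian-filtered white noise windowed around the brain and scaled so its
in-brain 99th-percentile magnitude equals the requested amplitude
(default 1.5 mm, smoothness 8 mm); window-and-scale is needed because
max-normalised fields concentrate their energy near grid corners and leave
the brain essentially unwarped. Fields are verified fold-free (positive
Jacobian determinant) at generation.

What the phantoms do **not** emulate: MR physics (no k-space, no bias
fields, no partial-volume mixtures beyond grid sampling), cortical folding,
and real inter-subject anatomical variability beyond the planted affine,
warp and age effects. Passing tests therefore demonstrate the *mechanics*
of the pipeline — recovery of known transforms, trends and noise levels —
not performance on real brains.

## Noise estimation and QC

Pseudo-residuals r = (6·I − Σ face neighbours)/√42 have Var r = σ² for
i.i.d. additive noise on a locally smooth image; σ̂ = 1.4826·MAD(r). The
whole-grid estimate is the QC statistic: the air background dominates the
field of view and carries the noise floor free of anatomy (recovery of
planted σ ∈ {4, 8, 12} within 10%, typically 2%). The in-mask variant
erodes the mask and drops voxels whose median-filtered gradient exceeds 5%
of the robust intensity range, because at desk scale most in-brain voxels
abut a tissue edge; it rests on only ~10² flat voxels and is accordingly
noisier (±25% at 48³). QC accepts a subject iff σ̂ ≤ threshold; SNR
(foreground mean / σ̂) is reported for information. The threshold is a
config value with no privileged default beyond the CLI's examples.

## Histogram standardization

Full-CDF quantile mapping over foreground voxels (mask if given, else Otsu)
onto a reference histogram (default 1024 bins). The fitted monotone map is
applied to all voxels, background included, clamped at the fitted range.
Idempotent within one bin width; undoes any monotone scanner transform up
to binning (KS < 0.02 in the tests). Landmark-based (piecewise-linear)
matching was not implemented: the full quantile map is the simplest scheme
meeting the contract. Bias fields are out of scope — correct upstream.

## Registration

**Affine.** 12 parameters (3 translations mm, 3 rotations rad, 3
log-scales, 3 shears), composed T·R·S·H about the fixed mask's centroid
with R = Rz·Ry·Rx; the zero vector is exactly the identity. Optimization is
gradient-free (Powell) over a 3-level pyramid (decimation 4/2/1, capped so
grids keep ≥ 12 voxels per axis), with a dense deterministic translation
search (one coarse voxel steps, ±4) at the coarsest level, then staged
releases: translations → rigid at the coarse level, 9 parameters at the
middle, all 12 at full resolution. The objective is normalized correlation
over mask voxels only (sampled directly, which is what makes the optimizer
affordable); the moving image is blurred to match each pyramid level. A
final masked correlation < 0.1 raises a convergence error with diagnostics
rather than silently returning the identity. Planted translations are
recovered to ~0.01 voxel and isotropic scale to ~0.1%.

**Diffeomorphic.** A greedy scheme: per iteration, the analytic gradient of
windowed cross-correlation (window radius 2) is computed inside the mask,
smoothed with the Gaussian regularizer (σ = 3 voxels), scaled to a maximum
step (0.25 voxel), composed with the current field
(φ ← φ ∘ (id + δ)), and the total field is lightly smoothed (σ = 0.5
voxels). Three levels with at most 50/50/10 iterations; per level the
best-metric field is kept, which makes the final metric non-decreasing. A
proposed step that would drive the Jacobian determinant below 0.05 is
halved (up to 8 times) before the level stops early. The regularizer σ is
interpreted in voxels and applied to the *update* field: applying it to the
total field instead shrinks the accumulated deformation every iteration and
planted 3-mm warps then cannot be recovered to better than ~1.5 voxels mean
endpoint error, whereas the update-field convention recovers them to
0.3–0.7 voxels. The scheme is one-directional (not inverse-consistent);
symmetric formulations are out of scope.

**Field algebra.** Composition resamples-then-adds in world mm; inversion
is fixed-point iteration with a 0.1-voxel residual contract; the Jacobian
uses central differences. Displacement fields extrapolate with
nearest-border values so inversion stays contractive near the grid edge.

## Groupwise template construction

Weights: Gaussian kernel w_i ∝ exp(−(a_i−t)²/2h²), normalized, default
bandwidth h = 5 years (half the default 5-year grid spacing times two; any
h preserves the closer-contributes-more property). Weights are computed
with a max-exponent shift, so a sparsely covered target age still
normalizes; an error is raised only when even the closest subject's kernel
value underflows.

Algorithm per target age: the initial reference is the weighted voxelwise
average (no subject is elected); each outer iteration affine- then
diffeo-registers every subject to the current reference, warps subject,
mask (and labels) through the composed transform, and re-averages. Two
corrections are applied, both on by default:

* **Drift (unbias) correction** — the weighted mean of the inverse affines
  and the inverse of the weighted mean deformation are composed into every
  subject's transform, so the mean transform stays near identity. Without
  the affine part the template's brain volume drifted by ~9% on phantom
  cohorts; with it, template volume matches the generating anatomy to
  <1%.
* **Reference sharpening** — the registration target is an unsharp-masked
  average (2·avg − Gauss(avg, 1 voxel)). Registering to the plain average
  lets small structures converge to a partial-volumed fixed point (the
  ventricle-analog stabilized ~17% too small); sharpening the target
  removes most of that bias. The *returned* template intensity is always
  the plain weighted average.

Stopping: mean absolute intensity change < 0.1% of the range, or
max_outer_iterations (default 5; the test suite and acceptance runs use 2
with reduced diffeo schedules — problem sizes chosen as the package's
desk-scale defaults). Subjects whose registration fails are dropped with a
logged warning and weights renormalized. The age series is one template per
grid age (default 20…75 step 5 → 12 templates); the population template
fuses the series with the same algorithm under uniform weights and no
target age.

Tissue probability maps: per warped subject, a 3-component Gaussian mixture
(tied covariance, quantile-initialized means, variance floor scaled to the
intensity span) is fit inside the template mask; components are ordered by
mean (CSF < GM < WM analog) and posteriors averaged with the kernel
weights. Tied covariance is load-bearing: with free covariances EM can
place one broad component over two intensity modes and break the
order-by-mean contract. A degenerate fit falls back to quantile thresholds
with a warning. Template labels, when the cohort carries them, are the
weighted majority vote of subject labels warped through their final
transforms — the synthetic stand-in for expert labels drawn on the
template. The template mask is the ≥ 0.5 weighted majority of warped
subject masks.

## Validation procedures

**Dice.** 2|A∩B|/(|A|+|B|) per label; both-empty is defined as 1 with a
warning. **Atlas-based segmentation** registers atlas→subject
(affine + diffeo, the configuration above) and propagates labels with
nearest-neighbour. **Morphometry**: AC–PC is the Euclidean distance between
the two landmarks; length/width/height are inclusive world-axis extents of
the mask (voxel-centre span plus one voxel footprint — a radius-50 mm
sphere sampled on an even grid measures exactly 100 mm); the protocol is a
package choice since extents can also be defined slice-wise.
**Deformation burden** affine-registers each subject to a candidate
template, re-measures morphometry on the warped mask and mapped landmarks,
and reports paired two-sided t statistics per measure without
multiple-testing correction. Extents are voxel-quantized, so sub-voxel
shape changes are invisible at desk scale.

On the default synthetic conditions the age-matched template segments the
hippocampus-analog of held-out aged subjects at mean Dice ≈ 0.78 vs ≈ 0.65
for an age-mismatched template (paired over 10 subjects, identical
registration settings), and a deliberately oversized template lengthens
every registered subject — the package's directional analogs of validating
a population- and age-specific atlas. These are directions, not calibrated
effect sizes: absolute Dice values on real brains depend on anatomy and
resolution the phantoms do not model.

## Numerical and degenerate-input choices

* Constant-zero volumes are legal for noise estimation (σ̂ = 0); constant
  foreground is an error for histogram matching (quantiles undefined).
* Empty masks are rejected at construction; masks smaller than 27 voxels
  are rejected for noise estimation.
* Field inversion failing its 0.1-voxel residual raises an error carrying
  the residual.
* A cohort of one builds a template with a warning; an empty cohort is an
  error. All-zero kernel weights advise a larger bandwidth.
* Determinism: phantom generation, registration and template construction
  are deterministic given seeds and configs (fixed initialisation, fixed
  pyramid, seeded mixture fits); permuting cohort order changes templates
  only at float-summation level.

## Known limitations

* The in-mask noise estimator needs ≳ 100 flat interior voxels; below that
  it falls back to the eroded mask and inherits edge bias.
* The greedy diffeomorphic scheme is uni-directional and first-order; very
  large or sharp deformations (amplitude approaching the regularizer
  scale) stop early on the Jacobian guard instead of converging.
* Template sharpness is limited by residual cross-subject misalignment;
  hard-threshold volumes of structures a few voxels across are biased low
  on templates even with reference sharpening (the tests use blur-invariant
  linear partial-volume masses where that matters).
* Histogram matching assumes a monotone scanner effect; spatially varying
  (bias-field) effects must be corrected upstream.
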