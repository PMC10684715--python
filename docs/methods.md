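# Methods

## Problem

A gradient-echo MR scanner measures a complex signal per voxel; the phase
that downstream applications need (field mapping, susceptibility-weighted
imaging, quantitative susceptibility mapping) is only observed as its
principal value in `(-pi, pi]`.  Recovering the smooth true phase means
assigning every voxel an integer number of 2*pi turns, under the sole
assumption that the true phase varies smoothly in space.  The hard cases
are exactly the clinically interesting ones: low SNR, rapid phase
variation, and open-ended wrap lines that defeat path-following
unwrappers.

## Algorithm

`polyunwrap` implements a 3D split-merge unwrapper built from four stages.

**1. Region partitioning** (`polyunwrap.partition`).  The principal
interval is divided into six equal subintervals; each subinterval's voxel
mask is decomposed into 26-connected components.  Because one component
spans less than a sixth of a turn in raw phase, it cannot contain a wrap —
*unless* two areas a full turn apart are falsely joined by a strand of
noisy voxels.  Such connectors are excised before components are
re-identified: a voxel is removed when (i) it lies on the region edge
(a 6-neighbor is outside the region) and (ii) along at least two of the
three coordinate axes its first, second and third neighbors on one side
are all outside the region.  Criterion (ii) deliberately requires a *run*
of three outside voxels: an isolated speckle hole (ubiquitous under
noise) does not condemn its neighborhood, whereas a thin bridge — whose
cross-section is small in two of three axes — is excised along its whole
length.  The disjunctive variant ("some neighbor within distance three is
outside") is available as `exclusion_criterion="any"`, but under moderate
complex noise it removes the majority of the ROI and can leave no block
at all.  Re-identified components with at least `size_threshold` voxels
(default 100) become **blocks**; smaller components become **second
residual voxels**; the excised connectors are the **first residual
voxels**.  The three categories tile the ROI exactly.

**2. Local polynomial model** (`polyunwrap.polyfit`).  The true phase in
a neighborhood is modeled as a tensor-product polynomial with per-axis
orders `(L, M, N)` (default `(2, 2, 2)`, 27 coefficients), fitted by
least squares to already-unwrapped voxels.  Coordinates are normalized
(centroid subtracted, each axis scaled by its half-extent) before
monomials are formed — raw voxel indices raised to sixth-order cross
terms would be numerically hopeless.  Rank-deficient systems (coplanar
interface patches are common) get the minimum-norm solution with singular
values below 1e-10 of the largest truncated.  A voxel's integer offset is
`k = round((prediction - wrapped) / 2*pi)` — exact whenever the
prediction errs by less than pi.  Sparse fits fall back to lower orders:
below one point per coefficient the orders drop to `(1, 1, 1)`, below 8
points to the constant model.  (A stricter two-points-per-coefficient
rule was tried and rejected: near a smooth phase extremum it starves the
fit of its curvature terms exactly where extrapolation needs them, and a
trilinear model then under-predicts the peak by more than pi, seeding a
cascade of wrong offsets.)

**3. Block merging** (`polyunwrap.engine`).  The largest block seeds the
unwrapped state with offset 0 (its raw phase is wrap-free; the overall
result is in any case defined only up to one global turn).  Remaining
blocks merge nearest-first by Euclidean distance between closest voxels.
For each growing block, the `fitting_count` (default 100) done voxels
nearest the block and the 100 block voxels nearest the done set form the
interface.  The block's single integer offset is chosen by a *joint* fit:
for each candidate `k` (searched around a nearest-neighbor anchor), one
polynomial is fitted to the done-side unwrapped values together with the
block-side values shifted by `2*pi*k`, and the `k` with the smallest
residual RMS wins.  The correct offset places both patches on one smooth
surface; a wrong one introduces a step no smooth polynomial can absorb —
provided the gap is small.  Two safeguards follow from that proviso:
candidates within 5% of the best RMS defer to the anchor (a flexible
polynomial absorbs much of a step across a wide gap, and a degenerate
two-plane interface absorbs any step exactly), and blocks farther than
`merge_max_distance` (default 3 voxels) from the done set are not merged
rigidly at all but demoted to voxel-by-voxel growing, where every step
has dense local context.  A one-sided fit with a modal per-voxel vote is
retained as `block_offset_method="vote"`; it is cheaper but was found to
mis-merge blocks whose interface support is a thin curved shell, because
the polynomial is unconstrained along the shell normal.

**4. Residual growing** (`polyunwrap.engine` / `polyunwrap._growing`).
Residual voxels are unwrapped one at a time by quality-guided region
growing — second residuals first, then first residuals, then combined
mop-up passes until nothing is reachable (one class can wall in the
other; a connected ROI always finishes).  The quality map is the RMS of
principal phase differences to in-mask 26-neighbors (a phase-derivative
magnitude; lower = more reliable).  Candidates adjacent to the done set
are processed from a stable priority queue; each is fitted against the
done voxels in its centered `window`³ region (default 11) and committed
via the rounded offset, then enqueues its residual neighbors.

The growing kernel is numba-compiled (the same source runs un-jitted,
~1000x slower, which small-fixture tests exploit) and contains the
mechanisms that keep per-voxel rounding stable in heavy noise:

* *capped fits* — at most `window_cap` (default 100) nearest done voxels
  enter the routine fit; the full 11³ window would cost ~13x more;
* *adaptive model order* — constant, trilinear and full-order fits are
  compared by an AIC-style score `n*log(rss/n) + 2*terms`; where
  curvature dominates noise the full model wins, where the window is
  noise-dominated the low-variance constant/linear model wins.  A fixed
  quadratic has prediction errors of 2-3 rad at the edge of the done
  cloud in noise-dominated windows, which randomizes the rounded offset;
* *outlier trimming* — fitting points whose residual exceeds pi are
  dropped once and the model refitted: a previously mis-unwrapped voxel
  sits a whole turn off the local surface and would otherwise poison
  every window it appears in;
* *extrapolation guard* — a prediction farther than 2*pi from the nearest
  done voxel's value (at most one diagonal step away) is rejected and the
  order reduced; this stops the rare runaway solves outright;
* *boundary refinement* — when the offset fraction falls within
  `refine_band` (default 0.2) of the rounding boundary, the prediction is
  recomputed from *every* done voxel in the window.  The
  misclassification floor in heavy noise is the product of the density of
  noise-induced phase changes near ±pi and the prediction error, so
  shrinking the variance exactly at the boundary is what controls it;
* *banded fronts* — the queue key is `(distance-band, quality, insertion
  order)` with bands of `front_band` (default 4) voxels around the done
  set.  Fronts from all anchors then advance concentrically and meet
  early; without this, a mis-branched patch born at a thin front can
  capture large territory before colliding with a correct front (observed
  at the lowest SNR on full-size volumes).

Everything is deterministic: there is no randomness anywhere in the
pipeline, ties break on block id or voxel index, and the growing order is
recorded and reproducible bit for bit.

## Synthetic data (`polyunwrap.simulate`)

Two phantoms with known ground truth emulate the standard benchmark
conditions:

* **Gaussian bump**: true phase `peak * exp(-r²/(2*sd²))` (default peak
  20 rad, SD 20 voxels, 100³ grid, centered); complex signal
  `magnitude * exp(i*phase)` plus complex Gaussian noise (independent
  real/imaginary channels, each of SD `noise_sd`, default 20).  Sweeping
  the magnitude 10 … 100 yields SNR 0.5 … 5.  The defaults give a maximal
  gradient of 0.61 rad/voxel and about three wraps center-to-edge.
* **Variable-gradient phantom** (101x101x51): `height * [(sin(x)/pi) *
  (1.50 - z) + (sin(y)/pi) * (0.49 + z)]` with `z` normalized to [0, 1],
  height 5, magnitude 50, noise SD 10 (SNR 5).  The x/y coordinates are
  the voxel indices times `xy_scale`.  The default scale 0.25 gives a
  sinusoid period of ~25 voxels — several wrap lines per axis whose
  spacing changes with slice, and a maximal gradient (~0.6 rad/voxel)
  matching the bump phantom.  Taking the indices directly as radians
  (`xy_scale=1`) makes adjacent voxels differ by up to 2.4 rad; no
  polynomial fitted over an 11-voxel window can track a sinusoid with a
  6.3-voxel period, and measured MCR is ~50% for this implementation —
  we therefore treat that convention as outside the operating envelope
  of any windowed local model and keep it available only as a parameter.

The scoring reference is the *noise-corrected* phase: truth plus the
principal-value phase change the noise induced.  It is congruent to the
noisy wrapped phase modulo 2*pi (so a perfect unwrapper scores exactly
zero) and within pi of the truth.

What the generators do **not** emulate: coil sensitivities, Rician bias
fields, anatomy-shaped ROIs, open-end cutlines from air/tissue
interfaces, or multi-echo structure.  Passing these benchmarks therefore
demonstrates correctness of the unwrapping logic under controlled noise
and gradient conditions, not clinical robustness.

## Evaluation (`polyunwrap.evaluate`)

MCR = percentage of ROI voxels whose unwrapped phase differs from the
reference by more than pi/10 rad, after removing the modal global 2*pi
offset (any unwrapper's output carries that gauge freedom; without the
alignment a perfect result could score 100%).  Voxels the engine could
not reach count as wrong.  Because reference and wrapped input are
congruent mod 2*pi, a voxel is in fact wrong exactly when its integer
offset differs from the reference's — the pi/10 threshold is nominal.

The experiment harness repeats: per repetition, experiment 1 generates
one volume at each of the ten SNR levels and pools the MCRs; experiment 2
generates one variable-gradient volume.  Mean and SD are taken across
repetitions; per-SNR means are also reported, since a single pooled
number hides the strong SNR dependence (see below).

## Problem sizes and the misclassification floor

The default test and acceptance runs use three repetitions and a
proportional miniature of the SNR sweep (56³ in `scripts/acceptance.py`,
48³ in the test suite; bump SD and peak scaled by the same factor as the
grid so the per-voxel gradient structure is identical) and the full-size
variable-gradient phantom.  Per-SNR behavior at these sizes: MCR is 0.000%
at SNR ≥ 3, below 0.02% at SNR 2, ~0.25% at SNR 1 and ~1.3-1.7% at
SNR 0.5.

The low-SNR values are close to an information-theoretic floor rather
than an implementation artifact.  A voxel is scored wrong iff its integer
offset differs from the reference's; when the noise-induced principal
change δ lies near ±pi, an arbitrarily small prediction error flips the
rounding.  The flip rate is ≈ p(|δ|≈pi) x E|prediction error|, and *any*
estimator confined to an 11³ window has prediction error bounded below by
the noise level over ~1300 voxels.  Measured concretely: an oracle
smoother (uniform 11³ mean of the reference itself) still misclassifies
0.76% of voxels at SNR 0.5.  A pooled mean over SNR 0.5 … 5 therefore
cannot be driven to the 0.01% level under this scoring; sub-0.05% pooled
values are achievable only if the lowest SNR levels are excluded.  The
per-SNR table in every report makes both readings available.

## Numerical choices and degenerate inputs

* Principal interval `(-pi, pi]`; `-pi` folds to `+pi`; `unwrapped =
  wrapped + 2*pi*k`.
* Subinterval bins are half-open `(a, b]`, so boundary values belong to
  exactly one bin.
* Component labeling, EDT and hole filling use scipy.ndimage; 26-, 18-
  and 6-connectivity structuring elements are supported (26 default).
* The jitted kernel solves ridge-stabilized normal equations
  (`ridge = 1e-9 * n` on normalized coordinates); the library-level
  fit is SVD-based minimum-norm.  On well-conditioned systems they agree
  to ~1e-6; pathological kernel solves are caught by the extrapolation
  guard.
* Ties everywhere are deterministic: seed block by (count, smallest id),
  merge order by (distance, larger block, smaller id), fitting-voxel
  selection by (distance, voxel index), queue by (band, quality,
  insertion order).
* Empty ROI, no-block partitions, unreachable residual islands and
  non-finite inputs raise or are reported explicitly; nothing is
  silently imputed.

## Known limitations

* Voxels are treated as isotropic; anisotropic spacing is ignored in all
  distances (consistent with the algorithm's formulation, but a
  high-anisotropy acquisition would change what "nearest" means).
* Per-voxel phase gradients approaching the subinterval width
  (~1.05 rad/voxel along an axis, less diagonally) can let a connected
  component skip across a bin and reintroduce hidden wraps; gradients
  above ~2 rad/voxel defeat the windowed polynomial model entirely.
* At SNR ≤ 1 on large volumes, mis-branched growth fronts are contained
  (banded fronts, trimming) but not eliminated; isolated boundary-band
  flips remain at the ~1% level at SNR 0.5 (see the floor analysis
  above).
* The magnitude-threshold mask generator is a convenience surrogate
  (Otsu + largest component + slice-wise hole filling); externally
  produced masks are first-class inputs and always win.
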