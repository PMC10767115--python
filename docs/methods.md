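# Methods

## Displacement-field model

All transforms are dense 2D displacement fields on the pixel grid,
`F(r) = r + u(r)`, stored as `(rows, cols, 2)` float32 arrays in
(row, column) order with the origin at the top-left. Fields *pull*: the
output pixel at `r` samples the input at `r + u(r)` with bilinear
interpolation. A sample point falling outside the grid evaluates to exactly
0 — the value reserved for non-tissue — with no partial blending at the
boundary (the scipy `map_coordinates` convention; the autograd warp and the
finetuner's fused gradient use the same rule so all code paths agree).

Composition follows the same sampling rule:
`(A ∘ B)(r) = r + b(r) + a(r + b(r))`. Analysis code that composes fields
carrying a large accumulated drift (pair-preservation checks, recovery
metrics) may instead request edge-clamped extension (`extend="clamp"`),
because the zero-extension rule would otherwise manufacture spurious
deviations in a boundary band as wide as the drift.

**Inversion** solves the fixed point `V(r) = −U(r + V(r))` by iteration,
starting at `V = −U`, sampling `U` with edge clamping (the natural extension
of a field defined on the full grid; constant fields then invert exactly
everywhere). Convergence is the max-norm fixed-point residual, default
tolerance 1e-2 px, 200 iterations. The iteration is pointwise, so fields
that are non-invertible only inside masked defect bands (a fold is a genuine
many-to-one map) still invert correctly outside them; analysis callers pass
`check=False` and mask those bands instead of failing globally.

**Variable-σ blurring** for stitch decay is either a direct convolution with
a sampled Gaussian (truncated at radius `ceil(3σ)`, minimum radius 1,
renormalized — so constant fields are exact fixed points under replicate
boundary handling), or an approximation that trilinearly interpolates a MIP
hierarchy of the field: levels are built by an iterative 2×2 box filter, the
fractional level is `log2(max(σ, 1))`, and the two bracketing levels are
upsampled to the base grid and mixed linearly. On fields whose correlation
length is large compared to σ — the regime stitch fields live in, since they
vary at block scale — the approximation stays within ~15% relative L2 of the
direct blur for σ ∈ [1, 32]; for fields with structure at the scale of σ it
degrades, which is why the desk-scale default is the direct path and the MIP
path is reserved for large-scale use.

## Losses

The similarity term is the masked mean of the pixel-wise squared error
between the warped source and the target, averaged over the intersection of
their nonzero (tissue) sets; multi-channel encodings sum the error over
channels before masking. The elastic regularizer treats the field as a
spring mesh with forward neighbors (0,1), (1,0), (1,1): per-vertex energy
`Ω(p) = Σ_h (‖F(p) − F(p+h)‖ − ‖h‖)²`, averaged over tissue vertices of the
warped source. Rigid translations cost exactly zero. The defect mask is
dilated by 1 px before excluding vertices so that the spring *edges*
straddling a crack or fold are also free — the mask marks vertices but the
energies live on edges.

Stage-1 training loss: masked image MSE after warping plus `γ·L_er`.
Stage-2 adds the encoding-based terms: post-alignment encoding MSE, and the
best-sample pre-alignment similarity `−L_pre` computed over the
lowest-post-error chunks (32-px chunks, bottom 50th percentile, ties broken
in raster order), weighted by `α = 0.7`. The pre-alignment error uses the
*unwarped* source encoding even though chunk selection used the warped one,
matching the loss definition as stated. `γ` defaults to 15 and is
configurable per pyramid level in the 5–25 range (coarser levels higher).

## Pair aligners

**Masked-NCC block matching.** Source patches are correlated against larger
target patches on a Cartesian node grid, with the Pearson correlation
computed only over jointly nonzero pixels at every candidate offset. Nodes
with under 50% valid pixels in either patch, or a peak below `min_corr`
(default 0.2), are dropped and refilled from the nearest surviving node;
a 3-point parabolic fit per axis refines the peak to subpixel. Desk-scale
defaults are 32-px sources against 48-px targets on a 16-px grid; the
production-scale preset (256/358/96) is available as
`BlockmatchParams.coarse_em_preset()`.

**Encoder/Aligner nets.** A small residual conv encoder (1 → 8 → 8 → C
channels, 3×3 kernels, leaky-ReLU, 1×1 skip) and a four-layer conv aligner
over the concatenated encodings whose final layer is zero-initialized, so an
untrained aligner predicts the zero residual field. The encoder output is
bounded by tanh: with an unbounded encoder, stage-2 training can inflate the
encoding scale without limit to grow the (negative) pre-alignment term.
Both nets run on a minimal numpy reverse-mode autograd
(`emalign.autograd`) whose warp, convolution, and elastic-energy gradients
are finite-difference- and cross-checked in the test suite. Training is
two-stage (image-based then encoding-based), per-pair Adam (lr 2e-3), fully
deterministic given the seed; the production-scale schedule is 100 + 500
epochs and the desk-scale tests use 20 + 40.

**Online field finetuner.** Gradient descent on the masked encoding MSE plus
`γ·L_er`, starting from the incoming field. The gradient of the bilinear
warp with respect to the field is exact (piecewise-linear derivative of the
interpolant), fused with the elastic gradient in float32 for speed and
verified against the autograd reference. The optimizer is Adam on the field
itself — the per-pixel step normalization makes the step size (default
0.1) directly meaningful in pixels — with the best-loss iterate kept, so the
result never scores worse than the input. The stopping tolerance is 1e-6
relative loss change per iteration: per-iteration improvements are far
smaller than the distance to the optimum in this landscape, and looser
tolerances stall visibly short of convergence.

**Coarse-to-fine driver.** A zero field at the coarsest level is refined per
level: upsample ×2, pre-warp the source, run the level aligner, compose the
residual, finetune. Block matching runs at *every* level by default, not
just the coarsest: a patch correlator averages the deformation inside its
patch, so a single coarse match leaves a residual proportional to the
deformation amplitude times the patch-to-wavelength ratio; re-matching the
pre-warped source at each finer level (narrow ±4 px search on a sparser
grid) shrinks that residual geometrically until it sits inside the
finetuner's capture range, which is set by the texture feature size. The
default finetune schedule spends the full iteration budget (120) at the
coarsest level, two thirds at intermediate levels, and a quarter at the
finest; the elastic weight follows the coarser-is-stiffer rule
γ(level) = min(γ_max, 5·(level+1)).

## Vector voting

All candidate fields vote per pixel: subsets of size `m = ⌊n/2 + 1⌋` are
scored by the mean pairwise Euclidean displacement distance, softmin weights
(`T = 5.7` px by default, `n = 3`) are split evenly across subset members,
and the output is the resulting convex combination of the input
displacements. Optionally the fields entering the distance computation are
pre-smoothed (`presmooth_sigma`, default 0 — the vote itself always uses the
raw fields). Blank or missing targets are excluded before voting and n drops
to the number of valid candidates.

## Block alignment, stitching, decay

Blocks (default size 25, overlap 3, matching the production run; the
desk-scale tests use 10/3 on 30-section stacks) are aligned sequentially
from a starter section fixed to the identity. Up to n−1 sections *preceding*
the starter are bootstrapped into its frame by walking backwards one section
at a time, each hop aligned against the previous hop's render — single-hop
alignments are measurably more accurate than spanning k sections directly,
and the bootstrap quality propagates into every subsequent vote. Each later
section is aligned to its n nearest valid aligned predecessors (lookback
extends past blank sections), the candidates voted. A blank source section
inherits its predecessor's field.

The stitch between consecutive blocks aligns each overlap section rendered
in the later block's frame onto the same section rendered in the earlier
block's frame, and votes the results. For globalization each section's block
field is composed with all preceding stitch fields, each decayed by
`σ(n) = c·n` blur and `β(n) = max(1 − n/d, 0)` amplitude (defaults c = 0.2
px/section, d = 200 sections; d = 100 in the desk-scale runs). Stitches
beyond distance d contribute identity and are skipped. Overlap duplicates
resolve in favor of the **later** block: its leading sections sit next to
its own starter and carry the least accumulated sequential error, whereas
the earlier block's trailing copies are the farthest from theirs (measured
at ~0.9 px vs ~0.25 px pair deviation at block boundaries on the synthetic
stack); the earlier block's copies serve only to compute the stitch.

The decay construction preserves neighbor-pair alignment up to the
difference of consecutive decayed blur kernels. `kernel_difference_curve`
quantifies this: the L1 difference between the normalized discrete Gaussians
`G_{σ(n)}` and `G_{σ(n−1)}` as a function of n — with σ growing 0.02
px/section it is ~0 at n = 1, peaks near 5% around n ≈ 22–24, and declines
thereafter. The residual β-slope term contributes `‖u‖/d` per interface per
pair, which is why large decay distances and small stitch fields matter.

## Chunked execution and scheduling

`chunked_apply` tiles an image with overlap margins and reassembles by
cropping or linear feathering; for operators whose support radius fits the
margin the tiled result matches the untiled one to interpolation accuracy.
`run_jobs` executes generator-style jobs that yield tasks and barriers; task
batches between barriers run in any order on a thread pool, and because
tasks are pure and blocks independent, parallel results are bit-identical to
serial. The manifest records batches, timings, and the full configuration.

## CPC evaluation

Neighboring aligned sections are divided into non-overlapping chunks
(default 64 px, anchored at the origin; partial edge chunks excluded) and
Pearson r is computed over jointly nonzero pixels. Chunks containing any
defect-mask pixel, with under half their pixels valid, or with zero variance
are invalid. Summaries pool valid chunks into a percentile curve and the
fraction below a threshold (default 0.25); `sample_low_cpc` draws a seeded
uniform sample of qualifying chunk locations (default 300) for manual
review.

## Synthetic stacks

Section z observes `warp(base_texture, W_z)` with `W_z = drift_z + D_z`: a
constant per-section stage drift that accumulates linearly (default 2
px/section) plus an *independent* band-limited smooth distortion per section
(default max 8 px, correlation length 64 px, generated by periodic Gaussian
filtering of white noise so the stated band limit is exact). Acquisition
distortion thus does not random-walk across the stack — only drift
accumulates — keeping every per-section field invertible. The ground-truth
pair field is `R_z = invert(W_z) ∘ W_{z−1}`, and the generator self-check
verifies `warp(obs_z, R_z)` matches `obs_{z−1}` to < 0.05 RMS on unmasked
tissue.

Defects are discontinuous displacements across a random line: cracks
separate the two sides by the defect width (default 12 px, one fold every 5
sections by default), folds overlap them; displacement decays within a
16-px apron. The detection mask covers exactly the lost/occluded band (what
a detector would mark, and what the pipeline zeroes); a wider evaluation
band covering all non-negligible defect displacement is stored separately
and excluded from ground-truth comparisons, because the ground-truth pair
fields deliberately exclude the (non-invertible) defect transforms.
Artifacts — high-contrast stripes (on 20% of sections by default), additive
grid patterns, dark dust blobs, brightness gradients — are applied after
warping and are uncorrelated across sections, which is precisely the
property the stage-2 encoding loss exploits. One section (z = 15 by default)
is blanked entirely.

What the generator does *not* emulate: real EM texture statistics, section
thickness variation, montaging seams, charge artifacts, or correlated
multi-section damage. Passing the recovery tests therefore demonstrates the
pipeline's geometric machinery — candidate alignment, voting, stitching,
decay — not robustness to every failure mode of real acquisitions.

## Measurement conventions and problem sizes

Recovery is measured on *pair* transforms —
`RMS over tissue of ‖(F_z ∘ invert(F_{z−1})).u − R_z.u‖` per section, with
defect evaluation bands and an 8-px image margin excluded, summarized as the
mean and max over sections — because a global alignment is only defined up
to a slowly varying stack-wide drift. The headline recovery run uses the
default 30-section 512² recipe with block size 10, overlap 3, decay distance
100, net-free aligners (block matching at every level plus finetuning). The
pair-preservation suite isolates the decay property on an analytic
consistent-block fixture (24 sections at 128², three blocks, decay distance
200, with d = 1 as the negative control): block fields, stitches and pair
fields all derive from one smooth invertible per-section transform family,
so the measured deviation is attributable to the decayed composition alone
rather than to aligner error. Training smoke runs at 64² with four pairs,
20 + 40 epochs.

Striped sections are the accuracy bottleneck for the net-free aligner.
Periodic knife-chatter stripes replace tissue with content that is
uncorrelated across sections; when *both* sections of a pair are striped,
correlation and gradient descent can phase-lock onto the stripe period
(candidate errors of tens of pixels). Vector voting suppresses such a
candidate to a few percent weight, which still leaves a fraction-of-a-pixel
bias, and stripe-adjacent pairs end up around 1 px pair RMS versus
0.2–0.6 px on clean pairs — the exact failure mode the trainable encodings
exist to remove.

## Known limitations

- The fixed-point inversion requires displacement gradients below 1 in
  magnitude away from masked regions; pathological fields raise (or, in
  analysis mode, leave locally wrong values that masking must exclude).
- The MIP-trilinear blur is a coarse approximation for σ comparable to the
  field's correlation length; use the direct path when in doubt.
- Net-free alignment degrades on artifact-bearing sections; the trainable
  encodings recover this but the desk-scale training runs are demonstrative,
  not production-quality.
- ABCD trades a small, quantifiable pair-alignment discrepancy
  (~`‖u_stitch‖/d` per interface) for never solving a global relaxation;
  with large inter-block drift and small d this is the dominant error term.
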