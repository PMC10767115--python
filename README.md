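# emalign

Elastic alignment of serial-section electron microscopy (ssEM) image stacks.

Reconstructing neural circuits from ssEM requires registering thousands of
consecutive ultrathin sections into a coherent 3D volume. Each section
arrives with its own low-frequency deformation, stage drift, acquisition
artifacts (knife chatter, dust, brightness gradients), and physical defects —
cracks and folds that demand *discontinuous* transforms and destroy a band of
image data. `emalign` implements a scalable pipeline for this problem built
on three ideas:

1. **Dense displacement-field pair alignment.** A transform is a per-pixel
   displacement field `F(r) = r + u(r)` applied by bilinear pull-sampling,
   `(M ∘ F)(r) = M(r + u(r))`. Pair aligners (a masked-NCC block matcher, an
   optional trainable Encoder/Aligner convolutional pair, and an online
   gradient-descent finetuner) minimize the masked similarity loss plus an
   elastic spring regularizer
   `Ω(p) = Σ_h (‖F(p) − F(p+h)‖ − ‖h‖)²`, zeroed at defect
   locations so cracks and folds remain free to be non-smooth.
2. **Vector voting.** Each section is aligned against its *n* nearest already
   aligned predecessors; the candidate fields are merged by a per-pixel
   smooth median: all minimum-simple-majority subsets (size ⌊n/2+1⌋) are
   scored by mean pairwise field distance `D_k`, softmin-weighted
   (`w_k = e^{−D_k/T} / Σ_j e^{−D_j/T}`), and averaged. Outlier fields get
   exponentially small weight, so single-section failures do not propagate.
3. **ABCD — Alignment of Blocks and Composition with Decay.** The series is
   split into overlapping blocks aligned independently; neighboring blocks
   are stitched by voting over their overlap sections, and each stitch field
   is *decayed* before composition: displacements are blurred with
   `σ(n) = c·n` and scaled by `β(n) = max(1 − n/d, 0)` at section distance n.
   No global relaxation is ever solved, yet neighbor-pair alignment is
   preserved to a small, quantifiable discrepancy.

Quality is scored with the Chunked Pearson Correlation (CPC): per 64-px chunk
Pearson r between neighboring aligned sections, excluding non-tissue and
defect chunks; the fraction of chunks with CPC < 0.25 summarizes alignment
quality, and low-CPC locations can be sampled reproducibly for review.

A fully synthetic stack generator (`emalign.synthstack`) produces stacks with
known ground-truth deformations, defects, artifacts, and missing sections, so
the entire pipeline is testable end to end without any external data.

## Worked example

```python
from emalign.pipeline import PipelineConfig, run_pipeline
from emalign.synthstack import StackRecipe, gen_stack, recovery_error

stack = gen_stack(StackRecipe(seed=0))           # 30 sections, 512x512 px
cfg = PipelineConfig(seed=0, block_size=10, block_overlap=3, decay_d=100)
alignment, cpc_after, manifest = run_pipeline(cfg, stack)

err = recovery_error(stack, dict(alignment.fields))
print(f"pair-relative recovery RMS: {err['mean_rms']:.3f} px")
print(f"low-CPC chunk fraction after alignment: {100*cpc_after.fraction_below:.2f}%")
```

prints (seed 0):

```
pair-relative recovery RMS: 0.857 px
low-CPC chunk fraction after alignment: 0.19%
```

meaning the recovered per-pair transforms agree with the generator's
ground-truth deformations to well under a pixel on tissue on average, and
after alignment almost no 64-px chunk correlates below 0.25 with its
neighbor (before alignment ~47% of chunks do). The residual sub-pixel error
concentrates on sections bearing periodic knife-chatter stripes — the
failure mode of net-free alignment that the trainable encodings exist to
remove — and on late-block sections, which carry the small inherent
composition-with-decay discrepancy.

A thin CLI wraps the same library calls:

```
emalign synth --seed 0 --out stack/          # generate a synthetic stack
emalign run stack/stack.tiff --out result/   # align + render + CPC report
emalign cpc result/rendered.tiff             # quality summary
```

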