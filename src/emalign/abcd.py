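"""Block alignment, stitching, and globalization by composition with decay.

The section series is partitioned into overlapping blocks. Each block is
aligned sequentially with vector voting: the block's starter section is
fixed to the identity, and every later section is aligned to up to n already
aligned preceding sections, the resulting candidate fields voted into a
consensus. Neighboring blocks are stitched by aligning their overlap
sections (each rendered in its own block's frame) and voting; the stitch
field is then *decayed* before composition — its displacements are blurred
with a Gaussian whose std grows linearly with section distance
(sigma(n) = c*n) and scaled by beta(n) = max(1 - n/d, 0) — so each stitch
influences only the next d sections and sheds high spatial frequencies with
depth. This avoids any global relaxation while provably (for slowly growing
sigma) preserving neighbor-pair alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import (
    DisplacementField,
    blur_field,
    compose,
    gaussian_kernel_1d,
    invert,
    warp,
)
from .preprocess import SectionImage
from .voting import VotingConfig, vote


@dataclass
class BlockSpec:
    """One block of contiguous sections, aligned independently.

    start is the starter section (fixed to identity); sections [start, stop]
    inclusive belong to the block; consecutive blocks share ``overlap``
    leading sections with the previous block's tail.
    """

    start: int
    stop: int
    overlap: int = 0
    index: int = 0

    @property
    def sections(self) -> range:
        return range(self.start, self.stop + 1)


@dataclass
class StitchField:
    """Field mapping block i's frame onto block i-1's, voted over the overlap."""

    field: DisplacementField
    interface: int  # starter index of the later block


@dataclass
class DecayConfig:
    """Composition-with-decay parameters.

    c is the blur growth rate in px/section (sigma(n) = c*n); d the decay
    distance in sections (beta(n) = max(1 - n/d, 0)). blur_method selects the
    direct Gaussian or the MIP-trilinear approximation.
    """

    c: float = 0.2
    d: int = 200
    blur_method: str = "direct"

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("blur growth rate c must be >= 0")
        if self.d < 1:
            raise ValueError("decay distance d must be >= 1")


@dataclass
class GlobalAlignment:
    """Final per-section fields plus provenance of how they were composed."""

    fields: dict[int, DisplacementField] = dc_field(default_factory=dict)
    provenance: dict[int, dict] = dc_field(default_factory=dict)

    def sections(self) -> list[int]:
        return sorted(self.fields)

# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def partition_blocks(
    num_sections: int,
    block_size: int = 25,
    overlap: int = 3,
    starters: list[int] | None = None,
) -> list[BlockSpec]:
    """Partition a series into overlapping blocks.

    Consecutive blocks share ``overlap`` sections: each block after the first
    starts ``overlap`` sections before the previous block's end. Explicit
    starter indices override the uniform partition.
    """
    if not 0 <= overlap < block_size:
        raise ValueError("need block_size > overlap >= 0")
    if num_sections < 1:
        raise ValueError("num_sections must be >= 1")
    if starters is not None:
        starters = sorted(starters)
        if starters[0] != 0:
            starters = [0] + [s for s in starters if s != 0]
        for s in starters:
            if not 0 <= s < num_sections:
                raise ValueError(f"starter {s} outside section range [0, {num_sections})")
        for a, b in zip(starters, starters[1:]):
            if b - a <= overlap:
                raise ValueError(f"starters {a}, {b} closer than overlap + 1")
        blocks = []
        for i, s in enumerate(starters):
            stop = (starters[i + 1] + overlap - 1) if i + 1 < len(starters) else num_sections - 1
            stop = min(stop, num_sections - 1)
            blocks.append(BlockSpec(s, stop, overlap if i > 0 else 0, i))
        return blocks
    blocks = []
    start = 0
    i = 0
    while True:
        stop = min(start + block_size - 1, num_sections - 1)
        nxt = stop - overlap + 1
        # a trailing block must contribute more than stitching overhead;
        # otherwise the current block absorbs the remainder
        if stop < num_sections - 1 and num_sections - nxt <= 2 * overlap:
            stop = num_sections - 1
        blocks.append(BlockSpec(start, stop, overlap if i > 0 else 0, i))
        if stop >= num_sections - 1:
            break
        start = stop - overlap + 1
        i += 1
    return blocks


def select_starters(defect_fraction_per_section: np.ndarray, stride: int) -> list[int]:
    """Pick, per stride window, the section with the least defect coverage.

    Deterministic: ties break toward the lower index (argmin order).
    """
    fracs = np.asarray(defect_fraction_per_section, dtype=np.float64)
    if fracs.size == 0:
        raise ValueError("select_starters: empty input")
    out = []
    for w0 in range(0, fracs.size, stride):
        window = fracs[w0 : w0 + stride]
        out.append(w0 + int(np.argmin(window)))
    return out

# ---------------------------------------------------------------------------
# Sequential block alignment
# ---------------------------------------------------------------------------

def _is_blank(section: SectionImage) -> bool:
    return not (section.pixels != 0).any()


def align_block(
    stack: list[SectionImage],
    block: BlockSpec,
    aligner,
    voting_cfg: VotingConfig | None = None,
) -> dict[int, DisplacementField]:
    """Sequentially align a block's sections into the starter's frame.

    ``aligner(src, tgt) -> DisplacementField`` is any pair aligner obeying
    the phi contract. The starter gets the identity field. Up to
    ``voting_cfg.n - 1`` sections *preceding* the starter (when the stack has
    them) are aligned directly to the starter to bootstrap multiple voting
    targets. Every later section i is aligned against the nearest n valid
    (non-blank) already aligned sections, each target rendered by its own
    field, and the candidate fields are voted. Blank sections are skipped as
    targets; a blank source inherits the previous section's field.
    """
    voting_cfg = voting_cfg or VotingConfig()
    n = voting_cfg.n
    b0 = block.start
    if _is_blank(stack[b0]):
        raise ValueError(f"align_block: starter section {b0} has no tissue")
    shape = stack[b0].shape
    res = stack[b0].resolution
    fields: dict[int, DisplacementField] = {b0: DisplacementField.zeros(shape, res)}
    # bootstrap: align up to n-1 preceding sections into the starter frame,
    # walking backwards one section at a time (each hop is a single-section
    # alignment against the previous hop's render, which is far more
    # accurate than spanning k sections directly)
    prev = b0
    for k in range(1, n):
        z = b0 - k
        if z < 0:
            break
        if _is_blank(stack[z]):
            continue
        try:
            rendered = SectionImage(warp(stack[prev].pixels, fields[prev]), res, prev)
            fields[z] = aligner(stack[z], rendered)
            prev = z
        except Exception:
            continue
    for z in range(b0 + 1, block.stop + 1):
        if _is_blank(stack[z]):
            if z - 1 in fields:
                fields[z] = fields[z - 1].copy()
            else:
                fields[z] = DisplacementField.zeros(shape, res)
            continue
        # nearest n valid aligned targets, extending lookback past blanks
        targets = [t for t in range(z - 1, b0 - n, -1) if t in fields and not _is_blank(stack[t])]
        targets = targets[:n]
        if not targets:
            raise RuntimeError(
                f"align_block: no valid alignment targets for section {z} "
                f"(gap back to {b0 - n + 1})"
            )
        candidates = []
        for t in targets:
            rendered = SectionImage(warp(stack[t].pixels, fields[t]), res, t)
            if _is_blank(rendered):
                continue
            try:
                candidates.append(aligner(stack[z], rendered))
            except Exception:
                continue
        if not candidates:
            raise RuntimeError(f"align_block: all candidate alignments failed for section {z}")
        fields[z] = vote(candidates, voting_cfg)
    return {z: f for z, f in fields.items() if z >= b0}

# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def stitch_field(
    stack: list[SectionImage],
    block_prev_fields: dict[int, DisplacementField],
    block_next_fields: dict[int, DisplacementField],
    overlap_sections: list[int],
    aligner,
    voting_cfg: VotingConfig | None = None,
) -> StitchField:
    """Field registering the later block's frame onto the earlier block's.

    Each overlap section is rendered twice — once with its field in the later
    block's frame and once with its field in the earlier block's frame — the
    former is aligned to the latter, and the per-section fields are voted.
    """
    if not overlap_sections:
        raise ValueError("stitch_field: need at least one overlap section")
    voting_cfg = voting_cfg or VotingConfig()
    candidates = []
    for j in overlap_sections:
        if j not in block_prev_fields or j not in block_next_fields:
            continue
        if _is_blank(stack[j]):
            continue
        res = stack[j].resolution
        in_next = SectionImage(warp(stack[j].pixels, block_next_fields[j]), res, j)
        in_prev = SectionImage(warp(stack[j].pixels, block_prev_fields[j]), res, j)
        if _is_blank(in_next) or _is_blank(in_prev):
            continue
        try:
            candidates.append(aligner(in_next, in_prev))
        except Exception:
            continue
    if not candidates:
        raise RuntimeError("stitch_field: all overlap sections invalid")
    voted = vote(candidates, voting_cfg)
    return StitchField(voted, interface=min(overlap_sections))

# ---------------------------------------------------------------------------
# Decay and globalization
# ---------------------------------------------------------------------------

def decay(F: StitchField | DisplacementField, n: int, cfg: DecayConfig) -> DisplacementField:
    """Decay a stitch field for application n sections past its interface.

    Displacements are blurred with sigma(n) = c*n, then scaled by
    beta(n) = max(1 - n/d, 0). n = 0 leaves the field unchanged; n >= d
    yields the identity transform.
    """
    if n < 0:
        raise ValueError("decay distance n must be >= 0")
    fld = F.field if isinstance(F, StitchField) else F
    beta = max(1.0 - n / cfg.d, 0.0)
    if beta == 0.0:
        return DisplacementField.zeros(fld.shape, fld.resolution)
    if n == 0:
        return fld.copy()
    blurred = blur_field(fld, cfg.c * n, cfg.blur_method)
    return DisplacementField((beta * blurred.u).astype(np.float32), fld.resolution)


def globalize(
    block_fields: list[dict[int, DisplacementField]],
    stitch_fields: list[StitchField],
    cfg: DecayConfig,
    blocks: list[BlockSpec] | None = None,
) -> GlobalAlignment:
    """Compose block fields with decayed stitch fields into a global alignment.

    For a section z in block i the global field is
    ``F_z = F_{z->B_i} o decay(S_i, z-B_i) o ... o decay(S_1, z-B_1)``
    where S_j stitches block j onto block j-1. Stitches whose distance
    exceeds the decay distance contribute identity and are skipped. Overlap
    sections are taken from the later block: its leading sections sit next
    to its starter and carry the least accumulated sequential-alignment
    error, while the earlier block's trailing copies are the farthest from
    theirs; the earlier block's copies serve only to compute the stitch.
    """
    if len(stitch_fields) != len(block_fields) - 1:
        raise ValueError(
            f"globalize: need one stitch field per interface "
            f"({len(block_fields) - 1}), got {len(stitch_fields)}"
        )
    out = GlobalAlignment()
    interfaces = [s.interface for s in stitch_fields]
    for i, fields in enumerate(block_fields):
        for z, Fz in sorted(fields.items()):
            # later blocks overwrite overlap duplicates
            total = Fz
            applied = []
            for j in range(i, 0, -1):
                dist = z - interfaces[j - 1]
                if dist >= cfg.d:
                    continue
                # clamp extension: zero-extending a transform chain would
                # zero the stitch in a boundary band as wide as the drift
                total = compose(total, decay(stitch_fields[j - 1], max(dist, 0), cfg), extend="clamp")
                applied.append(interfaces[j - 1])
            out.fields[z] = total
            out.provenance[z] = {"block": i, "stitches": applied}
    return out


def verify_pair_preservation(
    global_alignment: GlobalAlignment,
    pair_fields: dict[int, DisplacementField],
    tol: float = 0.5,
    tissue_masks: dict[int, np.ndarray] | None = None,
) -> dict:
    """Check that globalization preserved neighbor-pair alignment.

    For each section z with a known pair field F_{z->z-1}, measures the
    deviation map ``||(F_z o invert(F_{z-1})).u - F_{z->z-1}.u||`` over
    tissue and reports per-section max/mean plus an overall pass/fail
    against ``tol`` (px). Pixels whose composition chain sampled outside the
    grid (the boundary band swept out by accumulated drift, where fields are
    only extensions, not measurements) are excluded automatically.
    """
    report = {"sections": {}, "max_deviation": 0.0, "mean_deviation": 0.0, "tol": tol}
    devs = []
    for z, pair in sorted(pair_fields.items()):
        if z not in global_alignment.fields or z - 1 not in global_alignment.fields:
            continue
        try:
            inv_prev = invert(global_alignment.fields[z - 1], tol=1e-2, max_iter=60, check=False)
        except RuntimeError as exc:
            report["sections"][z] = {"error": str(exc)}
            continue
        rel = compose(global_alignment.fields[z], inv_prev, extend="clamp")
        d = rel.u.astype(np.float64) - pair.u.astype(np.float64)
        dev = np.hypot(d[..., 0], d[..., 1])
        if tissue_masks is not None and z in tissue_masks:
            m = np.asarray(tissue_masks[z], bool).copy()
        else:
            m = np.ones(dev.shape, bool)
        # exclude pixels where the composition left the grid: there the
        # fields are extrapolations, not measurements
        H, W = dev.shape
        rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        for fld in (inv_prev, rel, pair):
            ys = rr + fld.u[..., 0]
            xs = cc + fld.u[..., 1]
            m &= (ys >= 0) & (ys <= H - 1) & (xs >= 0) & (xs <= W - 1)
        # a 2-px rim absorbs bilinear boundary effects of the inversion
        m[:2] = m[-2:] = False
        m[:, :2] = m[:, -2:] = False
        if not m.any():
            continue
        mx = float(dev[m].max())
        report["sections"][z] = {"max": mx, "mean": float(dev[m].mean())}
        devs.append(mx)
    if devs:
        report["max_deviation"] = float(np.max(devs))
        report["mean_deviation"] = float(np.mean(devs))
    report["passed"] = bool(report["max_deviation"] <= tol)
    return report


def kernel_difference_curve(c: float, n_max: int) -> np.ndarray:
    """L1 difference between consecutive decay-blur kernels, per section.

    For n = 1..n_max builds the normalized discrete Gaussians G_{sigma(n)}
    with sigma(n) = c*n (radius ceil(3*sigma), minimum 1) and returns the
    array of pairs (n, sum |G_{sigma(n)} - G_{sigma(n-1)}|) — the operator
    bound on the per-section pair-alignment discrepancy introduced by the
    growing blur, expressed as a fraction.
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    out = np.zeros((n_max, 2))
    prev = gaussian_kernel_1d(0.0)
    for n in range(1, n_max + 1):
        cur = gaussian_kernel_1d(c * n)
        width = max(len(prev), len(cur))
        a = np.zeros(width)
        b = np.zeros(width)
        a[(width - len(prev)) // 2 : (width - len(prev)) // 2 + len(prev)] = prev
        b[(width - len(cur)) // 2 : (width - len(cur)) // 2 + len(cur)] = cur
        out[n - 1] = (n, np.abs(a - b).sum())
        prev = cur
    return out
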