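"""Pipeline configuration, chunked execution, job scheduling, end-to-end run.

The production-scale system dispatches chunk-level tasks to cloud workers;
here a local scheduler with the same job/barrier semantics runs tasks in a
thread pool (results are bit-identical to serial execution because tasks are
pure functions of their inputs and blocks are independent by construction).
"""

from __future__ import annotations

import json
import time
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .abcd import (
    DecayConfig,
    GlobalAlignment,
    align_block,
    globalize,
    partition_blocks,
    stitch_field,
)
from .aligners import BlockmatchParams, FinetuneConfig, MultiscaleConfig, align_pair_multiscale
from .evaluation import CPCSummary, cpc, cpc_summary
from .fields import DisplacementField, warp
from .preprocess import SectionImage, build_pyramid
from .synthstack import StackRecipe, SyntheticStack, gen_stack
from .voting import VotingConfig

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated end-to-end run parameters (YAML-serializable)."""

    seed: int = 0
    pyramid_levels: int = 2
    coarse_level: int = 2
    voting_n: int = 3
    voting_T: float = 5.7
    presmooth_sigma: float = 0.0
    block_size: int = 10
    block_overlap: int = 3
    starters: list[int] | None = None
    decay_c: float = 0.2
    decay_d: int = 100
    blur_method: str = "direct"
    blockmatch: dict = dc_field(default_factory=dict)
    finetune_levels: dict = dc_field(default_factory=dict)  # level -> FinetuneConfig kwargs
    finetune_step: float = 0.1
    finetune_iters: int = 120
    finetune_gamma: float = 15.0
    cpc_chunk: int = 64
    workers: int = 1

    def __post_init__(self) -> None:
        if self.block_size <= self.block_overlap:
            raise ValueError("block_size must exceed block_overlap")
        if self.voting_n < 1 or self.voting_T <= 0:
            raise ValueError("invalid voting parameters")
        if self.decay_d < 1 or self.decay_c < 0:
            raise ValueError("invalid decay parameters")
        if self.pyramid_levels < 0 or self.coarse_level > self.pyramid_levels:
            raise ValueError("coarse_level must be within pyramid_levels")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f)

    def voting(self) -> VotingConfig:
        return VotingConfig(self.voting_n, self.voting_T, self.presmooth_sigma)

    def decay(self) -> DecayConfig:
        return DecayConfig(self.decay_c, self.decay_d, self.blur_method)

# ---------------------------------------------------------------------------
# Chunked application
# ---------------------------------------------------------------------------

@dataclass
class ChunkSpec:
    """Spatial tiling with overlap margins, reassembled by crop or feather."""

    tile: int
    margin: int = 0
    blend: str = "crop"

    def __post_init__(self) -> None:
        if self.margin >= self.tile:
            raise ValueError("margin must be smaller than the tile size")
        if self.blend not in ("crop", "feather"):
            raise ValueError("blend must be 'crop' or 'feather'")


def chunked_apply(op, array: np.ndarray, spec: ChunkSpec) -> np.ndarray:
    """Apply ``op`` tile-by-tile with overlap and reassemble.

    crop mode discards the margin of each processed tile; feather mode
    linearly blends the overlap. For ops with support radius <= margin the
    result matches the untiled computation to interpolation accuracy. With
    margin 0 and a nonlocal op, seams are expected (a warning is emitted).
    """
    H, W = array.shape[:2]
    if spec.margin == 0 and spec.tile < max(H, W):
        warnings.warn("chunked_apply: margin 0 may produce seams for nonlocal ops", stacklevel=2)
    out = np.zeros_like(np.asarray(op(array[: min(spec.tile, H), : min(spec.tile, W)])), shape=array.shape)
    weight = np.zeros(array.shape[:2], dtype=np.float64) if spec.blend == "feather" else None
    acc = np.zeros(array.shape, dtype=np.float64) if spec.blend == "feather" else None
    for r0 in range(0, H, spec.tile):
        for c0 in range(0, W, spec.tile):
            r1, c1 = min(r0 + spec.tile, H), min(c0 + spec.tile, W)
            rm0, cm0 = max(r0 - spec.margin, 0), max(c0 - spec.margin, 0)
            rm1, cm1 = min(r1 + spec.margin, H), min(c1 + spec.margin, W)
            res = np.asarray(op(array[rm0:rm1, cm0:cm1]))
            if spec.blend == "crop":
                out[r0:r1, c0:c1] = res[r0 - rm0 : r0 - rm0 + (r1 - r0), c0 - cm0 : c0 - cm0 + (c1 - c0)]
            else:
                wr = np.minimum(np.arange(rm0, rm1) - rm0 + 1, rm1 - np.arange(rm0, rm1))
                wc = np.minimum(np.arange(cm0, cm1) - cm0 + 1, cm1 - np.arange(cm0, cm1))
                w2 = np.clip(np.outer(wr, wc), 0, None).astype(np.float64)
                if res.ndim == 3:
                    acc[rm0:rm1, cm0:cm1] += res * w2[..., None]
                else:
                    acc[rm0:rm1, cm0:cm1] += res * w2
                weight[rm0:rm1, cm0:cm1] += w2
    if spec.blend == "feather":
        w = np.where(weight > 0, weight, 1.0)
        out = (acc / (w[..., None] if array.ndim == 3 else w)).astype(array.dtype)
    return out

# ---------------------------------------------------------------------------
# Job / barrier scheduler
# ---------------------------------------------------------------------------

class Barrier:
    """Yielded by a job to require completion of all tasks issued so far."""


@dataclass
class Task:
    key: str
    fn: object
    args: tuple = ()


def run_jobs(jobs, workers: int = 1) -> dict:
    """Run generator-style jobs with barrier semantics.

    Each job is a generator yielding Task objects or Barrier instances.
    Tasks issued between barriers may run in any order (here: a thread
    pool); results are identical to serial execution because tasks are pure.
    Returns a manifest with task results, ordering, and timing; a failing
    task aborts at the next barrier with the task identified.
    """
    manifest = {"tasks": [], "results": {}, "workers": workers, "started": time.time()}
    results = manifest["results"]

    def run_batch(batch: list[Task]):
        if not batch:
            return
        t0 = time.time()
        if workers <= 1:
            for task in batch:
                try:
                    results[task.key] = task.fn(*task.args)
                except Exception as exc:
                    raise RuntimeError(f"task {task.key!r} failed: {exc}") from exc
        else:
            with ThreadPoolExecutor(max_workers=workers) as pool:
                futs = {task.key: pool.submit(task.fn, *task.args) for task in batch}
            for key, fut in futs.items():
                exc = fut.exception()
                if exc is not None:
                    raise RuntimeError(f"task {key!r} failed: {exc}") from exc
                results[key] = fut.result()
        manifest["tasks"].append({"batch": [t.key for t in batch], "seconds": time.time() - t0})

    for job in jobs:
        pending: list[Task] = []
        for item in job:
            if isinstance(item, Barrier):
                run_batch(pending)
                pending = []
            else:
                pending.append(item)
        run_batch(pending)
    manifest["finished"] = time.time()
    return manifest

# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _make_pair_aligner(cfg: PipelineConfig, levels: int, masks_by_z: dict | None = None):
    """Build the multiscale aligner closure used for every pair alignment.

    Block matching runs at *every* level: the coarse estimate alone carries a
    residual proportional to the deformation amplitude (patch matching
    averages the within-patch deformation), and re-matching the pre-warped
    source at each finer level shrinks that residual geometrically to within
    the finetuner's capture range. Finer levels search a narrow range over a
    sparse grid since the running field already holds the coarse solution.

    The finetuner's elastic weight follows the published guidance of larger
    values at coarser resolutions: gamma = min(gamma_max, 5 * (level + 1)).

    masks_by_z maps a section index to its MaskSet so that the finetuner can
    zero the elastic regularizer at defect locations of the source section;
    rendered targets keep their section_index, so lookup works transitively.
    """
    bm = BlockmatchParams(**cfg.blockmatch) if cfg.blockmatch else BlockmatchParams()
    level_list = list(range(cfg.coarse_level, -1, -1))
    bm_levels = {}
    for lvl in level_list:
        if lvl == cfg.coarse_level:
            bm_levels[lvl] = bm
        else:
            # narrow search (+-4 px), sparser grid at the finest level
            step = max(bm.grid_step, 32) if lvl == 0 else bm.grid_step
            bm_levels[lvl] = BlockmatchParams(
                src_patch=bm.src_patch, tgt_patch=bm.src_patch + 8, grid_step=step,
                min_corr=bm.min_corr, subpixel=bm.subpixel,
            )
    ft_levels = {}
    for lvl in level_list:
        if lvl == cfg.coarse_level:
            iters = cfg.finetune_iters
        elif lvl == 0:
            iters = max(1, cfg.finetune_iters // 4)
        else:
            iters = max(1, (2 * cfg.finetune_iters) // 3)
        gamma = min(cfg.finetune_gamma, 5.0 * (lvl + 1))
        ft_levels[lvl] = FinetuneConfig(
            step_size=cfg.finetune_step, max_iters=iters, tol=1e-6, gamma=gamma
        )
    overrides = {int(k): FinetuneConfig(**v) for k, v in cfg.finetune_levels.items()}
    ft_levels.update(overrides)
    ms = MultiscaleConfig(
        levels=level_list,
        aligners={lvl: "blockmatch" for lvl in level_list},
        blockmatch_params=bm,
        blockmatch_per_level=bm_levels,
        finetune=ft_levels,
    )

    def aligner(src: SectionImage, tgt: SectionImage) -> DisplacementField:
        src_masks = (masks_by_z or {}).get(src.section_index)
        src_pyr = build_pyramid(src, src_masks, levels)
        tgt_pyr = build_pyramid(tgt, None, levels)
        return align_pair_multiscale(src_pyr, tgt_pyr, ms)

    return aligner


def run_pipeline(
    config: PipelineConfig,
    stack: SyntheticStack | list[SectionImage] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[GlobalAlignment, CPCSummary, dict]:
    """Full run: block align -> stitch -> globalize -> render -> CPC report.

    With no stack supplied, the default synthetic recipe (seeded from the
    config) is generated. Returns the global alignment, the CPC summary of
    the rendered result, and the run manifest.
    """
    if stack is None:
        stack = gen_stack(StackRecipe(seed=config.seed))
    sections = stack.sections if isinstance(stack, SyntheticStack) else stack
    n = len(sections)
    masks_by_z = (
        {z: m for z, m in enumerate(stack.masks)}
        if isinstance(stack, SyntheticStack)
        else None
    )
    aligner = _make_pair_aligner(config, config.pyramid_levels, masks_by_z)
    voting = config.voting()
    blocks = partition_blocks(n, config.block_size, config.block_overlap, config.starters)

    block_results: dict[int, dict[int, DisplacementField]] = {}

    def block_job():
        for b in blocks:
            yield Task(f"block{b.index}", align_block, (sections, b, aligner, voting))
        yield Barrier()

    manifest = run_jobs([block_job()], workers=config.workers)
    for b in blocks:
        block_results[b.index] = manifest["results"][f"block{b.index}"]

    stitches = []
    for prev, nxt in zip(blocks, blocks[1:]):
        overlap = [z for z in nxt.sections if z in block_results[prev.index]][: config.block_overlap]
        stitches.append(
            stitch_field(
                sections,
                block_results[prev.index],
                block_results[nxt.index],
                overlap,
                aligner,
                voting,
            )
        )
    global_alignment = globalize(
        [block_results[b.index] for b in blocks], stitches, config.decay(), blocks
    )

    rendered = [
        SectionImage(warp(sections[z].pixels, global_alignment.fields[z]), sections[z].resolution, z)
        for z in global_alignment.sections()
    ]
    masks = stack.masks if isinstance(stack, SyntheticStack) else None
    maps = []
    zs = global_alignment.sections()
    for a, b in zip(zs, zs[1:]):
        msk = None
        if masks is not None:
            # carry the defect mask through the same transform as the image
            from .preprocess import MaskSet

            warped_defect = (
                warp(masks[b].defect.astype(np.float32), global_alignment.fields[b]) > 0.25
            )
            msk = MaskSet(warped_defect, np.ones_like(warped_defect), sections[b].resolution)
        maps.append(cpc(rendered[zs.index(b)], rendered[zs.index(a)], config.cpc_chunk, msk))
    summary = cpc_summary(maps) if maps else None
    manifest["config"] = asdict(config)
    manifest["blocks"] = [(b.start, b.stop) for b in blocks]
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import save_fields, save_stack_tiff

        save_fields(out / "global_fields.h5", dict(global_alignment.fields))
        save_stack_tiff(out / "rendered.tiff", rendered)
        safe = {k: v for k, v in manifest.items() if k != "results"}
        (out / "manifest.json").write_text(json.dumps(safe, default=str, indent=2))
    return global_alignment, summary, manifest
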