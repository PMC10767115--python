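"""Synthetic section stacks with known ground-truth deformations.

The generator emulates the failure modes alignment must survive: smooth
low-frequency per-section deformation plus drift, discontinuous defects
(cracks that separate tissue and folds that overlap it, with a band of lost
pixels), per-section acquisition artifacts (knife-chatter stripes, grid
pattern, dust, brightness gradients — deliberately uncorrelated across
sections), and fully missing sections. Every stack ships with its
ground-truth fields and masks so recovery can be measured exactly.

Determinism: the same recipe produces a bit-identical stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .fields import DisplacementField, compose, invert, warp
from .preprocess import MaskSet, SectionImage


@dataclass
class StackRecipe:
    """Generation parameters; the defaults are the desk-scale test stack.

    warp_amplitude is the maximum per-section relative displacement (px),
    warp_corr_length its spatial correlation length (px), drift a constant
    per-section translation magnitude (px). A defect of ``defect_width`` px
    is inserted every ``defect_every`` sections; stripes hit a
    ``stripe_fraction`` of sections; ``missing_sections`` are blanked.
    """

    seed: int = 0
    sections: int = 30
    size: int = 512
    warp_amplitude: float = 8.0
    warp_corr_length: float = 64.0
    drift: float = 2.0
    defect_kind: str = "fold"
    defect_width: float = 12.0
    defect_every: int = 5
    defect_apron: float = 16.0
    stripe_fraction: float = 0.2
    missing_sections: list[int] = dc_field(default_factory=lambda: [15])

    def __post_init__(self) -> None:
        for z in self.missing_sections:
            if not 0 <= z < self.sections:
                raise ValueError(f"missing section {z} outside range 0..{self.sections - 1}")


@dataclass
class SyntheticStack:
    """Observed sections plus the ground truth that generated them."""

    sections: list[SectionImage]
    gt_fields: list[DisplacementField]  # W_z: observed_z = warp(base, W_z)
    gt_rel_fields: list[DisplacementField | None]  # R_z: warp(obs_z, R_z) ~ obs_{z-1}
    masks: list[MaskSet]
    base: np.ndarray
    recipe: StackRecipe
    # per-section band where the defect displacement is non-negligible; wider
    # than the detection mask, used to exclude defect neighborhoods from
    # ground-truth comparisons (the gt pair fields exclude defect transforms)
    eval_masks: list[np.ndarray] = dc_field(default_factory=list)


def gen_texture(seed: int, size: int) -> np.ndarray:
    """Cell-boundary-like test texture: smoothed Voronoi edges + band noise.

    Values lie in [0.2, 1.2] so that 0 stays reserved for non-tissue.
    """
    if size < 64:
        raise ValueError("texture size must be >= 64 (NCC needs features)")
    rng = np.random.default_rng(seed)
    n_cells = max(16, (size // 24) ** 2)
    pts = rng.uniform(0, size, size=(n_cells, 2))
    tree = cKDTree(pts)
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1)
    d, _ = tree.query(grid, k=2)
    edge = np.exp(-(((d[:, 1] - d[:, 0]) / 2.5) ** 2)).reshape(size, size)
    noise = rng.normal(size=(size, size))
    band = ndimage.gaussian_filter(noise, 1.2) - ndimage.gaussian_filter(noise, 5.0)
    band /= max(band.std(), 1e-12)
    tex = 0.7 - 0.45 * edge + 0.12 * band
    return np.clip(tex, 0.2, 1.2).astype(np.float32)


def gen_smooth_field(
    seed: int, amplitude: float, corr_length: float, size: int
) -> DisplacementField:
    """Band-limited random field with max displacement norm <= amplitude."""
    if corr_length <= 0:
        raise ValueError("corr_length must be > 0")
    if amplitude == 0:
        return DisplacementField.zeros((size, size))
    rng = np.random.default_rng(seed)
    comps = []
    for _ in range(2):
        white = rng.normal(size=(size, size))
        comps.append(ndimage.gaussian_filter(white, corr_length / 2.0, mode="wrap"))
    u = np.stack(comps, axis=-1)
    mags = np.hypot(u[..., 0], u[..., 1])
    peak = mags.max()
    if peak > 0:
        u *= amplitude / peak
    return DisplacementField(u.astype(np.float32))


def gen_discontinuity(
    seed: int, kind: str, width: float, size: int, apron: float = 16.0
) -> tuple[DisplacementField, np.ndarray]:
    """Displacement discontinuous across a random line, plus its defect mask.

    crack: the two sides separate by ``width`` px; the gap band of lost
    pixels is masked. fold: the sides move toward the line (overlap); the
    occluded band is masked. Displacement decays to zero within the apron.
    The returned mask covers exactly the lost/occluded band (what a defect
    detector would mark), which contains the non-invertible region.
    """
    if width < 0:
        raise ValueError("defect width must be >= 0")
    if kind not in ("crack", "fold"):
        raise ValueError(f"unknown defect kind {kind!r}")
    if width == 0:
        return DisplacementField.zeros((size, size)), np.zeros((size, size), bool)
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, np.pi)
    normal = np.array([np.cos(theta), np.sin(theta)])
    p0 = rng.uniform(0.3 * size, 0.7 * size, size=2)
    rr, cc = np.meshgrid(np.arange(size, dtype=np.float64), np.arange(size, dtype=np.float64), indexing="ij")
    s = (rr - p0[0]) * normal[0] + (cc - p0[1]) * normal[1]
    decay = np.exp(-((s / apron) ** 2))
    sign = np.sign(s)
    half = width / 2.0
    if kind == "crack":
        mag = half * sign * decay
    else:  # fold: sides move toward the line
        mag = -half * sign * decay
    u = np.stack([mag * normal[0], mag * normal[1]], axis=-1)
    mask = np.abs(s) <= half
    return DisplacementField(u.astype(np.float32)), mask


def gen_artifacts(seed: int, image: np.ndarray, spec: dict) -> np.ndarray:
    """Apply acquisition artifacts to a section image.

    spec maps artifact kinds to parameter dicts; supported kinds are
    "stripes" (parallel high-contrast bands), "grid" (additive periodic
    pattern), "dust" (dark blobs), "brightness" (low-frequency gradient).
    """
    known = {"stripes", "grid", "dust", "brightness"}
    unknown = set(spec) - known
    if unknown:
        raise ValueError(f"unknown artifact kinds: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    out = image.astype(np.float32).copy()
    size = image.shape[0]
    tissue = out != 0
    if "stripes" in spec:
        p = spec["stripes"]
        period = p.get("period", 40)
        band = p.get("width", 3)
        phase = int(rng.integers(0, period))
        rows = (np.arange(image.shape[0]) + phase) % period < band
        out[rows, :] = np.where(tissue[rows, :], p.get("value", 1.5), out[rows, :])
    if "grid" in spec:
        p = spec["grid"]
        period = p.get("period", 32)
        amp = p.get("amplitude", 0.2)
        rr, cc = np.meshgrid(np.arange(image.shape[0]), np.arange(image.shape[1]), indexing="ij")
        pattern = amp * (np.sin(2 * np.pi * rr / period) + np.sin(2 * np.pi * cc / period))
        out = np.where(tissue, out + pattern.astype(np.float32), out)
    if "dust" in spec:
        p = spec["dust"]
        for _ in range(p.get("count", 5)):
            r0, c0 = rng.uniform(0, size, 2)
            rad = rng.uniform(3, p.get("max_radius", 8))
            rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
            blob = (rr - r0) ** 2 + (cc - c0) ** 2 < rad**2
            out[blob & tissue] = p.get("value", 0.05)
    if "brightness" in spec:
        p = spec["brightness"]
        gvec = rng.uniform(-1, 1, 2)
        rr, cc = np.meshgrid(np.linspace(-1, 1, size), np.linspace(-1, 1, size), indexing="ij")
        plane = 1.0 + p.get("amplitude", 0.3) * (gvec[0] * rr + gvec[1] * cc)
        out = np.where(tissue, out * plane.astype(np.float32), out)
    return out


def gen_stack(recipe: StackRecipe) -> SyntheticStack:
    """Generate a full synthetic stack with ground truth.

    Section z's observation is ``warp(base, W_z)`` where
    ``W_z = drift_z o D_z`` combines an accumulated constant drift
    (``z * drift`` px) with an *independent* per-section smooth distortion
    D_z of amplitude ``warp_amplitude`` — modeling acquisition distortion
    that does not accumulate across sections, on top of a slow stage drift.
    The ground-truth pair field ``R_z = invert(W_z) o W_{z-1}`` satisfies
    ``warp(obs_z, R_z) ~ obs_{z-1}``. Defect displacements with lost-pixel
    zeroing, artifacts, and blanking are applied per section after warping,
    with matching ground-truth masks.
    """
    rng = np.random.default_rng(recipe.seed)
    n_sections = recipe.sections
    base = gen_texture(int(rng.integers(2**31)), recipe.size)
    drift_theta = rng.uniform(0, 2 * np.pi)
    drift_vec = recipe.drift * np.array([np.sin(drift_theta), np.cos(drift_theta)])

    sections: list[SectionImage] = []
    gt_fields: list[DisplacementField] = []
    gt_rel: list[DisplacementField | None] = [None]
    masks: list[MaskSet] = []
    eval_masks: list[np.ndarray] = []
    stripe_seeds = rng.integers(2**31, size=n_sections)
    stripe_hits = rng.random(n_sections) < recipe.stripe_fraction
    W_prev: DisplacementField | None = None
    for z in range(n_sections):
        if z == 0:
            W = DisplacementField.zeros((recipe.size, recipe.size))
        else:
            D = gen_smooth_field(
                int(rng.integers(2**31)), recipe.warp_amplitude, recipe.warp_corr_length, recipe.size
            )
            W = DisplacementField((D.u + z * drift_vec).astype(np.float32))
            gt_rel.append(compose(invert(W, tol=1e-3, max_iter=200), W_prev, extend="clamp"))
        W_prev = W
        gt_fields.append(W.copy())
        obs = warp(base, W)
        defect_mask = np.zeros((recipe.size, recipe.size), bool)
        eval_mask = np.zeros((recipe.size, recipe.size), bool)
        if recipe.defect_every and z % recipe.defect_every == 2 and recipe.defect_width > 0:
            dfield, dmask = gen_discontinuity(
                int(rng.integers(2**31)),
                recipe.defect_kind,
                recipe.defect_width,
                recipe.size,
                recipe.defect_apron,
            )
            obs = warp(obs, dfield)
            obs[dmask] = 0.0
            defect_mask = dmask
            eval_mask = dmask | (dfield.magnitude() > 0.05)
        if stripe_hits[z]:
            obs = gen_artifacts(int(stripe_seeds[z]), obs, {"stripes": {}})
        if z in recipe.missing_sections:
            obs = np.zeros_like(obs)
            tissue = np.zeros_like(obs, bool)
        else:
            # full frame is tissue; lost defect pixels are covered by the defect mask
            tissue = np.ones_like(obs, bool)
        sections.append(SectionImage(obs.astype(np.float32), 1.0, z))
        masks.append(MaskSet(defect_mask, tissue))
        eval_masks.append(eval_mask)
    return SyntheticStack(sections, gt_fields, gt_rel, masks, base, recipe, eval_masks)


def recovery_error(
    gt: SyntheticStack,
    fields: dict[int, DisplacementField],
    margin: int = 8,
) -> dict:
    """Pair-relative recovery error of an alignment result against ground truth.

    Global alignment is only defined up to a slowly varying stack-wide
    drift, so error is measured on pair transforms: per section,
    ``RMS over tissue of ||(F_z o invert(F_{z-1})).u - R_z.u||`` where R_z is
    the ground-truth relative field. Defect bands of both sections and a
    boundary margin are excluded. Returns per-section RMS plus max/mean.
    """
    n = len(gt.sections)
    per_section: dict[int, float] = {}
    for z in range(1, n):
        if gt.gt_rel_fields[z] is None or z not in fields or z - 1 not in fields:
            continue
        if gt.recipe.missing_sections and (
            z in gt.recipe.missing_sections or z - 1 in gt.recipe.missing_sections
        ):
            continue
        rel = compose(fields[z], invert(fields[z - 1], tol=1e-2, max_iter=60, check=False), extend="clamp")
        d = rel.u.astype(np.float64) - gt.gt_rel_fields[z].u.astype(np.float64)
        dev = np.hypot(d[..., 0], d[..., 1])
        excl_z = gt.eval_masks[z] if gt.eval_masks else gt.masks[z].defect
        excl_p = gt.eval_masks[z - 1] if gt.eval_masks else gt.masks[z - 1].defect
        m = gt.masks[z].tissue & ~excl_z & ~excl_p
        if margin:
            m = m.copy()
            m[:margin] = m[-margin:] = False
            m[:, :margin] = m[:, -margin:] = False
        if not m.any():
            continue
        per_section[z] = float(np.sqrt((dev[m] ** 2).mean()))
    if not per_section:
        raise ValueError("recovery_error: no comparable section pairs")
    vals = np.array(list(per_section.values()))
    return {
        "per_section_rms": per_section,
        "mean_rms": float(vals.mean()),
        "max_rms": float(vals.max()),
    }
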