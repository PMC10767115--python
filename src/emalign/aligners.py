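"""Pair aligners: NCC block matching, trainable Encoder/Aligner, the online
field finetuner, and the coarse-to-fine multiscale driver.

Every aligner obeys the same contract: given a (preprocessed) source and
target section it returns a dense displacement field on the source grid such
that ``warp(source, field) ~ target``. Aligners support transitive use — the
source may be pre-warped by an earlier field, or the target may already
carry its own alignment — which is what sequential block alignment and
stitching rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from . import autograd as ag
from .fields import DisplacementField, compose, rescale_field, warp
from .losses import LossConfig, select_best_sample_chunks
from .nets import PairAlignerModel
from .preprocess import SectionImage

# ---------------------------------------------------------------------------
# Block matching
# ---------------------------------------------------------------------------

@dataclass
class BlockmatchParams:
    """Masked-NCC block matching parameters (all in pixels).

    A source patch of ``src_patch`` px is correlated against a larger target
    patch of ``tgt_patch`` px on a Cartesian grid of ``grid_step`` px; the
    search range per axis is ``(tgt_patch - src_patch) // 2``. Defaults are
    desk-scale; ``coarse_em_preset`` reproduces the production-scale values
    (256 px patches against 358 px patches on a 96 px grid).
    """

    src_patch: int = 32
    tgt_patch: int = 48
    grid_step: int = 16
    min_corr: float = 0.2
    subpixel: bool = True
    min_valid_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.tgt_patch <= self.src_patch:
            raise ValueError("tgt_patch must exceed src_patch")
        if self.grid_step < 1:
            raise ValueError("grid_step must be >= 1")

    @classmethod
    def coarse_em_preset(cls) -> "BlockmatchParams":
        return cls(src_patch=256, tgt_patch=358, grid_step=96)


def _masked_ncc_node(src_patch, src_mask, tgt_patch, tgt_mask):
    """Masked Pearson correlation of a template against every placement.

    Returns the (S, S) correlation surface over all offsets, with NaN where
    fewer than half the template pixels are jointly valid.
    """
    ps = src_patch.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(tgt_patch, (ps, ps))
    mwin = np.lib.stride_tricks.sliding_window_view(tgt_mask, (ps, ps))
    m = mwin & src_mask[None, None]
    n = m.sum(axis=(2, 3)).astype(np.float64)
    s = np.where(m, src_patch[None, None], 0.0)
    t = np.where(m, win, 0.0)
    sx = s.sum(axis=(2, 3))
    sy = t.sum(axis=(2, 3))
    sxx = (s * s).sum(axis=(2, 3))
    syy = (t * t).sum(axis=(2, 3))
    sxy = (s * t).sum(axis=(2, 3))
    var_x = n * sxx - sx * sx
    var_y = n * syy - sy * sy
    denom = np.sqrt(np.clip(var_x, 0, None) * np.clip(var_y, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (n * sxy - sx * sy) / denom
    r[(denom <= 0) | (n < 0.5 * ps * ps)] = np.nan
    return r


def _parabolic_refine(surface: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """1D parabolic sub-pixel refinement of an NCC peak, per axis."""
    out = []
    for axis in range(2):
        i = peak[axis]
        if i <= 0 or i >= surface.shape[axis] - 1:
            out.append(0.0)
            continue
        idx = list(peak)
        idx[axis] = i - 1
        f0 = surface[tuple(idx)]
        f1 = surface[peak]
        idx[axis] = i + 1
        f2 = surface[tuple(idx)]
        denom = f0 - 2 * f1 + f2
        if not np.isfinite(f0) or not np.isfinite(f2) or denom >= 0 or abs(denom) < 1e-12:
            out.append(0.0)
        else:
            out.append(float(np.clip(0.5 * (f0 - f2) / denom, -0.5, 0.5)))
    return out[0], out[1]


def blockmatch(
    src: SectionImage | np.ndarray,
    tgt: SectionImage | np.ndarray,
    params: BlockmatchParams | None = None,
) -> DisplacementField:
    """Dense field from masked-NCC block matching on a Cartesian node grid.

    Nodes whose source or target patch is less than half nonzero, or whose
    peak correlation falls below ``min_corr``, are dropped and filled from
    the nearest surviving node; surviving node vectors are interpolated
    bilinearly to a dense field.
    """
    params = params or BlockmatchParams()
    s = np.asarray(getattr(src, "pixels", src), dtype=np.float64)
    t = np.asarray(getattr(tgt, "pixels", tgt), dtype=np.float64)
    if s.shape != t.shape:
        raise ValueError(f"blockmatch: shape mismatch {s.shape} vs {t.shape}")
    H, W = s.shape
    hs = params.src_patch // 2
    ht = params.tgt_patch // 2
    search = ht - hs
    node_rows = np.arange(ht, H - ht + 1, params.grid_step)
    node_cols = np.arange(ht, W - ht + 1, params.grid_step)
    if len(node_rows) == 0 or len(node_cols) == 0:
        raise ValueError(
            f"blockmatch: image {s.shape} too small for tgt_patch {params.tgt_patch}"
        )
    sm = s != 0
    tm = t != 0
    node_u = np.full((len(node_rows), len(node_cols), 2), np.nan)
    for i, r in enumerate(node_rows):
        for j, c in enumerate(node_cols):
            sp = s[r - hs : r - hs + params.src_patch, c - hs : c - hs + params.src_patch]
            spm = sm[r - hs : r - hs + params.src_patch, c - hs : c - hs + params.src_patch]
            if spm.mean() < params.min_valid_frac:
                continue
            tp = t[r - ht : r - ht + params.tgt_patch, c - ht : c - ht + params.tgt_patch]
            tpm = tm[r - ht : r - ht + params.tgt_patch, c - ht : c - ht + params.tgt_patch]
            if tpm.mean() < params.min_valid_frac:
                continue
            surface = _masked_ncc_node(sp, spm, tp, tpm)
            if np.all(np.isnan(surface)):
                continue
            peak = np.unravel_index(np.nanargmax(surface), surface.shape)
            if not (surface[peak] >= params.min_corr):
                continue
            dy, dx = (0.0, 0.0)
            if params.subpixel:
                dy, dx = _parabolic_refine(surface, peak)
            # window index o means tgt(p + o - search) ~ src(p): u = search - o
            node_u[i, j, 0] = search - (peak[0] + dy)
            node_u[i, j, 1] = search - (peak[1] + dx)
    valid = ~np.isnan(node_u[..., 0])
    if not valid.any():
        raise RuntimeError("blockmatch: insufficient texture, no surviving nodes")
    # fill dropped nodes from the nearest surviving node
    if not valid.all():
        _, (ir, ic) = ndimage.distance_transform_edt(~valid, return_indices=True)
        node_u = node_u[ir, ic]
    # interpolate node grid to a dense field (edge-clamped bilinear)
    rr, cc = np.meshgrid(np.arange(H, dtype=np.float64), np.arange(W, dtype=np.float64), indexing="ij")
    gr = (rr - node_rows[0]) / params.grid_step
    gc = (cc - node_cols[0]) / params.grid_step
    u = np.stack(
        [
            ndimage.map_coordinates(node_u[..., k], [gr, gc], order=1, mode="nearest", prefilter=False)
            for k in range(2)
        ],
        axis=-1,
    )
    res = getattr(src, "resolution", 1.0)
    return DisplacementField(u.astype(np.float32), res)

# ---------------------------------------------------------------------------
# Encoding / residual prediction
# ---------------------------------------------------------------------------

def encode(image: SectionImage | np.ndarray, model: PairAlignerModel | None = None) -> np.ndarray:
    """Dense per-pixel encoding (C, rows, cols) of a section.

    Without a trained model (or with a passthrough model) the encoding is the
    image itself as a single channel, so the rest of the pipeline runs
    net-free. The forward pass is deterministic.
    """
    px = np.asarray(getattr(image, "pixels", image), dtype=np.float64)
    if isinstance(image, SectionImage) and model is not None and model.encoder is not None:
        if abs(image.resolution - model.resolution) > 1e-9:
            raise ValueError(
                f"encode: image resolution {image.resolution} != model resolution {model.resolution}"
            )
    if model is None or model.encoder is None:
        return px[None]
    return model.encoder(ag.Tensor(px[None])).data


def predict_residual(
    enc_s: np.ndarray, enc_t: np.ndarray, model: PairAlignerModel
) -> DisplacementField:
    """Residual displacement field predicted by the Aligner net."""
    if enc_s.shape != enc_t.shape:
        raise ValueError(f"predict_residual: shape mismatch {enc_s.shape} vs {enc_t.shape}")
    if model.aligner is None:
        raise ValueError("predict_residual: passthrough model has no aligner net")
    out = model.aligner(ag.Tensor(enc_s), ag.Tensor(enc_t)).data  # (2, H, W)
    return DisplacementField(np.moveaxis(out, 0, -1).astype(np.float32), model.resolution)

# ---------------------------------------------------------------------------
# Online field finetuner
# ---------------------------------------------------------------------------

@dataclass
class FinetuneConfig:
    """Gradient-descent refinement parameters.

    step_size is the Adam learning rate, directly interpretable in pixels
    per iteration thanks to Adam's per-pixel gradient normalization.
    Iteration stops at max_iters or when the relative loss improvement over
    an iteration falls below tol. The best-loss iterate is kept throughout.
    """

    step_size: float = 0.1
    max_iters: int = 200
    tol: float = 1e-6
    gamma: float = 15.0

    def __post_init__(self) -> None:
        if self.step_size <= 0 or self.max_iters < 1 or self.tol < 0 or self.gamma <= 0:
            raise ValueError("FinetuneConfig values must be positive")


def _finetune_loss_and_grad(u, qs, qt, qt_tissue, defect_dil, gamma):
    """Masked encoding MSE + gamma * elastic regularizer, with du gradient.

    Fused float32 implementation (the finetuner's inner loop dominates
    pipeline runtime); cross-checked against the autograd engine in tests.
    """
    C, H, W = qs.shape
    rr, cc = np.meshgrid(
        np.arange(H, dtype=np.float32), np.arange(W, dtype=np.float32), indexing="ij"
    )
    y = rr + u[0]
    x = cc + u[1]
    y0 = np.floor(y).astype(np.int32)
    x0 = np.floor(x).astype(np.int32)
    fy = (y - y0).astype(np.float32)
    fx = (x - x0).astype(np.float32)
    warped = np.zeros((C, H, W), dtype=np.float32)
    inside = (y >= 0) & (y <= H - 1) & (x >= 0) & (x <= W - 1)
    corner_cache = []
    for dy, dx in ((0, 0), (0, 1), (1, 0), (1, 1)):
        yy = y0 + dy
        xx = x0 + dx
        valid = inside & (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        wy = fy if dy else 1.0 - fy
        wx = fx if dx else 1.0 - fx
        wgt = (wy * wx * valid).astype(np.float32)
        yyc = np.clip(yy, 0, H - 1)
        xxc = np.clip(xx, 0, W - 1)
        vals = qs[:, yyc, xxc]
        warped += vals * wgt
        corner_cache.append((vals, dy, dx, valid))
    w_tissue = np.any(warped != 0, axis=0)
    tst = w_tissue & qt_tissue
    n_t = int(tst.sum())
    grad = np.zeros((2, H, W), dtype=np.float32)
    loss = 0.0
    if n_t:
        diff = (warped - qt) * tst
        loss += float((diff * diff).sum()) / n_t
        # d(bilinear)/dy and /dx, exact within each cell
        resid = (2.0 / n_t) * diff
        gy = np.zeros((H, W), dtype=np.float32)
        gx = np.zeros((H, W), dtype=np.float32)
        for vals, dy, dx, valid in corner_cache:
            coef = (vals * resid).sum(axis=0)
            dw_dfy = (1.0 if dy else -1.0) * (fx if dx else 1.0 - fx)
            dw_dfx = (1.0 if dx else -1.0) * (fy if dy else 1.0 - fy)
            gy += coef * dw_dfy * valid
            gx += coef * dw_dfx * valid
        grad[0] = gy
        grad[1] = gx
    vmask = w_tissue & ~defect_dil
    n_v = int(vmask.sum())
    if n_v:
        vw = (gamma / n_v) * vmask.astype(np.float32)
        for dr, dc in ((0, 1), (1, 0), (1, 1)):
            rest = np.float32(np.hypot(dr, dc))
            dyc = u[0, : H - dr or None, : W - dc or None] - u[0, dr:, dc:] - dr
            dxc = u[1, : H - dr or None, : W - dc or None] - u[1, dr:, dc:] - dc
            dist = np.hypot(dyc, dxc).astype(np.float32)
            wv = vw[: H - dr or None, : W - dc or None]
            loss += float((((dist - rest) ** 2) * wv).sum())
            safe = np.where(dist > 1e-12, dist, 1.0)
            coef = 2.0 * (dist - rest) / safe * wv
            gye = coef * dyc
            gxe = coef * dxc
            grad[0, : H - dr or None, : W - dc or None] += gye
            grad[1, : H - dr or None, : W - dc or None] += gxe
            grad[0, dr:, dc:] -= gye
            grad[1, dr:, dc:] -= gxe
    if not np.isfinite(loss):
        raise RuntimeError("finetune_field: non-finite loss")
    return loss, grad


def finetune_field(
    F0: DisplacementField,
    Q_s: np.ndarray,
    Q_t: np.ndarray,
    defect_mask: np.ndarray | None = None,
    cfg: FinetuneConfig | None = None,
) -> DisplacementField:
    """Refine a displacement field by gradient descent.

    Minimizes the masked squared difference between the encodings after
    alignment plus the elastic regularizer, starting from ``F0``. The
    best-loss iterate is returned, so the result's loss never exceeds
    ``F0``'s.
    """
    cfg = cfg or FinetuneConfig()
    qs = np.asarray(Q_s, dtype=np.float32)
    qt = np.asarray(Q_t, dtype=np.float32)
    if qs.ndim == 2:
        qs = qs[None]
    if qt.ndim == 2:
        qt = qt[None]
    qt_tissue = np.any(qt != 0, axis=0)
    if defect_mask is not None:
        defect_dil = ndimage.binary_dilation(np.asarray(defect_mask, bool), iterations=1)
    else:
        defect_dil = np.zeros(qs.shape[-2:], bool)

    u = np.moveaxis(F0.u.astype(np.float32), -1, 0).copy()  # (2, H, W)
    loss, grad = _finetune_loss_and_grad(u, qs, qt, qt_tissue, defect_dil, cfg.gamma)
    best_u, best_loss = u.copy(), loss
    if np.abs(grad).max() == 0:
        return F0.copy()
    # Adam on the field: per-pixel normalization makes step_size meaningful in px
    m = np.zeros_like(u)
    v = np.zeros_like(u)
    prev_loss = loss
    for t in range(1, cfg.max_iters + 1):
        m = 0.9 * m + 0.1 * grad
        v = 0.999 * v + 0.001 * grad * grad
        mh = m / (1 - 0.9**t)
        vh = v / (1 - 0.999**t)
        u = u - cfg.step_size * mh / (np.sqrt(vh) + 1e-8)
        loss, grad = _finetune_loss_and_grad(u, qs, qt, qt_tissue, defect_dil, cfg.gamma)
        if loss < best_loss:
            best_loss, best_u = loss, u.copy()
        if abs(prev_loss - loss) <= cfg.tol * max(abs(prev_loss), 1e-12):
            break
        prev_loss = loss
    return DisplacementField(np.moveaxis(best_u, 0, -1).astype(np.float32), F0.resolution)

# ---------------------------------------------------------------------------
# Coarse-to-fine multiscale driver
# ---------------------------------------------------------------------------

@dataclass
class MultiscaleConfig:
    """Which aligner runs at each pyramid level, finest (0) excluded or not.

    levels lists pyramid level indices coarsest-first. ``aligners`` maps a
    level to either the string "blockmatch" (with blockmatch_params) or a
    PairAlignerModel. ``finetune`` maps a level to a FinetuneConfig or None.
    ``blockmatch_per_level`` optionally overrides the matching parameters at
    individual levels (finer levels need only a narrow search over a sparse
    grid, since the running field already captures the coarse deformation).
    """

    levels: list[int] = dc_field(default_factory=lambda: [2, 1, 0])
    aligners: dict = dc_field(default_factory=dict)
    blockmatch_params: BlockmatchParams = dc_field(default_factory=BlockmatchParams)
    blockmatch_per_level: dict = dc_field(default_factory=dict)
    finetune: dict = dc_field(default_factory=dict)


def _match_field_shape(F: DisplacementField, shape: tuple[int, int]) -> DisplacementField:
    """Crop or edge-pad a field to an exact grid shape (rounding slack only)."""
    u = F.u
    dr = shape[0] - u.shape[0]
    dc = shape[1] - u.shape[1]
    if dr < 0:
        u = u[: shape[0]]
    if dc < 0:
        u = u[:, : shape[1]]
    if dr > 0 or dc > 0:
        u = np.pad(u, ((0, max(dr, 0)), (0, max(dc, 0)), (0, 0)), mode="edge")
    return DisplacementField(u, F.resolution)


def align_pair_multiscale(src_pyr, tgt_pyr, cfg: MultiscaleConfig) -> DisplacementField:
    """Coarse-to-fine pair alignment over an image pyramid.

    Starts from a zero field at the coarsest configured level; at each level
    the running field (upsampled x2 between levels) pre-warps the source, the
    level aligner predicts a residual which is composed on, and the optional
    finetuner polishes the composite. Returns the finest-level field.
    """
    field: DisplacementField | None = None
    prev_level: int | None = None
    for level in cfg.levels:
        src_im = src_pyr.images[level]
        tgt_im = tgt_pyr.images[level]
        masks = src_pyr.masks[level] if src_pyr.masks else None
        try:
            if field is None:
                field = DisplacementField.zeros(src_im.shape, src_im.resolution)
            else:
                field = rescale_field(field, 2.0 ** (prev_level - level))
                field = _match_field_shape(field, src_im.shape)
                field.resolution = src_im.resolution
            warped_src = warp(src_im.pixels, field)
            aligner = cfg.aligners.get(level, "blockmatch")
            if aligner == "blockmatch":
                params = cfg.blockmatch_per_level.get(level, cfg.blockmatch_params)
                residual = blockmatch(
                    SectionImage(warped_src, src_im.resolution), tgt_im, params
                )
            elif aligner == "none":
                residual = DisplacementField.zeros(src_im.shape, src_im.resolution)
            else:
                enc_s = encode(SectionImage(warped_src, src_im.resolution), aligner)
                enc_t = encode(tgt_im, aligner)
                residual = predict_residual(enc_s, enc_t, aligner)
            field = compose(field, residual, extend="clamp")
            ft_cfg = cfg.finetune.get(level)
            if ft_cfg is not None:
                model = aligner if not isinstance(aligner, str) else None
                q_s = encode(src_im, model) if model else src_im.pixels[None]
                q_t = encode(tgt_im, model) if model else tgt_im.pixels[None]
                defect = masks.defect if masks is not None else None
                field = finetune_field(field, q_s, q_t, defect, ft_cfg)
        except Exception as exc:
            raise RuntimeError(f"pair alignment failed at pyramid level {level}: {exc}") from exc
        prev_level = level
    assert field is not None
    return field

# ---------------------------------------------------------------------------
# Two-stage self-supervised training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Two-stage training schedule and optimization hyperparameters.

    The production-scale schedule is 100 stage-1 epochs plus 500 stage-2
    epochs; desk-scale runs shrink both. gamma weighs the elastic
    regularizer; alpha_pre weighs the pre-alignment (best-sample) similarity
    in stage 2.
    """

    stage1_epochs: int = 100
    stage2_epochs: int = 500
    lr: float = 2e-3
    gamma: float = 15.0
    alpha_pre: float = 0.7
    chunk_size: int = 32
    k_percentile: float = 50.0
    enc_channels: int = 8
    hidden: int = 16
    seed: int = 0
    resolution: float = 1.0


def _pair_arrays(pair):
    """Normalize a dataset item to (src, tgt, defect_mask | None)."""
    if len(pair) == 2:
        s, t = pair
        d = None
    else:
        s, t, d = pair
    s = np.asarray(getattr(s, "pixels", s), dtype=np.float64)
    t = np.asarray(getattr(t, "pixels", t), dtype=np.float64)
    return s, t, d


def _stage1_graph(model: PairAlignerModel, s, t, defect_dil, cfg: TrainConfig):
    xs = ag.Tensor(s[None])
    xt = ag.Tensor(t[None])
    enc_s = model.encoder(xs)
    enc_t = model.encoder(xt)
    field = model.aligner(enc_s, enc_t)
    warped = ag.warp_op(xs, field)
    w_tissue = warped.data[0] != 0
    tst = w_tissue & (t != 0)
    n_t = tst.sum()
    sim = (
        ag.weighted_sum((warped - xt).square(), (tst / n_t)[None])
        if n_t
        else ag.Tensor(0.0)
    )
    vmask = w_tissue & ~defect_dil
    n_v = vmask.sum()
    loss = sim if n_v == 0 else sim + cfg.gamma * ag.elastic_energy(field, vmask / n_v)
    return loss


def _stage2_graph(model: PairAlignerModel, s, t, defect_dil, cfg: TrainConfig):
    xs = ag.Tensor(s[None])
    xt = ag.Tensor(t[None])
    enc_s = model.encoder(xs)
    enc_t = model.encoder(xt)
    field = model.aligner(enc_s, enc_t)
    warped_enc = ag.warp_op(enc_s, field)
    # tissue sets from the *images*, detached
    warped_img = ag.warp_op(xs, field).data[0]
    tst = (warped_img != 0) & (t != 0)
    n_t = tst.sum()
    C = enc_s.data.shape[0]
    if n_t:
        l_post = ag.weighted_sum(
            (warped_enc - enc_t).square(), np.broadcast_to(tst / n_t, (C, *tst.shape))
        )
    else:
        l_post = ag.Tensor(0.0)
    # best-sample chunk selection on detached post-alignment error
    post_err = ((warped_enc.data - enc_t.data) ** 2).sum(axis=0)
    lcfg = LossConfig(cfg.gamma, cfg.alpha_pre, cfg.chunk_size, cfg.k_percentile)
    try:
        chunks = select_best_sample_chunks(post_err, tst, lcfg)
    except ValueError:
        chunks = []
    if chunks:
        wpre = np.zeros(tst.shape)
        for sl in chunks:
            m = tst[sl]
            wpre[sl][m] = 1.0 / (len(chunks) * m.sum())
        l_pre = -1.0 * ag.weighted_sum(
            (enc_s - enc_t).square(), np.broadcast_to(wpre, (C, *wpre.shape))
        )
    else:
        l_pre = ag.Tensor(0.0)
    vmask = (warped_img != 0) & ~defect_dil
    n_v = vmask.sum()
    reg = ag.Tensor(0.0) if n_v == 0 else cfg.gamma * ag.elastic_energy(field, vmask / n_v)
    return cfg.alpha_pre * l_pre + l_post + reg


def train_pair_aligner(dataset, cfg: TrainConfig | None = None) -> PairAlignerModel:
    """Train an Encoder/Aligner pair on neighboring-section image pairs.

    Stage 1 minimizes the image-based loss (masked image MSE after warping
    plus the elastic regularizer); stage 2 switches the similarity terms to
    the encodings and adds the best-sample pre-alignment term. The run is
    fully deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    if not dataset:
        raise ValueError("train_pair_aligner: empty dataset")
    model = PairAlignerModel(
        resolution=cfg.resolution,
        enc_channels=cfg.enc_channels,
        hidden=cfg.hidden,
        seed=cfg.seed,
    )
    prepared = []
    for pair in dataset:
        s, t, d = _pair_arrays(pair)
        defect_dil = (
            ndimage.binary_dilation(np.asarray(d, bool), iterations=1)
            if d is not None
            else np.zeros(s.shape, bool)
        )
        prepared.append((s, t, defect_dil))
    opt = ag.Adam(model.params, lr=cfg.lr)
    for stage, n_epochs, graph_fn in (
        (1, cfg.stage1_epochs, _stage1_graph),
        (2, cfg.stage2_epochs, _stage2_graph),
    ):
        model.stage = stage
        for epoch in range(n_epochs):
            epoch_loss = 0.0
            for s, t, defect_dil in prepared:
                opt.zero_grad()
                loss = graph_fn(model, s, t, defect_dil, cfg)
                val = float(loss.data)
                if not np.isfinite(val):
                    raise RuntimeError(f"training diverged: non-finite stage-{stage} loss")
                loss.backward()
                opt.step()
                epoch_loss += val
            model.loss_history[f"stage{stage}"].append(epoch_loss / len(prepared))
            model.epoch = epoch + 1
    return model


def train_hierarchy(dataset, configs: list[TrainConfig]) -> list[PairAlignerModel]:
    """Train a coarse-to-fine sequence of Encoder/Aligner pairs.

    configs are ordered coarsest-first. After each level trains, its
    predicted fields are applied to the whole training dataset (sources
    pre-warped toward their targets) to produce the next level's training
    inputs, so finer levels only see residual deformations.
    """
    models: list[PairAlignerModel] = []
    current = [(_pair_arrays(p)) for p in dataset]
    for cfg in configs:
        pairs = [(s, t) if d is None else (s, t, d) for s, t, d in current]
        model = train_pair_aligner(pairs, cfg)
        models.append(model)
        processed = []
        for s, t, d in current:
            enc_s = encode(s, model)
            enc_t = encode(t, model)
            field = predict_residual(enc_s, enc_t, model)
            processed.append((warp(s, field).astype(np.float64), t, d))
        current = processed
    return models
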