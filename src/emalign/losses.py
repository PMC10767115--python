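"""Error maps, the elastic regularizer, and the two-stage training losses.

The aligner objective combines a masked similarity term with an elastic
regularizer. The similarity term is the masked mean of the pixel-wise squared
error between the warped source and the target, averaged over the
intersection of their tissue sets. The elastic term treats the field as a
spring mesh: each vertex connects to its forward neighbors at offsets
(0,1), (1,0), (1,1), and the per-vertex energy is the squared deviation of
the transformed edge length from its rest length,

    Omega(p) = sum_h (||F(p) - F(p+h)|| - ||h||)^2 .

Rigid translations leave every edge at rest length, so the regularizer is
exactly zero for them (gauge invariance). The regularizer is zeroed at
defect locations because cracks and folds legitimately require nonsmooth
transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import DisplacementField, warp
from .preprocess import masked_average, tissue_coords

# forward neighbor offsets (drow, dcol) of the spring mesh
_NEIGHBOR_OFFSETS = ((0, 1), (1, 0), (1, 1))


@dataclass
class LossConfig:
    """Hyperparameters of the alignment losses.

    gamma weighs the elastic regularizer against similarity (useful range
    5-25, larger at coarser resolutions); alpha_pre weighs the pre-alignment
    similarity in the stage-2 loss; chunk_size and k_percentile control the
    best-sample chunk selection.
    """

    gamma: float = 15.0
    alpha_pre: float = 0.7
    chunk_size: int = 32
    k_percentile: float = 50.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if not 0 < self.k_percentile <= 100:
            raise ValueError("k_percentile must be in (0, 100]")


def _pixels(image) -> np.ndarray:
    px = getattr(image, "pixels", image)
    return np.asarray(px)


def error_map(M1, M2) -> np.ndarray:
    """Pixel-wise squared error map ``E(p) = (M1(p) - M2(p))**2``.

    Multi-channel inputs of shape (C, rows, cols) are summed over channels.
    """
    a = _pixels(M1).astype(np.float64)
    b = _pixels(M2).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"error_map: shape mismatch {a.shape} vs {b.shape}")
    e = (a - b) ** 2
    if e.ndim == 3:
        e = e.sum(axis=0)
    return e


def elastic_energy_map(F: DisplacementField) -> np.ndarray:
    """Per-vertex spring energy of a field; off-grid neighbor terms skipped."""
    u = F.u.astype(np.float64)
    rows, cols = F.shape
    omega = np.zeros((rows, cols), dtype=np.float64)
    for dr, dc in _NEIGHBOR_OFFSETS:
        rest = float(np.hypot(dr, dc))
        # F(p) - F(p+h) = -h + u(p) - u(p+h)
        du = u[: rows - dr or None, : cols - dc or None] - u[dr:, dc:]
        dy = du[..., 0] - dr
        dx = du[..., 1] - dc
        term = (np.hypot(dy, dx) - rest) ** 2
        omega[: rows - dr or None, : cols - dc or None] += term
    return omega


def elastic_regularizer(
    F: DisplacementField,
    warped_source,
    defect_mask: np.ndarray | None = None,
) -> float:
    """Masked mean of elastic energies over tissue vertices of the warped source.

    Vertices under the defect mask (dilated by 1 px so edges straddling a
    crack or fold are also free) are excluded: nonsmooth transforms at
    discontinuities are not penalized. Returns 0 with a warning if no vertex
    survives the masking.
    """
    omega = elastic_energy_map(F)
    allowed = tissue_coords(warped_source)
    if defect_mask is not None:
        dil = ndimage.binary_dilation(np.asarray(defect_mask, bool), iterations=1)
        allowed = allowed & ~dil
    if not allowed.any():
        warnings.warn("elastic_regularizer: empty vertex set, returning 0", stacklevel=2)
        return 0.0
    return masked_average(omega, allowed)


def regularizer_vertex_mask(
    warped_source, defect_mask: np.ndarray | None
) -> np.ndarray:
    """The vertex set the elastic regularizer averages over (shared helper)."""
    allowed = tissue_coords(warped_source)
    if defect_mask is not None:
        dil = ndimage.binary_dilation(np.asarray(defect_mask, bool), iterations=1)
        allowed = allowed & ~dil
    return allowed


def stage1_loss(
    M_s,
    M_t,
    F: DisplacementField,
    cfg: LossConfig,
    defect_mask: np.ndarray | None = None,
) -> float:
    """Stage-1 objective: masked image MSE after warping plus gamma * L_er."""
    warped = warp(_pixels(M_s), F)
    tst = tissue_coords(warped) & tissue_coords(M_t)
    if tst.any():
        sim = masked_average(error_map(warped, _pixels(M_t)), tst)
    else:
        warnings.warn("stage1_loss: empty tissue intersection, similarity term 0", stacklevel=2)
        sim = 0.0
    return sim + cfg.gamma * elastic_regularizer(F, warped, defect_mask)


def _chunk_slices(shape: tuple[int, int], size: int):
    for r0 in range(0, shape[0], size):
        for c0 in range(0, shape[1], size):
            yield (slice(r0, min(r0 + size, shape[0])), slice(c0, min(c0 + size, shape[1])))


def select_best_sample_chunks(
    post_error: np.ndarray, tst: np.ndarray, cfg: LossConfig
) -> list[tuple[slice, slice]]:
    """Rank chunks by masked post-alignment error; keep the lowest k percent.

    Chunks with empty tissue intersection are skipped. Ties at the percentile
    boundary break by chunk raster order (stable sort). The lowest-error
    chunks are the feature-poor regions whose pre-alignment difference the
    stage-2 loss then pushes up.
    """
    scored: list[tuple[float, tuple[slice, slice]]] = []
    for sl in _chunk_slices(post_error.shape, cfg.chunk_size):
        m = tst[sl]
        if m.any():
            scored.append((float(post_error[sl][m].mean()), sl))
    if not scored:
        raise ValueError("best-sample selection: all chunks have empty tissue intersection")
    order = np.argsort([s for s, _ in scored], kind="stable")
    n_keep = max(1, int(np.ceil(cfg.k_percentile / 100.0 * len(scored))))
    return [scored[i][1] for i in order[:n_keep]]


def best_sample_pre_similarity(
    Q_s,
    Q_t,
    F: DisplacementField,
    cfg: LossConfig,
) -> float:
    """Pre-alignment similarity loss over the best-sample chunk set.

    Chunks are selected on the *post*-alignment masked error (bottom
    k-percentile, lowest error), then the returned value is minus the mean
    over selected chunks of the masked *pre*-alignment error of the unwarped
    encodings.
    """
    qs = _pixels(Q_s)
    qt = _pixels(Q_t)
    warped = warp(qs, F)
    tst = tissue_coords(warped) & tissue_coords(qt)
    post = error_map(warped, qt)
    chunks = select_best_sample_chunks(post, tst, cfg)
    pre = error_map(qs, qt)
    vals = []
    for sl in chunks:
        m = tst[sl]
        if m.any():
            vals.append(float(pre[sl][m].mean()))
    return -float(np.mean(vals)) if vals else 0.0


def stage2_loss(
    Q_s,
    Q_t,
    F: DisplacementField,
    cfg: LossConfig,
    defect_mask: np.ndarray | None = None,
    warped_source=None,
) -> float:
    """Stage-2 objective: alpha * L_pre + L_post + gamma * L_er.

    L_post is the masked post-alignment encoding MSE; the regularizer's
    tissue set defaults to the warped encoding itself unless a warped source
    image is supplied.
    """
    qs = _pixels(Q_s)
    qt = _pixels(Q_t)
    warped = warp(qs, F)
    tst = tissue_coords(warped) & tissue_coords(qt)
    if tst.any():
        l_post = masked_average(error_map(warped, qt), tst)
    else:
        warnings.warn("stage2_loss: empty tissue intersection, L_post = 0", stacklevel=2)
        l_post = 0.0
    l_pre = best_sample_pre_similarity(Q_s, Q_t, F, cfg)
    reg_source = warped_source if warped_source is not None else warped
    l_er = elastic_regularizer(F, reg_source, defect_mask)
    return cfg.alpha_pre * l_pre + l_post + cfg.gamma * l_er
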