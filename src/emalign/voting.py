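"""Vector voting: a pixel-wise smooth median over candidate displacement fields.

Given n candidate fields, all minimum-simple-majority subsets (size
m = floor(n/2 + 1)) are formed; each subset is scored per pixel by the mean
pairwise Euclidean distance between its member fields, a softmin over
subsets turns the scores into convex weights, and each subset's weight is
split evenly across its members. Subsets containing an outlier field score
large distances and receive exponentially small weight, so the result tracks
the consensus fields while remaining smooth in the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .fields import DisplacementField, blur_field, field_distance_map


@dataclass
class VotingConfig:
    """n candidate fields, softmin temperature T (px), optional pre-smoothing
    of the fields entering the distance computation (sigma in px, 0 = off)."""

    n: int = 3
    T: float = 5.7
    presmooth_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("voting n must be >= 1")
        if self.T <= 0:
            raise ValueError("softmin temperature must be > 0")


def majority_subsets(n: int) -> list[tuple[int, ...]]:
    """All subsets of {0..n-1} of size floor(n/2 + 1), lexicographic order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    m = n // 2 + 1
    return list(combinations(range(n), m))


def subset_distance_maps(
    fields: list[DisplacementField],
    subsets: list[tuple[int, ...]],
    presmooth_sigma: float = 0.0,
) -> list[np.ndarray]:
    """Per-subset mean pairwise displacement distance, per pixel.

    Singleton subsets (n = 1 voting) have no pairs and score 0 everywhere.
    Distances may be computed on spatially smoothed copies of the fields; the
    vote itself is always taken over the original fields.
    """
    shape = fields[0].shape
    for f in fields[1:]:
        if f.shape != shape:
            raise ValueError(f"subset_distance_maps: shape mismatch {f.shape} vs {shape}")
    if presmooth_sigma > 0:
        dist_fields = [blur_field(f, presmooth_sigma, "direct") for f in fields]
    else:
        dist_fields = fields
    maps = []
    for sub in subsets:
        pairs = list(combinations(sub, 2))
        if not pairs:
            maps.append(np.zeros(shape, dtype=np.float64))
            continue
        acc = np.zeros(shape, dtype=np.float64)
        for i, j in pairs:
            acc += field_distance_map(dist_fields[i], dist_fields[j])
        maps.append(acc / len(pairs))
    return maps


def softmin_weights(distance_maps: list[np.ndarray], T: float) -> np.ndarray:
    """Per-pixel softmin over subsets: w_k = exp(-D_k/T) / sum_j exp(-D_j/T).

    Stabilized by subtracting the per-pixel minimum distance. Returns an
    array of shape (n_subsets, rows, cols) that sums to 1 over axis 0.
    """
    if T <= 0:
        raise ValueError("softmin temperature must be > 0")
    D = np.stack(distance_maps).astype(np.float64)
    D -= D.min(axis=0, keepdims=True)
    w = np.exp(-D / T)
    return w / w.sum(axis=0, keepdims=True)


def vote(fields: list[DisplacementField], cfg: VotingConfig | None = None) -> DisplacementField:
    """Smooth median of candidate fields.

    Each subset's softmin coefficient is split evenly across its m member
    fields; the output displacement at every pixel is a convex combination of
    the input displacements there.
    """
    if not fields:
        raise ValueError("vote: empty field list")
    cfg = cfg or VotingConfig(n=len(fields))
    if len(fields) != cfg.n:
        cfg = VotingConfig(n=len(fields), T=cfg.T, presmooth_sigma=cfg.presmooth_sigma)
    if cfg.n == 1:
        return fields[0].copy()
    subsets = majority_subsets(cfg.n)
    m = cfg.n // 2 + 1
    dmaps = subset_distance_maps(fields, subsets, cfg.presmooth_sigma)
    w = softmin_weights(dmaps, cfg.T)
    out = np.zeros_like(fields[0].u, dtype=np.float64)
    for k, sub in enumerate(subsets):
        coeff = (w[k] / m)[..., None]
        for i in sub:
            out += coeff * fields[i].u
    return DisplacementField(out.astype(np.float32), fields[0].resolution)
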