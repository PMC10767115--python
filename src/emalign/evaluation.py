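"""Chunked Pearson Correlation (CPC) quality metric and proofreading sampling.

Neighboring aligned sections are divided into non-overlapping square chunks
(default 64 px, matching 2048 nm at 32 nm/px) and the Pearson correlation of
each chunk is computed over pixels where both images are nonzero. High CPC
marks well-aligned chunks; low CPC flags potential misalignments (or natural
content change / artifacts — hence the seeded sampling support for manual
review). Non-tissue chunks, chunks touched by a defect mask, chunks with
less than half their pixels jointly valid, and zero-variance chunks are
excluded from all statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import MaskSet, SectionImage


@dataclass
class CPCMap:
    """Per-chunk correlation grid; NaN marks invalid chunks."""

    values: np.ndarray
    chunk_size: int
    resolution: float = 1.0
    section_index: int = 0

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class CPCSummary:
    """Pooled CPC statistics over a list of maps."""

    percentiles: np.ndarray  # shape (101,), value at each percentile 0..100
    fraction_below: float
    threshold: float
    n_valid: int
    n_excluded: int


def cpc(
    img1: SectionImage | np.ndarray,
    img2: SectionImage | np.ndarray,
    chunk_size: int = 64,
    masks: MaskSet | None = None,
) -> CPCMap:
    """Per-chunk Pearson correlation between two neighboring sections.

    The chunk grid is anchored at (0, 0); partial edge chunks are excluded.
    A chunk is invalid when it contains any defect-mask pixel, when fewer
    than half its pixels are nonzero in both images, or when either image
    has zero variance over the jointly valid pixels.
    """
    a = np.asarray(getattr(img1, "pixels", img1), dtype=np.float64)
    b = np.asarray(getattr(img2, "pixels", img2), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"cpc: shape mismatch {a.shape} vs {b.shape}")
    H, W = a.shape
    nr, nc = H // chunk_size, W // chunk_size
    values = np.full((nr, nc), np.nan)
    defect = masks.defect if masks is not None else None
    for i in range(nr):
        for j in range(nc):
            sl = (
                slice(i * chunk_size, (i + 1) * chunk_size),
                slice(j * chunk_size, (j + 1) * chunk_size),
            )
            if defect is not None and defect[sl].any():
                continue
            ca, cb = a[sl], b[sl]
            m = (ca != 0) & (cb != 0)
            if m.sum() < 0.5 * chunk_size * chunk_size:
                continue
            x, y = ca[m], cb[m]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                continue
            values[i, j] = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    res = getattr(img1, "resolution", 1.0)
    z = getattr(img1, "section_index", 0)
    return CPCMap(values, chunk_size, res, z)


def cpc_summary(maps: list[CPCMap], threshold: float = 0.25) -> CPCSummary:
    """Pooled percentile curve and low-CPC fraction over valid chunks."""
    vals = np.concatenate([m.values[m.valid] for m in maps]) if maps else np.array([])
    n_excluded = int(sum((~m.valid).sum() for m in maps))
    if vals.size == 0:
        raise ValueError("cpc_summary: no valid chunks")
    pct = np.percentile(vals, np.arange(101))
    frac = float((vals < threshold).mean())
    return CPCSummary(pct, frac, threshold, int(vals.size), n_excluded)


def sample_low_cpc(
    maps: list[CPCMap], threshold: float = 0.25, count: int = 300, seed: int = 0
) -> list[tuple[int, int, int]]:
    """Seeded uniform sample (without replacement) of low-CPC chunk locations.

    Returns (section_index, chunk_row, chunk_col) triples; if fewer than
    ``count`` chunks qualify, all are returned (in sampling order).
    """
    qualifying = []
    for m in maps:
        idx = np.argwhere(m.valid & (m.values < threshold))
        qualifying.extend((m.section_index, int(r), int(c)) for r, c in idx)
    rng = np.random.default_rng(seed)
    if len(qualifying) <= count:
        order = rng.permutation(len(qualifying))
        return [qualifying[i] for i in order]
    chosen = rng.choice(len(qualifying), size=count, replace=False)
    return [qualifying[i] for i in chosen]


def save_cpc_maps(path, maps: list[CPCMap]) -> None:
    """CPC maps as HDF5: one dataset per section, NaN marking invalid chunks."""
    import h5py

    with h5py.File(path, "w") as f:
        for m in maps:
            ds = f.create_dataset(f"z{m.section_index:05d}", data=m.values)
            ds.attrs["chunk_size"] = m.chunk_size
            ds.attrs["resolution_nm"] = m.resolution


def save_cpc_heatmap(path, cpc_map: CPCMap) -> None:
    """Render one CPC map as a heatmap PNG (invalid chunks in black)."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError("heatmap rendering requires matplotlib (plot extra)") from exc
    fig, ax = plt.subplots(figsize=(6, 6))
    masked = np.ma.masked_invalid(cpc_map.values)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    im = ax.imshow(masked, vmin=-1, vmax=1, cmap=cmap)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title(f"CPC, section {cpc_map.section_index}")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def save_low_cpc_samples(path, samples, seed: int) -> None:
    """Sampled low-CPC locations as CSV with the sampling seed recorded."""
    lines = [f"# seed={seed}", "section,chunk_row,chunk_col"]
    lines += [f"{z},{r},{c}" for z, r, c in samples]
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")
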