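"""Section preprocessing: resolution hierarchy, mask burn-in, normalization.

Sections are single-channel float images in which the value 0 is reserved for
non-tissue: resin, empty space, and masked defects. The preprocessing contract
is (1) build a pyramid of resolutions by 2x2 average pooling, (2) zero out
pixels under the defect mask or outside the tissue mask, and (3) normalize
each section to zero mean / unit variance computed over its nonzero pixels
only, leaving zero pixels exactly zero.

Masks pool in the conservative direction when downsampled: defect masks by
max pooling (defects never shrink) and tissue masks by min pooling (non-tissue
never shrinks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np


@dataclass
class SectionImage:
    """Normalized grayscale section; non-tissue pixels are exactly 0."""

    pixels: np.ndarray
    resolution: float = 1.0
    section_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError(f"section image must be 2D, got shape {self.pixels.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class MaskSet:
    """Binary defect (cracks + folds) and tissue masks at one resolution."""

    defect: np.ndarray
    tissue: np.ndarray
    resolution: float = 1.0

    def __post_init__(self) -> None:
        self.defect = np.asarray(self.defect).astype(bool)
        self.tissue = np.asarray(self.tissue).astype(bool)
        if self.defect.shape != self.tissue.shape:
            raise ValueError(
                f"defect/tissue mask shape mismatch {self.defect.shape} vs {self.tissue.shape}"
            )

    @classmethod
    def trivial(cls, shape: tuple[int, int], resolution: float = 1.0) -> "MaskSet":
        """No defects, all tissue."""
        return cls(np.zeros(shape, bool), np.ones(shape, bool), resolution)


@dataclass
class ImagePyramid:
    """Per-resolution SectionImage + MaskSet, resolutions doubling upward."""

    images: list[SectionImage] = dc_field(default_factory=list)
    masks: list[MaskSet] = dc_field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)


_POOL_ROLES = ("image", "defect_mask", "tissue_mask")


def _pool2x2(grid: np.ndarray, role: str) -> np.ndarray:
    """One 2x2 stride-2 pooling step with role-appropriate reduction.

    Odd dims are padded so the reduction direction is preserved: images by
    edge replication, defect masks by 0 (defect-free) and tissue masks by 1
    (tissue), neutral values for max- and min-pooling respectively.
    """
    r, c = grid.shape
    pr, pc = r % 2, c % 2
    if pr or pc:
        if role == "image":
            grid = np.pad(grid, ((0, pr), (0, pc)), mode="edge")
        elif role == "defect_mask":
            grid = np.pad(grid, ((0, pr), (0, pc)), constant_values=0)
        else:
            grid = np.pad(grid, ((0, pr), (0, pc)), constant_values=1)
        r, c = grid.shape
    blocks = grid.reshape(r // 2, 2, c // 2, 2)
    if role == "image":
        return blocks.mean(axis=(1, 3))
    if role == "defect_mask":
        return blocks.max(axis=(1, 3))
    return blocks.min(axis=(1, 3))


def downsample(grid: np.ndarray, levels: int, role: str = "image") -> list[np.ndarray]:
    """Pyramid of ``levels + 1`` grids: the input plus ``levels`` poolings.

    Images are average-pooled; defect masks max-pooled (overestimating
    defects); tissue masks min-pooled (overestimating non-tissue).
    """
    if role not in _POOL_ROLES:
        raise ValueError(f"unknown grid role {role!r}; expected one of {_POOL_ROLES}")
    grid = np.asarray(grid)
    out = [grid]
    for _ in range(levels):
        out.append(_pool2x2(out[-1], role))
    return out


def zero_masked(image: SectionImage, masks: MaskSet) -> SectionImage:
    """Zero out pixels under the defect mask or outside the tissue mask."""
    if image.shape != masks.defect.shape:
        raise ValueError(
            f"image/mask shape mismatch {image.shape} vs {masks.defect.shape}"
        )
    px = image.pixels.copy()
    px[masks.defect | ~masks.tissue] = 0.0
    return SectionImage(px, image.resolution, image.section_index)


def normalize_nonzero(image: SectionImage) -> SectionImage:
    """Zero-mean / unit-variance normalization over nonzero pixels only.

    Zero-valued pixels (empty space and masked regions) are ignored by the
    statistics and remain exactly zero afterwards. Population (1/N) variance.
    """
    px = image.pixels
    nz = px != 0
    if not nz.any():
        warnings.warn("normalize_nonzero: all-zero image returned unchanged", stacklevel=2)
        return SectionImage(px.copy(), image.resolution, image.section_index)
    vals = px[nz].astype(np.float64)
    mean = vals.mean()
    std = vals.std()  # population
    if std == 0:
        raise ValueError("normalize_nonzero: nonzero pixels have zero variance")
    out = np.zeros_like(px)
    out[nz] = ((vals - mean) / std).astype(np.float32)
    return SectionImage(out, image.resolution, image.section_index)


def tissue_coords(image: SectionImage | np.ndarray) -> np.ndarray:
    """Boolean indicator of nonzero (tissue) pixels.

    Intersections of tissue sets (e.g. warped source with target) are plain
    logical ANDs of these maps.
    """
    px = image.pixels if isinstance(image, SectionImage) else np.asarray(image)
    if px.ndim == 3:  # multi-channel encoding: tissue where any channel nonzero
        return np.any(px != 0, axis=0)
    return px != 0


def masked_average(K: np.ndarray, P: np.ndarray) -> float:
    """Mean of a scalar map over the pixels selected by a binary map."""
    P = np.asarray(P, dtype=bool)
    if K.shape != P.shape:
        raise ValueError(f"masked_average: shape mismatch {K.shape} vs {P.shape}")
    n = int(P.sum())
    if n == 0:
        raise ValueError("masked_average: empty coordinate set")
    return float(np.asarray(K, dtype=np.float64)[P].sum() / n)


def build_pyramid(
    image: SectionImage, masks: MaskSet | None, levels: int
) -> ImagePyramid:
    """Mask, pool, and normalize a section into a multi-resolution hierarchy.

    At every level the masks are burned in (pixels zeroed) before per-level
    nonzero normalization, matching the order of the preprocessing contract.
    """
    if masks is None:
        masks = MaskSet.trivial(image.shape, image.resolution)
    imgs = downsample(image.pixels, levels, "image")
    defs = downsample(masks.defect, levels, "defect_mask")
    tiss = downsample(masks.tissue, levels, "tissue_mask")
    pyr = ImagePyramid()
    for lvl, (im, de, ti) in enumerate(zip(imgs, defs, tiss)):
        res = image.resolution * 2**lvl
        ms = MaskSet(de, ti, res)
        sec = zero_masked(SectionImage(im, res, image.section_index), ms)
        if (sec.pixels != 0).any() and sec.pixels[sec.pixels != 0].std() > 0:
            sec = normalize_nonzero(sec)
        pyr.images.append(sec)
        pyr.masks.append(ms)
    return pyr
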