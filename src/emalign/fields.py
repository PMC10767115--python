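"""Dense displacement-field algebra.

A displacement field assigns a 2D pixel-unit displacement ``u(r)`` to every
pixel ``r`` of a section grid; the full transform is ``F(r) = r + u(r)``.
Fields are *pull* transforms: when an image is warped by a field, the output
pixel at ``r`` samples the input at ``r + u(r)`` with bilinear interpolation.
Samples falling outside the grid evaluate to 0, the value that encodes
non-tissue throughout the pipeline.

Coordinates are row/column, 0-based, origin at the top-left corner.
Displacement components are stored as ``u[..., 0] = drow``,
``u[..., 1] = dcol``, in pixels at the field's native resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage


@dataclass
class DisplacementField:
    """Dense 2D displacement field on a regular pixel grid.

    Parameters
    ----------
    u : ndarray, shape (rows, cols, 2)
        Per-pixel displacements in pixels; ``u[..., 0]`` is the row
        component, ``u[..., 1]`` the column component.
    resolution : float
        Physical pixel size in nm/px. Purely descriptive metadata; all
        arithmetic is in pixel units.
    """

    u: np.ndarray
    resolution: float = 1.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float32)
        if self.u.ndim != 3 or self.u.shape[-1] != 2:
            raise ValueError(f"field array must have shape (rows, cols, 2), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[:2]

    @classmethod
    def zeros(cls, shape: tuple[int, int], resolution: float = 1.0) -> "DisplacementField":
        return cls(np.zeros((*shape, 2), dtype=np.float32), resolution)

    @classmethod
    def constant(cls, shape: tuple[int, int], vec, resolution: float = 1.0) -> "DisplacementField":
        u = np.empty((*shape, 2), dtype=np.float32)
        u[...] = np.asarray(vec, dtype=np.float32)
        return cls(u, resolution)

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.u.copy(), self.resolution)

    def magnitude(self) -> np.ndarray:
        """Per-pixel Euclidean norm of the displacement, in pixels."""
        return np.hypot(self.u[..., 0], self.u[..., 1])


@dataclass
class FieldPyramid:
    """MIP hierarchy of a field built with an iterative 2x2 box filter.

    Level 0 is the base field; level ``l`` has grid dims
    ``ceil(base dims / 2**l)``. Displacement values stay in base-resolution
    pixel units at every level — only the grid is decimated.
    """

    levels: list[DisplacementField] = dc_field(default_factory=list)
    base_resolution: float = 1.0


def _check_same_shape(a_shape, b_shape, what: str) -> None:
    if tuple(a_shape) != tuple(b_shape):
        raise ValueError(f"{what}: shape mismatch {tuple(a_shape)} vs {tuple(b_shape)}")


def _sample_grid(arr: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear sample of a 2D array at fractional (row, col) positions.

    Out-of-grid samples evaluate to 0.
    """
    return ndimage.map_coordinates(
        arr, [rows, cols], order=1, mode="constant", cval=0.0, prefilter=False
    )


def warp(image: np.ndarray, field: DisplacementField) -> np.ndarray:
    """Transform an image by a displacement field.

    ``out(r) = image(r + u(r))`` with bilinear interpolation; samples outside
    the grid yield 0 (the non-tissue value). Multi-channel images with shape
    (C, rows, cols) are warped channel-wise by the same field.
    """
    image = np.asarray(image)
    spatial = image.shape[-2:]
    _check_same_shape(spatial, field.shape, "warp(image, field)")
    rr, cc = np.meshgrid(
        np.arange(spatial[0], dtype=np.float32),
        np.arange(spatial[1], dtype=np.float32),
        indexing="ij",
    )
    rows = rr + field.u[..., 0]
    cols = cc + field.u[..., 1]
    if image.ndim == 2:
        return _sample_grid(image, rows, cols).astype(image.dtype, copy=False)
    out = np.stack([_sample_grid(ch, rows, cols) for ch in image])
    return out.astype(image.dtype, copy=False)


def compose(A: DisplacementField, B: DisplacementField, extend: str = "zero") -> DisplacementField:
    """Compose two fields: ``(A o B)(r) = r + b(r) + a(r + b(r))``.

    ``a`` is sampled bilinearly at ``r + b(r)``. With ``extend="zero"``
    (the default, matching image warping) out-of-grid samples of ``a``
    contribute zero displacement; ``extend="clamp"`` edge-clamps instead,
    which analysis paths (pair-preservation checks on fields with large
    accumulated drift) use to avoid artificial boundary bands.
    """
    _check_same_shape(A.shape, B.shape, "compose(A, B)")
    rr, cc = np.meshgrid(
        np.arange(A.shape[0], dtype=np.float32),
        np.arange(A.shape[1], dtype=np.float32),
        indexing="ij",
    )
    rows = rr + B.u[..., 0]
    cols = cc + B.u[..., 1]
    mode = {"zero": "constant", "clamp": "nearest"}[extend]
    a_at = np.stack(
        [
            ndimage.map_coordinates(A.u[..., k], [rows, cols], order=1, mode=mode, cval=0.0, prefilter=False)
            for k in range(2)
        ],
        axis=-1,
    )
    return DisplacementField(B.u + a_at, B.resolution)


def invert(
    F: DisplacementField, tol: float = 1e-2, max_iter: int = 200, check: bool = True
) -> DisplacementField:
    """Invert a displacement field by fixed-point iteration.

    Solves ``V(r) = -U(r + V(r))`` starting from ``V = -U``. During the
    iteration ``U`` is sampled with edge clamping (the natural extension of
    a field defined on the whole grid), so e.g. constant fields invert
    exactly everywhere. Convergence is the fixed-point residual
    ``max ||V + U(r + V)|| <= tol``; for fields that vanish toward the
    boundary this equals the ``compose(F, invert(F))`` residual.

    With ``check=False`` no convergence error is raised: the fixed point is
    pointwise, so fields that are non-invertible only inside masked defect
    bands still invert correctly everywhere else, and analysis paths that
    mask those bands can use the best iterate.
    """
    rr, cc = np.meshgrid(
        np.arange(F.shape[0], dtype=np.float32),
        np.arange(F.shape[1], dtype=np.float32),
        indexing="ij",
    )

    def u_at(v):
        rows = rr + v[..., 0]
        cols = cc + v[..., 1]
        return np.stack(
            [
                ndimage.map_coordinates(F.u[..., k], [rows, cols], order=1, mode="nearest", prefilter=False)
                for k in range(2)
            ],
            axis=-1,
        )

    v = -F.u.copy()
    residual = np.inf
    for _ in range(max_iter):
        fp = v + u_at(v)  # fixed-point residual; the next iterate is v - fp
        residual = float(np.hypot(fp[..., 0], fp[..., 1]).max())
        if residual <= tol:
            break
        v = v - fp
    if check and residual > tol:
        raise RuntimeError(
            f"field inversion did not converge: residual {residual:.3g} px > tol {tol:g} px "
            f"after {max_iter} iterations"
        )
    return DisplacementField(v, F.resolution)


def rescale_field(F: DisplacementField, factor: float) -> DisplacementField:
    """Resample a field's grid by ``factor`` and scale displacements to match.

    The new grid has ``round(dim * factor)`` pixels per axis; values are
    sampled bilinearly at source coordinates ``i / factor`` (edge-clamped) and
    displacement values are multiplied by ``factor`` so they remain in pixel
    units of the new grid. The stated resolution divides by ``factor``.
    """
    if factor <= 0:
        raise ValueError(f"rescale factor must be positive, got {factor}")
    rows_out = max(1, int(round(F.shape[0] * factor)))
    cols_out = max(1, int(round(F.shape[1] * factor)))
    rr, cc = np.meshgrid(
        np.arange(rows_out, dtype=np.float32) / factor,
        np.arange(cols_out, dtype=np.float32) / factor,
        indexing="ij",
    )
    comps = [
        ndimage.map_coordinates(F.u[..., k], [rr, cc], order=1, mode="nearest", prefilter=False)
        for k in range(2)
    ]
    u = np.stack(comps, axis=-1) * factor
    return DisplacementField(u.astype(np.float32), F.resolution / factor)


def _box_decimate(plane: np.ndarray) -> np.ndarray:
    """One 2x2 box-filter + decimate step; odd dims are edge-padded."""
    r, c = plane.shape
    if r % 2 or c % 2:
        plane = np.pad(plane, ((0, r % 2), (0, c % 2)), mode="edge")
        r, c = plane.shape
    return plane.reshape(r // 2, 2, c // 2, 2).mean(axis=(1, 3))


def build_mip(F: DisplacementField, levels: int) -> FieldPyramid:
    """Build a MIP pyramid of a field with an iterative 2x2 box filter.

    Level 0 is ``F`` itself; each subsequent level halves the grid extent.
    Displacement values are averaged, not rescaled: they stay in
    base-resolution pixel units.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    max_levels = int(np.floor(np.log2(min(F.shape)))) + 1
    if levels > max_levels:
        raise ValueError(
            f"levels={levels} exceeds log2(min dim) for shape {F.shape} (max {max_levels})"
        )
    pyramid = FieldPyramid(levels=[F], base_resolution=F.resolution)
    for lvl in range(1, levels):
        prev = pyramid.levels[-1].u
        u = np.stack([_box_decimate(prev[..., k]) for k in range(2)], axis=-1)
        pyramid.levels.append(
            DisplacementField(u.astype(np.float32), F.resolution * 2**lvl)
        )
    return pyramid


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    """Sampled, renormalized 1D Gaussian truncated at radius ceil(3*sigma).

    The radius is never smaller than 1, so every kernel has at least three
    taps; sigma == 0 yields the discrete delta [0, 1, 0].
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    radius = max(1, int(np.ceil(3.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    if sigma == 0:
        k = (x == 0).astype(np.float64)
    else:
        k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _blur_plane(plane: np.ndarray, sigma: float) -> np.ndarray:
    k = gaussian_kernel_1d(sigma)
    out = ndimage.correlate1d(plane.astype(np.float64), k, axis=0, mode="nearest")
    out = ndimage.correlate1d(out, k, axis=1, mode="nearest")
    return out


def _upsample_plane_to(plane: np.ndarray, shape: tuple[int, int], level: int) -> np.ndarray:
    """Bilinearly upsample a MIP level plane back onto the base grid."""
    scale = 2.0**level
    rr, cc = np.meshgrid(
        np.arange(shape[0], dtype=np.float64) / scale,
        np.arange(shape[1], dtype=np.float64) / scale,
        indexing="ij",
    )
    return ndimage.map_coordinates(plane, [rr, cc], order=1, mode="nearest", prefilter=False)


def blur_field(F: DisplacementField, sigma: float, method: str = "direct") -> DisplacementField:
    """Blur each displacement component with a normalized Gaussian of std ``sigma``.

    ``method="direct"`` convolves with the truncated, renormalized kernel
    (edge replication at the boundary, so constant fields are fixed points).
    ``method="mip"`` approximates the variable-sigma blur by trilinear
    interpolation within a 2x2 box-filter MIP hierarchy of the field: the
    fractional level is ``log2(max(sigma, 1))`` and the two bracketing levels
    are upsampled to the base grid and linearly mixed.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return F.copy()
    if method == "direct":
        u = np.stack([_blur_plane(F.u[..., k], sigma) for k in range(2)], axis=-1)
        return DisplacementField(u.astype(np.float32), F.resolution)
    if method == "mip":
        frac_level = float(np.log2(max(sigma, 1.0)))
        lo = int(np.floor(frac_level))
        hi = int(np.ceil(frac_level))
        max_levels = int(np.floor(np.log2(min(F.shape)))) + 1
        lo = min(lo, max_levels - 1)
        hi = min(hi, max_levels - 1)
        t = frac_level - np.floor(frac_level) if hi > lo else 0.0
        pyr = build_mip(F, max(lo, hi) + 1)
        comps = []
        for k in range(2):
            p_lo = _upsample_plane_to(pyr.levels[lo].u[..., k], F.shape, lo)
            if hi > lo:
                p_hi = _upsample_plane_to(pyr.levels[hi].u[..., k], F.shape, hi)
                comps.append((1.0 - t) * p_lo + t * p_hi)
            else:
                comps.append(p_lo)
        u = np.stack(comps, axis=-1)
        return DisplacementField(u.astype(np.float32), F.resolution)
    raise ValueError(f"unknown blur method {method!r}; expected 'direct' or 'mip'")


def field_distance_map(A: DisplacementField, B: DisplacementField) -> np.ndarray:
    """Per-pixel Euclidean norm of the displacement difference ||u_A - u_B||."""
    _check_same_shape(A.shape, B.shape, "field_distance_map(A, B)")
    d = A.u.astype(np.float64) - B.u.astype(np.float64)
    return np.hypot(d[..., 0], d[..., 1])
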