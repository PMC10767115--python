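"""Serialization: fields and stacks as HDF5, sections and masks as TIFF.

Fields are stored as rows x cols x 2 float datasets with ``resolution_nm``
and ``units="px"`` attributes. Stacks are multi-page TIFF (one page per
section) or a single z x rows x cols HDF5 dataset; masks are 8-bit 0/1.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .fields import DisplacementField
from .preprocess import MaskSet, SectionImage


def save_field(path, field: DisplacementField, name: str = "field") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        ds = f.create_dataset(name, data=field.u)
        ds.attrs["resolution_nm"] = field.resolution
        ds.attrs["units"] = "px"


def load_field(path, name: str = "field") -> DisplacementField:
    with h5py.File(path, "r") as f:
        ds = f[name]
        return DisplacementField(ds[...], float(ds.attrs.get("resolution_nm", 1.0)))


def save_fields(path, fields: dict[int, DisplacementField]) -> None:
    """Per-section fields of an alignment, one dataset per section index."""
    with h5py.File(path, "w") as f:
        for z, fld in fields.items():
            ds = f.create_dataset(f"z{z:05d}", data=fld.u)
            ds.attrs["resolution_nm"] = fld.resolution
            ds.attrs["units"] = "px"
            ds.attrs["z"] = z


def load_fields(path) -> dict[int, DisplacementField]:
    out = {}
    with h5py.File(path, "r") as f:
        for name in f:
            ds = f[name]
            out[int(ds.attrs["z"])] = DisplacementField(
                ds[...], float(ds.attrs.get("resolution_nm", 1.0))
            )
    return out


def save_stack_tiff(path, sections: list[SectionImage]) -> None:
    tifffile.imwrite(path, np.stack([s.pixels for s in sections]).astype(np.float32), photometric="minisblack")


def load_stack_tiff(path, resolution: float = 1.0) -> list[SectionImage]:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return [SectionImage(page.astype(np.float32), resolution, z) for z, page in enumerate(data)]


def save_stack_h5(path, sections: list[SectionImage], dataset: str = "stack") -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset(dataset, data=np.stack([s.pixels for s in sections]).astype(np.float32))
        ds.attrs["resolution_nm"] = sections[0].resolution if sections else 1.0


def load_stack_h5(path, dataset: str = "stack") -> list[SectionImage]:
    with h5py.File(path, "r") as f:
        ds = f[dataset]
        res = float(ds.attrs.get("resolution_nm", 1.0))
        return [SectionImage(page.astype(np.float32), res, z) for z, page in enumerate(ds[...])]


def save_masks_tiff(path, masks: list[MaskSet], which: str = "defect") -> None:
    planes = [getattr(m, which).astype(np.uint8) for m in masks]
    tifffile.imwrite(path, np.stack(planes), photometric="minisblack")


def load_masks_tiff(defect_path=None, tissue_path=None, resolution: float = 1.0) -> list[MaskSet]:
    defect = tifffile.imread(defect_path) if defect_path else None
    tissue = tifffile.imread(tissue_path) if tissue_path else None
    if defect is None and tissue is None:
        raise ValueError("need at least one of defect/tissue mask paths")
    n = len(defect) if defect is not None else len(tissue)
    shape = (defect if defect is not None else tissue).shape[1:]
    out = []
    for z in range(n):
        d = defect[z] > 0 if defect is not None else np.zeros(shape, bool)
        t = tissue[z] > 0 if tissue is not None else np.ones(shape, bool)
        out.append(MaskSet(d, t, resolution))
    return out


def ensure_parent(path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
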