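"""NIfTI volume I/O with JSON sidecars.

All volumes in this package live on axis-aligned grids, so the affine is a
diagonal voxel-size matrix unless a full affine is supplied.  Arrays are
written as float32 (masks as uint8); numerical work upstream is float64.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_nifti", "load_nifti", "sidecar_path"]


def sidecar_path(path: str | Path) -> Path:
    """JSON sidecar path for a ``.nii`` / ``.nii.gz`` volume."""
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_nifti(
    path: str | Path,
    data: np.ndarray,
    *,
    voxel_size_mm: tuple[float, float, float] | None = None,
    affine: np.ndarray | None = None,
    dtype: np.dtype | type = np.float32,
    sidecar: dict | None = None,
) -> None:
    """Write ``data`` as NIfTI; grid geometry from ``affine`` or ``voxel_size_mm``."""
    if affine is None:
        if voxel_size_mm is None:
            raise ValueError("either affine or voxel_size_mm is required")
        affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    if sidecar is not None:
        sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[float, ...], dict | None]:
    """Read a NIfTI volume.

    Returns ``(data, affine, voxel_size_mm, sidecar)``; the sidecar is ``None``
    when no JSON file sits next to the volume.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    affine = np.asarray(img.affine, dtype=float)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    sc_path = sidecar_path(path)
    sidecar = json.loads(sc_path.read_text()) if sc_path.exists() else None
    return data, affine, voxel, sidecar
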