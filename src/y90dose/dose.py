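"""Absorbed-dose computation: kernel convolution and dose-map I/O.

The voxel dose is the discrete linear convolution of the cumulated activity
with the dose voxel kernel,

.. math::

    D(x,y,z) = \\frac{1}{\\lambda}\\sum_{x'}\\sum_{y'}\\sum_{z'}
        A(x',y',z')\\,\\mathrm{DVK}(x-x', y-y', z-z'),

evaluated in the frequency domain with zero padding (no circular wrap), so
activity outside the head contributes nothing and dose carried beyond the
image is discarded but tallied.  A brute-force triple-loop direct sum is
provided as an independent validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

from .activity import ActivityMap, cumulated_activity
from .kernel import DoseVoxelKernel

__all__ = ["DoseMap", "convolve_dose", "direct_convolve_dose", "export_dose", "load_dose"]


@dataclass
class DoseMap:
    """3-D absorbed dose (Gy) with grid and fractionation metadata."""

    voxel_dose_gy: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    source: str  # "convolution" | "vmat_surrogate"
    n_fractions: int = 1
    dose_per_fraction_gy: float | None = None
    affine: np.ndarray | None = None
    escaped_dose_gy_cm3: float = 0.0  # dose-volume integral lost past the image edge

    def __post_init__(self) -> None:
        if np.any(self.voxel_dose_gy < 0):
            raise ValueError("dose must be non-negative")
        if self.source not in ("convolution", "vmat_surrogate"):
            raise ValueError("unknown dose source")

    def scaled(self, factor: float) -> "DoseMap":
        """Linearly rescaled dose map (physical dose is linear in activity)."""
        return DoseMap(
            voxel_dose_gy=self.voxel_dose_gy * factor,
            voxel_size_mm=self.voxel_size_mm,
            source=self.source,
            n_fractions=self.n_fractions,
            dose_per_fraction_gy=self.dose_per_fraction_gy,
            affine=self.affine,
            escaped_dose_gy_cm3=self.escaped_dose_gy_cm3 * factor,
        )

    def mean_dose_gy(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        return float(self.voxel_dose_gy[mask].mean())


def _check_grids_match(activity: ActivityMap, kernel: DoseVoxelKernel) -> None:
    a = np.asarray(activity.voxel_size_mm, dtype=float)
    k = np.asarray(kernel.grid.voxel_size_mm, dtype=float)
    if not np.allclose(a, k, rtol=1e-9, atol=1e-9):
        raise ValueError(
            f"kernel voxel size {tuple(k)} does not match activity grid {tuple(a)}; "
            "regenerate the kernel on the activity grid (resampling is refused)"
        )
    if any(ks > 2 * s - 1 for ks, s in zip(kernel.grid.shape, activity.voxel_activity_mbq.shape)):
        raise ValueError("kernel larger than the padded image grid")


def convolve_dose(activity: ActivityMap, kernel: DoseVoxelKernel) -> DoseMap:
    """Convolve cumulated activity with the kernel; output in Gy.

    Frequency-domain linear convolution with zero padding; tiny negative
    round-off values are clipped to zero.  Dose deposited outside the image
    extent is tallied in ``escaped_dose_gy_cm3``.
    """
    _check_grids_match(activity, kernel)
    a_cum = cumulated_activity(activity)  # MBq·s
    if not np.all(np.isfinite(a_cum)) or not np.all(np.isfinite(kernel.values)):
        raise ValueError("non-finite values in activity or kernel")
    full = fftconvolve(a_cum, kernel.values, mode="full") * 1e-3  # mGy -> Gy
    np.clip(full, 0.0, None, out=full)
    center = [(ks - 1) // 2 for ks in kernel.grid.shape]
    slices = tuple(
        slice(c, c + s) for c, s in zip(center, a_cum.shape)
    )
    dose = full[slices].copy()
    voxel_cm3 = float(np.prod(activity.voxel_size_mm)) * 1e-3
    escaped = float(full.sum() - dose.sum()) * voxel_cm3
    return DoseMap(
        voxel_dose_gy=dose,
        voxel_size_mm=activity.voxel_size_mm,
        source="convolution",
        n_fractions=1,
        affine=activity.affine,
        escaped_dose_gy_cm3=escaped,
    )


def direct_convolve_dose(activity: ActivityMap, kernel: DoseVoxelKernel) -> DoseMap:
    """Brute-force triple-loop evaluation of the convolution sum.

    Independent oracle for :func:`convolve_dose`; only sensible on small grids.
    """
    _check_grids_match(activity, kernel)
    a_cum = cumulated_activity(activity)
    shape = a_cum.shape
    kshape = kernel.grid.shape
    kc = kernel.grid.center_index
    dose = np.zeros(shape)
    nz = np.argwhere(a_cum != 0)
    for (sx, sy, sz) in nz:
        a = a_cum[sx, sy, sz]
        for kx in range(kshape[0]):
            x = sx + kx - kc[0]
            if x < 0 or x >= shape[0]:
                continue
            for ky in range(kshape[1]):
                y = sy + ky - kc[1]
                if y < 0 or y >= shape[1]:
                    continue
                for kz in range(kshape[2]):
                    z = sz + kz - kc[2]
                    if z < 0 or z >= shape[2]:
                        continue
                    dose[x, y, z] += a * kernel.values[kx, ky, kz]
    return DoseMap(
        voxel_dose_gy=dose * 1e-3,
        voxel_size_mm=activity.voxel_size_mm,
        source="convolution",
        n_fractions=1,
        affine=activity.affine,
    )


def export_dose(dose_map: DoseMap, path: str | Path) -> None:
    """Write the dose map as a float32 NIfTI aligned to the anatomical grid."""
    from . import io as _io

    sidecar = {
        "kind": "dose_map",
        "units": "Gy",
        "source": dose_map.source,
        "n_fractions": dose_map.n_fractions,
        "dose_per_fraction_gy": dose_map.dose_per_fraction_gy,
        "voxel_size_mm": list(dose_map.voxel_size_mm),
        "escaped_dose_gy_cm3": dose_map.escaped_dose_gy_cm3,
    }
    _io.save_nifti(
        path,
        dose_map.voxel_dose_gy,
        voxel_size_mm=dose_map.voxel_size_mm,
        affine=dose_map.affine,
        sidecar=sidecar,
    )


def load_dose(path: str | Path) -> DoseMap:
    """Round-trip reader for :func:`export_dose`."""
    from . import io as _io

    data, affine, voxel, sidecar = _io.load_nifti(path)
    if sidecar is None or sidecar.get("kind") != "dose_map":
        raise ValueError("missing or invalid dose-map sidecar")
    dpf = sidecar.get("dose_per_fraction_gy")
    return DoseMap(
        voxel_dose_gy=np.clip(data, 0.0, None),
        voxel_size_mm=tuple(sidecar["voxel_size_mm"]),
        source=sidecar["source"],
        n_fractions=int(sidecar["n_fractions"]),
        dose_per_fraction_gy=float(dpf) if dpf is not None else None,
        affine=affine,
        escaped_dose_gy_cm3=float(sidecar.get("escaped_dose_gy_cm3", 0.0)),
    )
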