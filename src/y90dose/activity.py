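"""Voxel activity maps from contrast-enhancement intensity.

The central planning assumption is that the relative voxel intensity of the
contrast-enhanced T1-weighted volume, restricted to the tumor VOI, is a
valid surrogate for how the administered :sup:`90`Y activity distributes.
The activity map therefore allocates the total administered activity
proportionally to intensity inside the VOI and exactly zero outside.

Because the carrier adheres to the vessel wall and acts as a permanent
implant, the time-integrated (cumulated) activity per voxel is simply
``a / lambda`` with ``lambda`` the physical decay constant — no biological
clearance term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ActivityMap", "build_activity_map", "cumulated_activity", "Y90_HALF_LIFE_H"]

log = logging.getLogger(__name__)

#: physical half-life of 90Y used throughout (hours)
Y90_HALF_LIFE_H = 64.0


@dataclass
class ActivityMap:
    """Per-voxel activity (MBq) with decay metadata.

    Invariants: activity is non-negative, zero outside the VOI, and sums to
    ``total_activity_mbq`` to float precision.
    """

    voxel_activity_mbq: np.ndarray
    total_activity_mbq: float
    half_life_h: float
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half-life must be positive")
        if np.any(self.voxel_activity_mbq < 0):
            raise ValueError("voxel activity must be non-negative")

    @property
    def decay_constant_per_h(self) -> float:
        """lambda = ln2 / T_half (h^-1)."""
        return float(np.log(2.0) / self.half_life_h)

    @property
    def decay_constant_per_s(self) -> float:
        return self.decay_constant_per_h / 3600.0

    def rescaled(self, total_activity_mbq: float) -> "ActivityMap":
        """Same spatial distribution at a different administered activity."""
        scale = total_activity_mbq / self.total_activity_mbq
        return ActivityMap(
            voxel_activity_mbq=self.voxel_activity_mbq * scale,
            total_activity_mbq=total_activity_mbq,
            half_life_h=self.half_life_h,
            voxel_size_mm=self.voxel_size_mm,
            affine=self.affine,
        )


def build_activity_map(
    intensity: np.ndarray,
    voi_mask: np.ndarray,
    total_activity_mbq: float,
    *,
    half_life_h: float = Y90_HALF_LIFE_H,
    voxel_size_mm: tuple[float, float, float] = (0.8, 0.8, 0.8),
    affine: np.ndarray | None = None,
    background_subtract: float | None = None,
    threshold: float | None = None,
) -> ActivityMap:
    """Allocate ``total_activity_mbq`` over the VOI proportionally to intensity.

    Voxel activity is ``A_total * I_i / sum_VOI(I)`` inside the mask and zero
    elsewhere.  Negative intensities (possible after preprocessing) are
    clipped to zero before normalisation and logged.  Optional variants:
    subtract a background level, or zero out intensities below a threshold,
    before normalising.
    """
    intensity = np.asarray(intensity, dtype=float)
    voi_mask = np.asarray(voi_mask, dtype=bool)
    if intensity.shape != voi_mask.shape:
        raise ValueError("intensity and mask shapes differ")
    if not voi_mask.any():
        raise ValueError("empty VOI")
    if total_activity_mbq <= 0:
        raise ValueError("total activity must be positive")

    values = intensity[voi_mask].copy()
    n_negative = int((values < 0).sum())
    if n_negative:
        log.info("clipping %d negative VOI intensities to zero", n_negative)
        values = np.clip(values, 0.0, None)
    if background_subtract is not None:
        values = np.clip(values - background_subtract, 0.0, None)
    if threshold is not None:
        values[values < threshold] = 0.0
    total_intensity = values.sum()
    if total_intensity <= 0:
        raise ValueError("VOI intensity is all zero; activity allocation undefined")

    voxel_activity = np.zeros(intensity.shape, dtype=float)
    voxel_activity[voi_mask] = total_activity_mbq * values / total_intensity
    return ActivityMap(
        voxel_activity_mbq=voxel_activity,
        total_activity_mbq=float(total_activity_mbq),
        half_life_h=half_life_h,
        voxel_size_mm=tuple(float(v) for v in voxel_size_mm),
        affine=affine,
    )


def cumulated_activity(activity: ActivityMap) -> np.ndarray:
    """Per-voxel cumulated activity (MBq·s): a / lambda, physical decay only."""
    lam = activity.decay_constant_per_s
    if lam <= 0:
        raise ValueError("decay constant must be positive")
    return activity.voxel_activity_mbq / lam
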