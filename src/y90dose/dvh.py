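"""Dose-volume histograms, coverage metrics and activity prescription.

Conventions
-----------
``D_p`` is the dose received by at least fraction ``p`` of a structure's
volume.  Two evaluation paths are provided on purpose:

* :func:`coverage_dose` — the exact order statistic on voxel doses.  It is
  scale-equivariant (``D_p(sD) = s D_p(D)``), which is what makes activity
  prescription by linear rescaling close exactly;
* :func:`compute_dvh` + :func:`dose_at_volume` — a binned cumulative curve
  (default 0.1 Gy bins) with linear interpolation between bin edges, for
  curve export and plotting.

Because physical dose is exactly linear in administered activity, the
activity that delivers the prescription to fraction ``p`` of the PTV is the
closed-form rescale ``A_p = A0 * Rx / D_p(A0)``.  BED-matched prescription
solves the strictly monotone scale equation by bracketing + Brent's method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dose import DoseMap
from .radiobiology import BEDParameters, bed_y90

__all__ = [
    "DVHCurve",
    "PrescriptionResult",
    "PairedTestResult",
    "compute_dvh",
    "dose_at_volume",
    "coverage_dose",
    "prescribe_activity",
    "prescribe_activity_bed_matched",
    "compare_plans",
    "dvh_table",
]


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of structure volume receiving >= dose."""

    structure: str
    dose_gy: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.volume_fraction, dtype=float)
        if v[0] != 1.0 or np.any(np.diff(v) > 1e-12) or v[-1] != 0.0:
            raise ValueError("DVH must start at 1, be non-increasing, and end at 0")


@dataclass
class PrescriptionResult:
    """Solved activities and the coverage metrics that justified them."""

    a95_mbq: float
    a99_mbq: float
    a_bed_matched_mbq: float | None
    nominal_activity_mbq: float
    prescription_gy: float
    d95_nominal_gy: float
    d99_nominal_gy: float
    metrics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a99_mbq < self.a95_mbq - 1e-9 * self.a95_mbq:
            raise ValueError("A99 must be >= A95 (D99 <= D95 for any distribution)")


@dataclass
class PairedTestResult:
    """Two-sided paired t-test outcome; degenerate when the differences have zero variance."""

    t: float | None
    p_value: float | None
    df: int
    n: int
    mean_difference: float
    degenerate: bool = False


def compute_dvh(
    dose_map: DoseMap | np.ndarray,
    mask: np.ndarray,
    n_bins: int | None = None,
    bin_width_gy: float = 0.1,
    structure: str = "structure",
) -> DVHCurve:
    """Cumulative DVH of a structure, volume-weighted by (uniform) voxel volume."""
    dose = dose_map.voxel_dose_gy if isinstance(dose_map, DoseMap) else np.asarray(dose_map)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    values = dose[mask].astype(float)
    dmax = float(values.max())
    if n_bins is not None:
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        edges = np.linspace(0.0, dmax + max(dmax, 1.0) * 1e-9, n_bins)
    else:
        edges = np.arange(0.0, dmax + 2.0 * bin_width_gy, bin_width_gy)
    # fraction of volume receiving >= edge
    counts = np.searchsorted(np.sort(values), edges, side="left")
    fraction = 1.0 - counts / values.size
    fraction[0] = 1.0
    fraction[-1] = 0.0
    return DVHCurve(structure=structure, dose_gy=edges, volume_fraction=fraction)


def dose_at_volume(dvh: DVHCurve, volume_fraction: float) -> float:
    """D_p from a DVH curve: largest dose with coverage >= p, interpolated between edges."""
    p = volume_fraction
    if not 0 < p <= 1:
        raise ValueError("volume fraction must be in (0, 1]")
    v = dvh.volume_fraction
    d = dvh.dose_gy
    idx = np.nonzero(v >= p)[0]
    if idx.size == 0:
        return 0.0
    j = int(idx[-1])
    if j == len(v) - 1 or v[j] <= p + 1e-12:
        return float(d[j])
    return float(d[j] + (d[j + 1] - d[j]) * (v[j] - p) / (v[j] - v[j + 1]))


def coverage_dose(dose_map: DoseMap | np.ndarray, mask: np.ndarray, p: float) -> float:
    """Exact D_p: the k-th largest voxel dose with k = ceil(p * n)."""
    if not 0 < p <= 1:
        raise ValueError("volume fraction must be in (0, 1]")
    dose = dose_map.voxel_dose_gy if isinstance(dose_map, DoseMap) else np.asarray(dose_map)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    values = dose[mask]
    k = math.ceil(p * values.size)
    return float(np.partition(values, values.size - k)[values.size - k])


def prescribe_activity(
    dose_map: DoseMap,
    ptv_mask: np.ndarray,
    nominal_activity_mbq: float,
    prescription_gy: float = 60.0,
    coverage: float = 0.95,
) -> float:
    """Activity delivering ``prescription_gy`` to fraction ``coverage`` of the PTV.

    Exploits exact linearity of physical dose in activity:
    ``A_p = A0 * Rx / D_p(A0)``.
    """
    d_p = coverage_dose(dose_map, ptv_mask, coverage)
    if d_p <= 0:
        raise ValueError("zero PTV coverage at nominal activity; no activity in the VOI?")
    return nominal_activity_mbq * prescription_gy / d_p


def prescribe_activity_bed_matched(
    dose_map: DoseMap,
    ptv_mask: np.ndarray,
    nominal_activity_mbq: float,
    target_bed_gy: float,
    params: BEDParameters | None = None,
    statistic: str = "mean",
    scale_bounds: tuple[float, float] = (1e-9, 1e9),
    rtol: float = 1e-6,
) -> float:
    """Activity at which the PTV BED statistic matches ``target_bed_gy``.

    ``statistic`` is ``"mean"`` (mean PTV BED, the default matching target) or
    ``"d95"`` (BED at the D95 dose level).  The statistic is strictly
    increasing in the activity scale, so the bracketed root is unique.
    """
    if target_bed_gy <= 0:
        raise ValueError("target BED must be positive")
    params = params or BEDParameters.tumor()
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    doses = dose_map.voxel_dose_gy[ptv_mask]
    if doses.size == 0 or doses.max() <= 0:
        raise ValueError("no dose in the PTV at nominal activity")

    if statistic == "mean":
        def stat(s: float) -> float:
            return float(np.mean(bed_y90(s * doses, params)))
    elif statistic == "d95":
        d95 = coverage_dose(dose_map, ptv_mask, 0.95)

        def stat(s: float) -> float:
            return float(bed_y90(s * d95, params))
    else:
        raise ValueError("statistic must be 'mean' or 'd95'")

    def f(s: float) -> float:
        return stat(s) - target_bed_gy

    lo, hi = 1.0, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > scale_bounds[1]:
            raise ValueError("no bracket: target BED unreachable within activity bounds")
    while f(lo) > 0:
        lo *= 0.5
        if lo < scale_bounds[0]:
            raise ValueError("no bracket: target BED below reachable range")
    s = optimize.brentq(f, lo, hi, rtol=rtol * 1e-2, xtol=1e-30)
    return float(s * nominal_activity_mbq)


def compare_plans(plan_a: np.ndarray, plan_b: np.ndarray) -> PairedTestResult:
    """Two-sided paired t-test on per-phantom metric differences (a - b)."""
    a = np.asarray(plan_a, dtype=float)
    b = np.asarray(plan_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    diff = a - b
    if np.std(diff, ddof=1) == 0.0:
        return PairedTestResult(
            t=None, p_value=None, df=a.size - 1, n=a.size,
            mean_difference=float(diff.mean()), degenerate=True,
        )
    res = stats.ttest_rel(a, b)
    return PairedTestResult(
        t=float(res.statistic),
        p_value=float(res.pvalue),
        df=a.size - 1,
        n=a.size,
        mean_difference=float(diff.mean()),
    )


def dvh_table(curves: list[DVHCurve]) -> pd.DataFrame:
    """Tabulate DVH curves on a common dose axis for CSV export."""
    grid = np.unique(np.concatenate([c.dose_gy for c in curves]))
    data = {"dose_Gy": grid}
    for c in curves:
        data[c.structure] = np.interp(grid, c.dose_gy, c.volume_fraction)
    return pd.DataFrame(data)
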