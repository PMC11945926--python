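"""Biologically effective dose (BED) under the linear-quadratic model.

Two delivery regimes are covered:

* fractionated external-beam:  ``BED = D (1 + d / (alpha/beta))`` with total
  dose ``D`` and dose per fraction ``d``;
* single-administration permanent implant (the :sup:`90`Y regime):
  ``BED = D (1 + [lambda / (lambda + mu)] D / (alpha/beta))`` where
  ``lambda = ln2 / T_phys`` is the physical decay rate and
  ``mu = ln2 / T_rep`` the sublethal-damage repair rate.  The dose-rate
  factor ``lambda / (lambda + mu)`` expresses how much sublethal damage is
  repaired during the protracted exposure; instant repair (``T_rep -> 0``)
  collapses BED to the physical dose.

Default parameters: tumor alpha/beta = 10 Gy with T_rep = 1.5 h; normal
tissue alpha/beta = 2.5 Gy with T_rep = 2.5 h; physical half-life 64 h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose import DoseMap

__all__ = [
    "BEDParameters",
    "EBRTPlan",
    "bed_ebrt",
    "bed_y90",
    "invert_bed_y90",
    "bed_map",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class BEDParameters:
    """Radiobiological parameters of one tissue class."""

    alpha_beta_gy: float
    t_rep_h: float
    t_phys_h: float = 64.0
    tissue_class: str = "tumor"

    def __post_init__(self) -> None:
        if self.alpha_beta_gy <= 0 or self.t_rep_h <= 0 or self.t_phys_h <= 0:
            raise ValueError("alpha/beta and half-times must be positive")

    @property
    def mu_per_h(self) -> float:
        """Sublethal-damage repair rate mu = ln2 / T_rep (h^-1)."""
        return LN2 / self.t_rep_h

    @property
    def lambda_per_h(self) -> float:
        """Physical decay rate lambda = ln2 / T_phys (h^-1)."""
        return LN2 / self.t_phys_h

    @property
    def dose_rate_factor(self) -> float:
        """lambda / (lambda + mu): the permanent-implant dose-protraction factor."""
        lam, mu = self.lambda_per_h, self.mu_per_h
        return lam / (lam + mu)

    @classmethod
    def tumor(cls, t_phys_h: float = 64.0) -> "BEDParameters":
        return cls(alpha_beta_gy=10.0, t_rep_h=1.5, t_phys_h=t_phys_h, tissue_class="tumor")

    @classmethod
    def normal(cls, t_phys_h: float = 64.0) -> "BEDParameters":
        return cls(alpha_beta_gy=2.5, t_rep_h=2.5, t_phys_h=t_phys_h, tissue_class="normal")


@dataclass(frozen=True)
class EBRTPlan:
    """Fractionation of the external-beam comparator."""

    total_dose_gy: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.total_dose_gy < 0:
            raise ValueError("total dose must be non-negative")

    @property
    def dose_per_fraction_gy(self) -> float:
        return self.total_dose_gy / self.n_fractions


def bed_ebrt(total_dose_gy, dose_per_fraction_gy, params: BEDParameters):
    """Fractionated external-beam BED: D (1 + d / (alpha/beta)). Accepts arrays."""
    d = np.asarray(total_dose_gy, dtype=float)
    dpf = np.asarray(dose_per_fraction_gy, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = d * (1.0 + dpf / params.alpha_beta_gy)
    return out if out.ndim else float(out)


def bed_y90(total_dose_gy, params: BEDParameters):
    """Permanent-implant BED: D (1 + [lambda/(lambda+mu)] D / (alpha/beta)). Accepts arrays."""
    d = np.asarray(total_dose_gy, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = d * (1.0 + params.dose_rate_factor * d / params.alpha_beta_gy)
    return out if out.ndim else float(out)


def invert_bed_y90(bed_gy, params: BEDParameters):
    """Physical dose giving the requested permanent-implant BED (closed form).

    Solves the quadratic ``g D^2 / (alpha/beta) + D - BED = 0`` for its
    positive root, with ``g`` the dose-rate factor.
    """
    bed = np.asarray(bed_gy, dtype=float)
    if np.any(bed < 0):
        raise ValueError("BED must be non-negative")
    a = params.dose_rate_factor / params.alpha_beta_gy
    out = (np.sqrt(1.0 + 4.0 * a * bed) - 1.0) / (2.0 * a)
    return out if out.ndim else float(out)


def bed_map(
    dose_map: DoseMap,
    tumor_mask: np.ndarray,
    normal_mask: np.ndarray,
    tumor_params: BEDParameters | None = None,
    normal_params: BEDParameters | None = None,
) -> np.ndarray:
    """Voxelwise BED over the union of the two tissue masks.

    The regime follows the dose map's source: convolution maps use the
    permanent-implant formula, external-beam surrogate maps the fractionated
    formula with a per-voxel dose per fraction ``D_voxel / N`` (the standard
    voxelwise LQ convention at fixed fraction number).  Voxels outside both
    masks are zero; a voxel in both masks is an error.
    """
    tumor_params = tumor_params or BEDParameters.tumor()
    normal_params = normal_params or BEDParameters.normal()
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    normal_mask = np.asarray(normal_mask, dtype=bool)
    if (tumor_mask & normal_mask).any():
        raise ValueError("a voxel is assigned to both tumor and normal classes")
    d = dose_map.voxel_dose_gy
    out = np.zeros_like(d)
    for mask, params in ((tumor_mask, tumor_params), (normal_mask, normal_params)):
        if not mask.any():
            continue
        dv = d[mask]
        if dose_map.source == "vmat_surrogate":
            out[mask] = bed_ebrt(dv, dv / dose_map.n_fractions, params)
        else:
            out[mask] = bed_y90(dv, params)
    return out
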