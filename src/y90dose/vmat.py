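"""Parametric external-beam (VMAT-like) comparator dose maps.

A full arc-therapy optimiser is out of scope; what the plan comparison
needs from the comparator is (i) homogeneous PTV coverage at the
prescription, (ii) a finite lateral penumbra, and (iii) the low-dose bath
that arc delivery spreads through the rest of the brain.  Those three are
modelled directly: prescription dose inside the PTV within a small
homogeneity band (renormalised so the PTV mean hits the prescription
exactly), a Gaussian-blurred PTV indicator as the penumbra, and a constant
out-of-field base fraction of the prescription.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dose import DoseMap
from .phantom import StructureSet

__all__ = ["SurrogatePlanSpec", "generate_vmat_like_dose"]


@dataclass(frozen=True)
class SurrogatePlanSpec:
    """Parameters of the external-beam comparator.

    ``penumbra_sigma_mm`` controls the dose falloff at the PTV edge;
    ``base_fraction`` is the out-of-field dose floor as a fraction of the
    prescription; ``homogeneity`` the half-width of the relative dose band
    inside the PTV.
    """

    prescription_gy: float = 60.0
    n_fractions: int = 30
    homogeneity: float = 0.02
    penumbra_sigma_mm: float = 6.0
    base_fraction: float = 0.08

    def __post_init__(self) -> None:
        if self.prescription_gy <= 0 or self.penumbra_sigma_mm <= 0:
            raise ValueError("prescription and penumbra sigma must be positive")
        if not 0 <= self.base_fraction < 1 or not 0 <= self.homogeneity < 1:
            raise ValueError("base_fraction and homogeneity must be in [0, 1)")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


def generate_vmat_like_dose(
    structures: StructureSet,
    spec: SurrogatePlanSpec | None = None,
    seed: int = 0,
) -> DoseMap:
    """Generate the comparator dose map on the structure set's grid.

    The PTV mean dose equals the prescription exactly (within float
    precision); outside the PTV the dose is the larger of the Gaussian
    penumbra and the base-fraction floor, hence non-increasing away from the
    target down to the floor.
    """
    spec = spec or SurrogatePlanSpec()
    ptv = structures.masks["PTV"]
    if not ptv.any():
        raise ValueError("empty PTV")
    rng = np.random.default_rng(seed)
    rx = spec.prescription_gy

    sigma_vox = [spec.penumbra_sigma_mm / v for v in structures.voxel_size_mm]
    penumbra = ndimage.gaussian_filter(ptv.astype(float), sigma=sigma_vox) * rx
    dose = np.maximum(penumbra, spec.base_fraction * rx)

    n_ptv = int(ptv.sum())
    in_field = rx * (1.0 + rng.uniform(-spec.homogeneity, spec.homogeneity, n_ptv))
    in_field *= rx / in_field.mean()  # pin the PTV mean to the prescription
    dose[ptv] = in_field

    return DoseMap(
        voxel_dose_gy=dose,
        voxel_size_mm=structures.voxel_size_mm,
        source="vmat_surrogate",
        n_fractions=spec.n_fractions,
        dose_per_fraction_gy=rx / spec.n_fractions,
        affine=structures.affine,
    )
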