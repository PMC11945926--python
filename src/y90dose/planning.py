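"""End-to-end plan evaluation for one phantom / patient volume.

Glues the pipeline together: intensity -> activity map -> convolution dose
at a nominal administered activity -> coverage prescription (A95, A99) ->
external-beam comparator -> BED matching -> per-structure mean dose and
mean BED at each prescription.  This is what the CLI ``plan`` command, the
cohort analyses and the acceptance checks all run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity import Y90_HALF_LIFE_H, build_activity_map
from .dose import DoseMap, convolve_dose
from .dvh import (
    PrescriptionResult,
    coverage_dose,
    prescribe_activity,
    prescribe_activity_bed_matched,
)
from .kernel import DoseVoxelKernel
from .phantom import StructureSet
from .radiobiology import BEDParameters, bed_map
from .vmat import SurrogatePlanSpec, generate_vmat_like_dose

__all__ = ["PlanReport", "evaluate_phantom_plan"]


@dataclass
class PlanReport:
    """Per-phantom planning summary.

    ``mean_dose_gy`` and ``mean_bed_gy`` map structure name -> plan label
    ("y90_a95", "y90_a99", "y90_bed_matched", "vmat") -> value.
    """

    prescription: PrescriptionResult
    ptv_brain_ratio: float
    mean_dose_gy: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_bed_gy: dict[str, dict[str, float]] = field(default_factory=dict)
    nominal_dose: DoseMap | None = None
    vmat_dose: DoseMap | None = None


def evaluate_phantom_plan(
    intensity: np.ndarray,
    structures: StructureSet,
    kernel: DoseVoxelKernel,
    *,
    nominal_activity_mbq: float = 1000.0,
    prescription_gy: float = 60.0,
    half_life_h: float = Y90_HALF_LIFE_H,
    vmat_spec: SurrogatePlanSpec | None = None,
    tumor_params: BEDParameters | None = None,
    normal_params: BEDParameters | None = None,
    bed_statistic: str = "mean",
    seed: int = 0,
    keep_dose_maps: bool = True,
) -> PlanReport:
    """Run the full planning chain on one phantom.

    The nominal simulation is performed once; prescriptions follow from the
    exact linearity of physical dose in activity.  BED maps are recomputed
    at every prescription because BED is non-linear in dose.
    """
    ptv = structures.masks["PTV"]
    brain_ptv = structures.masks["Brain-PTV"]
    tumor_params = tumor_params or BEDParameters.tumor()
    normal_params = normal_params or BEDParameters.normal()
    vmat_spec = vmat_spec or SurrogatePlanSpec(prescription_gy=prescription_gy)

    amap = build_activity_map(
        intensity,
        ptv,
        nominal_activity_mbq,
        half_life_h=half_life_h,
        voxel_size_mm=structures.voxel_size_mm,
        affine=structures.affine,
    )
    dose0 = convolve_dose(amap, kernel)

    d95 = coverage_dose(dose0, ptv, 0.95)
    d99 = coverage_dose(dose0, ptv, 0.99)
    a95 = prescribe_activity(dose0, ptv, nominal_activity_mbq, prescription_gy, 0.95)
    a99 = prescribe_activity(dose0, ptv, nominal_activity_mbq, prescription_gy, 0.99)

    vmat_dose = generate_vmat_like_dose(structures, vmat_spec, seed=seed)
    vmat_bed = bed_map(vmat_dose, ptv, brain_ptv, tumor_params, normal_params)
    target_bed = float(vmat_bed[ptv].mean())
    a_bed = prescribe_activity_bed_matched(
        dose0, ptv, nominal_activity_mbq, target_bed, tumor_params, statistic=bed_statistic
    )

    plans = {
        "y90_a95": a95 / nominal_activity_mbq,
        "y90_a99": a99 / nominal_activity_mbq,
        "y90_bed_matched": a_bed / nominal_activity_mbq,
    }
    mean_dose: dict[str, dict[str, float]] = {"PTV": {}, "Brain-PTV": {}}
    mean_bed: dict[str, dict[str, float]] = {"PTV": {}, "Brain-PTV": {}}
    for label, scale in plans.items():
        scaled = dose0.scaled(scale)
        bed = bed_map(scaled, ptv, brain_ptv, tumor_params, normal_params)
        for name, mask in (("PTV", ptv), ("Brain-PTV", brain_ptv)):
            mean_dose[name][label] = float(scaled.voxel_dose_gy[mask].mean())
            mean_bed[name][label] = float(bed[mask].mean())
    for name, mask in (("PTV", ptv), ("Brain-PTV", brain_ptv)):
        mean_dose[name]["vmat"] = float(vmat_dose.voxel_dose_gy[mask].mean())
        mean_bed[name]["vmat"] = float(vmat_bed[mask].mean())

    prescription = PrescriptionResult(
        a95_mbq=a95,
        a99_mbq=a99,
        a_bed_matched_mbq=a_bed,
        nominal_activity_mbq=nominal_activity_mbq,
        prescription_gy=prescription_gy,
        d95_nominal_gy=d95,
        d99_nominal_gy=d99,
        metrics={"target_bed_gy": target_bed, "bed_statistic": bed_statistic},
    )
    return PlanReport(
        prescription=prescription,
        ptv_brain_ratio=structures.ptv_brain_ratio,
        mean_dose_gy=mean_dose,
        mean_bed_gy=mean_bed,
        nominal_dose=dose0 if keep_dose_maps else None,
        vmat_dose=vmat_dose if keep_dose_maps else None,
    )
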