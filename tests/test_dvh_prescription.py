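"""DVH curves, coverage doses, activity prescription and plan statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from y90dose import (
    BEDParameters,
    bed_y90,
    compare_plans,
    compute_dvh,
    coverage_dose,
    dose_at_volume,
    invert_bed_y90,
    prescribe_activity,
    prescribe_activity_bed_matched,
)
from y90dose.dose import DoseMap
from y90dose.dvh import dvh_table


def _dose_map(values):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values.reshape(1, 1, -1)
    return DoseMap(voxel_dose_gy=values, voxel_size_mm=(1, 1, 1), source="convolution")


def _full_mask(dose_map):
    return np.ones(dose_map.voxel_dose_gy.shape, dtype=bool)


# ---------------------------------------------------------------------------
# DVH curves
# ---------------------------------------------------------------------------

def test_uniform_dose_gives_a_step_dvh():
    dm = _dose_map(np.full(8, 60.0))
    curve = compute_dvh(dm, _full_mask(dm))
    assert np.all(curve.volume_fraction[curve.dose_gy <= 60.0] == 1.0)
    assert np.all(curve.volume_fraction[curve.dose_gy > 60.0] == 0.0)


def test_two_voxel_dvh_matches_hand_counting():
    dm = _dose_map([10.0, 30.0])
    curve = compute_dvh(dm, _full_mask(dm))
    at_20 = curve.volume_fraction[np.searchsorted(curve.dose_gy, 20.0)]
    assert at_20 == pytest.approx(0.5)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    hnp.arrays(
        np.float64, st.integers(1, 100), elements=st.floats(0.0, 300.0, allow_nan=False)
    )
)
def test_dvh_is_non_increasing_and_bounded(values):
    dm = _dose_map(values)
    curve = compute_dvh(dm, _full_mask(dm))
    assert curve.volume_fraction[0] == 1.0
    assert curve.volume_fraction[-1] == 0.0
    assert np.all(np.diff(curve.volume_fraction) <= 1e-12)
    assert np.all((curve.volume_fraction >= 0) & (curve.volume_fraction <= 1))
    # D99 <= D95 for every dose distribution
    assert coverage_dose(dm, _full_mask(dm), 0.99) <= coverage_dose(dm, _full_mask(dm), 0.95)


def test_empty_mask_and_bad_parameters_are_rejected():
    dm = _dose_map([1.0, 2.0])
    with pytest.raises(ValueError, match="empty"):
        compute_dvh(dm, np.zeros((1, 1, 2), dtype=bool))
    with pytest.raises(ValueError):
        compute_dvh(dm, _full_mask(dm), n_bins=1)
    with pytest.raises(ValueError):
        dose_at_volume(compute_dvh(dm, _full_mask(dm)), 1.5)


# ---------------------------------------------------------------------------
# coverage dose D_p
# ---------------------------------------------------------------------------

def test_coverage_dose_convention_on_the_two_voxel_map():
    """Dose received by at least p of the volume: D50 = 30 Gy, D100 = 10 Gy."""
    dm = _dose_map([10.0, 30.0])
    mask = _full_mask(dm)
    assert coverage_dose(dm, mask, 0.50) == 30.0
    assert coverage_dose(dm, mask, 1.00) == 10.0
    assert coverage_dose(dm, mask, 0.95) == 10.0
    curve = compute_dvh(dm, mask)
    assert dose_at_volume(curve, 0.50) == pytest.approx(30.0, abs=0.1)
    assert dose_at_volume(curve, 1.00) == pytest.approx(10.0, abs=0.1)


def test_uniform_dose_coverage_levels_coincide():
    dm = _dose_map(np.full(100, 60.0))
    mask = _full_mask(dm)
    assert coverage_dose(dm, mask, 0.95) == 60.0
    assert coverage_dose(dm, mask, 0.99) == 60.0
    curve = compute_dvh(dm, mask)
    assert dose_at_volume(curve, 0.95) == pytest.approx(60.0, abs=0.11)


# ---------------------------------------------------------------------------
# activity prescription
# ---------------------------------------------------------------------------

def test_prescription_rescale_identity_and_magnitude():
    uniform = _dose_map(np.full(50, 60.0))
    assert prescribe_activity(uniform, _full_mask(uniform), 1000.0) == pytest.approx(1000.0)
    hot = _dose_map(np.full(50, 222.9))
    a95 = prescribe_activity(hot, _full_mask(hot), 1000.0)
    assert a95 == pytest.approx(269.2, abs=0.05)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    hnp.arrays(
        np.float64, st.integers(5, 200), elements=st.floats(0.1, 400.0, allow_nan=False)
    )
)
def test_a99_never_falls_below_a95(values):
    dm = _dose_map(values)
    mask = _full_mask(dm)
    a95 = prescribe_activity(dm, mask, 1000.0, coverage=0.95)
    a99 = prescribe_activity(dm, mask, 1000.0, coverage=0.99)
    assert a99 >= a95


def test_prescription_closure_is_exact_under_linear_scaling():
    rng = np.random.default_rng(9)
    dm = _dose_map(rng.lognormal(3.0, 0.8, size=500))
    mask = _full_mask(dm)
    a95 = prescribe_activity(dm, mask, 1000.0, prescription_gy=60.0, coverage=0.95)
    rescaled = dm.scaled(a95 / 1000.0)
    assert coverage_dose(rescaled, mask, 0.95) == pytest.approx(60.0, rel=1e-12)


def test_zero_coverage_is_rejected():
    dm = _dose_map(np.zeros(10))
    with pytest.raises(ValueError, match="zero PTV coverage"):
        prescribe_activity(dm, _full_mask(dm), 1000.0)


# ---------------------------------------------------------------------------
# BED-matched prescription
# ---------------------------------------------------------------------------

def test_bed_matching_fixed_point_returns_the_nominal_activity():
    rng = np.random.default_rng(10)
    dm = _dose_map(rng.lognormal(3.5, 0.5, 200))
    mask = _full_mask(dm)
    params = BEDParameters.tumor()
    current = float(np.mean(bed_y90(dm.voxel_dose_gy[mask], params)))
    a = prescribe_activity_bed_matched(dm, mask, 1000.0, current, params)
    assert a == pytest.approx(1000.0, rel=1e-6)


def test_bed_matching_on_uniform_dose_matches_the_quadratic_inversion():
    """For a uniform PTV dose the solver must agree with the closed-form
    inversion of the implant BED quadratic."""
    params = BEDParameters.tumor()
    dm = _dose_map(np.full(64, 80.0))
    mask = _full_mask(dm)
    target = 130.0
    a = prescribe_activity_bed_matched(dm, mask, 1000.0, target, params)
    expected_scale = invert_bed_y90(target, params) / 80.0
    assert a == pytest.approx(1000.0 * expected_scale, rel=1e-6)
    # the d95 statistic coincides with the mean on a uniform distribution
    a_d95 = prescribe_activity_bed_matched(dm, mask, 1000.0, target, params, statistic="d95")
    assert a_d95 == pytest.approx(a, rel=1e-6)


def test_bed_matching_is_monotone_in_the_target():
    rng = np.random.default_rng(11)
    dm = _dose_map(rng.lognormal(3.5, 0.5, 200))
    mask = _full_mask(dm)
    a1 = prescribe_activity_bed_matched(dm, mask, 1000.0, 70.0)
    a2 = prescribe_activity_bed_matched(dm, mask, 1000.0, 140.0)
    assert a2 > a1


# ---------------------------------------------------------------------------
# paired comparison
# ---------------------------------------------------------------------------

def test_paired_t_matches_hand_computation_and_is_antisymmetric():
    a = np.array([2.0, 4.0, 6.0])
    b = np.array([1.0, 2.0, 3.0])
    res = compare_plans(a, b)
    assert res.t == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)
    assert res.df == 2
    flipped = compare_plans(b, a)
    assert flipped.t == pytest.approx(-res.t, rel=1e-12)
    assert flipped.p_value == pytest.approx(res.p_value, rel=1e-12)


def test_zero_variance_differences_are_flagged_degenerate():
    res = compare_plans(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))
    assert res.degenerate
    assert res.t is None and res.p_value is None
    assert res.mean_difference == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        compare_plans(np.array([1.0]), np.array([2.0]))


def test_dvh_table_collects_curves_on_a_common_axis():
    dm = _dose_map([10.0, 30.0])
    mask = _full_mask(dm)
    table = dvh_table(
        [compute_dvh(dm, mask, structure="A"), compute_dvh(dm.scaled(2.0), mask, structure="B")]
    )
    assert list(table.columns) == ["dose_Gy", "A", "B"]
    assert table["A"].iloc[0] == 1.0
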