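"""Monte Carlo dose voxel kernel: physics invariants, uncertainty, units."""

import numpy as np
import pytest

from y90dose import (
    KernelGrid,
    energy_to_dose_rate_units,
    estimate_kernel_uncertainty,
    extrapolate_relative_uncertainty,
    generate_dvk,
)
from y90dose.kernel import MEV_TO_J, csda_range_mm, energy_from_range_mm


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

def test_grid_requires_odd_shape_and_centers_correctly():
    grid = KernelGrid((5, 7, 9), (1.0, 1.0, 1.0))
    assert grid.center_index == (2, 3, 4)
    with pytest.raises(ValueError):
        KernelGrid((4, 5, 5), (1.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        KernelGrid((5, 5, 5), (1.0, -1.0, 1.0))


# ---------------------------------------------------------------------------
# range-energy relation
# ---------------------------------------------------------------------------

def test_range_energy_relation_is_a_consistent_inverse_pair():
    e = np.array([0.05, 0.3, 0.9337, 2.2801])
    r = csda_range_mm(e)
    np.testing.assert_allclose(energy_from_range_mm(r), e, rtol=1e-3)
    # endpoint electrons stop within ~1.1 cm of water, the classic 90Y figure
    assert 10.0 < csda_range_mm(np.array([2.2801]))[0] < 12.0


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def test_unit_conversion_matches_hand_arithmetic():
    """1 MeV in one 0.8x0.8x0.78 mm³ water voxel -> 3.209e-7 Gy per decay."""
    grid = KernelGrid((3, 3, 3), (0.8, 0.8, 0.78))
    emap = np.zeros((3, 3, 3))
    emap[1, 1, 1] = 1.0  # MeV per decay
    out = energy_to_dose_rate_units(emap, grid, density_g_cm3=1.0)
    mass_kg = 0.8 * 0.8 * 0.78 * 1e-3 * 1e-3  # 4.992e-7 kg
    gy_per_decay = MEV_TO_J / mass_kg
    assert gy_per_decay == pytest.approx(3.209e-7, rel=1e-3)
    # mGy per MBq.s = Gy/decay * 1e6 decays * 1e3
    assert out[1, 1, 1] == pytest.approx(gy_per_decay * 1e9)
    assert out[0, 0, 0] == 0.0


def test_unit_conversion_is_linear_and_inverse_in_density():
    grid = KernelGrid((3, 3, 3), (1.0, 1.0, 1.0))
    emap = np.zeros((3, 3, 3))
    assert np.all(energy_to_dose_rate_units(emap, grid) == 0)
    emap[1, 1, 1] = 2.0
    ref = energy_to_dose_rate_units(emap, grid, density_g_cm3=1.0)
    np.testing.assert_allclose(
        energy_to_dose_rate_units(emap, grid, density_g_cm3=2.0), ref / 2.0
    )
    with pytest.raises(ValueError):
        energy_to_dose_rate_units(emap, grid, density_g_cm3=0.0)


# ---------------------------------------------------------------------------
# generated kernel invariants
# ---------------------------------------------------------------------------

def test_kernel_component_split_and_positivity(small_kernel):
    k = small_kernel
    np.testing.assert_allclose(
        k.values, k.beta_component + k.photon_component, rtol=1e-12
    )
    assert np.all(k.values >= 0)
    assert k.values.argmax() == np.ravel_multi_index(k.grid.center_index, k.grid.shape)


def test_kernel_energy_conservation(small_kernel, y90):
    """Grid contains the full beta range, so the locally deposited beta energy
    equals (1 - radiative yield) x mean emitted energy within 3 MC standard errors."""
    k = small_kernel
    expected = (1.0 - k.radiative_yield) * y90.mean_energy_mev
    # SE of the mean deposited energy from the spectrum's variance
    e2 = np.trapezoid(y90.energies_mev**2 * y90.density, y90.energies_mev)
    se = (1.0 - k.radiative_yield) * np.sqrt(e2 - y90.mean_energy_mev**2) / np.sqrt(k.n_primaries)
    assert k.escaped_beta_mev_per_decay == pytest.approx(0.0, abs=1e-6)
    assert abs(k.deposited_energy_mev_per_decay("beta") - expected) < 3 * se
    # total on-grid energy never exceeds the emitted energy per decay
    total = k.deposited_energy_mev_per_decay("total") + k.escaped_photon_mev_per_decay
    assert total <= y90.mean_energy_mev * (1 + 1e-9) + 3 * se


def test_kernel_is_reflection_symmetric_within_mc_noise(small_kernel):
    dev = small_kernel.symmetry_deviation()
    finite = dev[np.isfinite(dev)]
    assert np.mean(finite > 3.0) < 0.01  # ~0.3% expected by chance
    assert finite.max() < 10.0


def test_beta_radial_profile_decreases_away_from_the_source(small_kernel):
    centers, profile = small_kernel.radial_profile("beta")
    inside = centers < 8.0  # region with good statistics
    p = profile[inside]
    assert np.all(np.diff(p) <= 0.05 * p[:-1])  # non-increasing within noise


def test_kernel_generation_is_bitwise_deterministic(y90):
    grid = KernelGrid((9, 9, 9), (1.6, 1.6, 1.6))
    k1 = generate_dvk(y90, grid, 6_000, seed=77, n_batches=3)
    k2 = generate_dvk(y90, grid, 6_000, seed=77, n_batches=3)
    np.testing.assert_array_equal(k1.values, k2.values)
    k3 = generate_dvk(y90, grid, 6_000, seed=78, n_batches=3)
    assert not np.array_equal(k1.values, k3.values)


def test_central_self_dose_agrees_with_high_statistics_rerun(y90):
    """Central-voxel self-dose fraction matches a 10x-primaries oracle within 2 SE."""
    grid = KernelGrid((11, 11, 11), (1.6, 1.6, 1.6))
    k_lo = generate_dvk(y90, grid, 20_000, seed=5, n_batches=8)
    k_hi = generate_dvk(y90, grid, 200_000, seed=6, n_batches=8)
    c = grid.center_index
    v_lo, v_hi = k_lo.values[c], k_hi.values[c]
    se = np.hypot(
        k_lo.rel_uncertainty[c] * v_lo, k_hi.rel_uncertainty[c] * v_hi
    )
    assert abs(v_lo - v_hi) < 2 * se


def test_generation_preconditions_are_enforced(y90):
    grid = KernelGrid((9, 9, 9), (1.6, 1.6, 1.6))
    with pytest.raises(ValueError):
        generate_dvk(y90, grid, 0, seed=0, n_batches=2)
    with pytest.raises(ValueError):
        generate_dvk(y90, grid, 100, seed=0, n_batches=1)


# ---------------------------------------------------------------------------
# uncertainty estimation
# ---------------------------------------------------------------------------

def test_uncertainty_max_is_monotone_in_the_radius(small_kernel):
    u_center = estimate_kernel_uncertainty(small_kernel, 0.1)
    u_ball = estimate_kernel_uncertainty(small_kernel, 4.8)
    u_wide = estimate_kernel_uncertainty(small_kernel, 10.0)
    assert u_center <= u_ball <= u_wide
    with pytest.raises(ValueError):
        estimate_kernel_uncertainty(small_kernel, -1.0)


def test_uncertainty_extrapolation_follows_sqrt_n():
    assert extrapolate_relative_uncertainty(0.04, 10_000, 40_000) == pytest.approx(0.02)
    with pytest.raises(ValueError):
        extrapolate_relative_uncertainty(0.04, 0, 100)


def test_batch_uncertainty_scales_as_inverse_sqrt_primaries(y90):
    """Regression of log(uncertainty) on log(N) over three runs gives slope ~ -1/2."""
    grid = KernelGrid((15, 15, 15), (1.6, 1.6, 1.6))
    ns = [8_000, 32_000, 128_000]
    med = []
    for i, n in enumerate(ns):
        k = generate_dvk(y90, grid, n, seed=100 + i, n_batches=8)
        r = k.grid.center_distances_mm()
        sel = (r <= 6.0) & np.isfinite(k.rel_uncertainty)
        med.append(np.median(k.rel_uncertainty[sel]))
    slope = np.polyfit(np.log(ns), np.log(med), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.15)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def test_kernel_round_trips_through_nifti(small_kernel, tmp_path):
    from y90dose import DoseVoxelKernel

    path = tmp_path / "kernel.nii.gz"
    small_kernel.save(path)
    loaded = DoseVoxelKernel.load(path)
    np.testing.assert_allclose(loaded.values, small_kernel.values, rtol=1e-6)
    assert loaded.grid == small_kernel.grid
    assert loaded.n_primaries == small_kernel.n_primaries
    assert loaded.mean_beta_energy_mev == pytest.approx(small_kernel.mean_beta_energy_mev)
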