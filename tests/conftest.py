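"""Shared fixtures: Monte Carlo kernels at several scales and synthetic phantoms.

Session-scoped kernels are reused across modules to keep the suite fast;
history counts are small but large enough for the statistical assertions
they back.
"""

import numpy as np
import pytest

from y90dose import (
    DoseVoxelKernel,
    KernelGrid,
    PhantomSpec,
    evaluate_phantom_plan,
    generate_cohort,
    generate_dvk,
    generate_phantom,
    y90_spectrum,
)

MASTER_SEED = 20260924


@pytest.fixture(scope="session")
def y90():
    return y90_spectrum()


@pytest.fixture(scope="session")
def small_kernel(y90):
    """Coarse kernel fully containing the beta range; for invariant checks."""
    grid = KernelGrid((21, 21, 21), (1.6, 1.6, 1.6))
    return generate_dvk(y90, grid, 24_000, seed=MASTER_SEED, n_batches=8)


@pytest.fixture(scope="session")
def clinical_kernel(y90):
    """Kernel on the clinical 53x53x53 grid with 0.8x0.8x0.78 mm voxels."""
    grid = KernelGrid((53, 53, 53), (0.8, 0.8, 0.78))
    return generate_dvk(y90, grid, 400_000, seed=MASTER_SEED, n_batches=16)


@pytest.fixture(scope="session")
def cohort_kernel(y90):
    """Kernel matched to the cohort phantoms' 1.6 mm grid."""
    grid = KernelGrid((17, 17, 17), (1.6, 1.6, 1.6))
    return generate_dvk(y90, grid, 150_000, seed=3, n_batches=10)


@pytest.fixture(scope="session")
def cohort():
    """Nine phantoms with PTV/brain ratios log-spaced over 0.005-0.15."""
    base = PhantomSpec(shape=(90, 108, 80), voxel_size_mm=(1.6, 1.6, 1.6))
    return generate_cohort(9, (0.005, 0.15), seed=7, base=base)


@pytest.fixture(scope="session")
def cohort_reports(cohort, cohort_kernel):
    return [
        evaluate_phantom_plan(p.intensity, p.structures, cohort_kernel, seed=11)
        for p in cohort
    ]


@pytest.fixture
def small_phantom():
    """Spherical 15 cm³ tumor at the clinical 0.8 mm voxel pitch."""
    spec = PhantomSpec(
        shape=(72, 72, 72),
        voxel_size_mm=(0.8, 0.8, 0.8),
        brain_semiaxes_mm=(23.0, 24.0, 22.0),
        tumor_offset_mm=(0.0, 0.0, 0.0),
        tumor_volume_cm3=15.0,
        tumor_shape="sphere",
        seed=5,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture
def synthetic_kernel():
    """Factory for hand-made kernels (no MC) used by convolution oracles."""

    def make(values: np.ndarray, voxel=(1.0, 1.0, 1.0)) -> DoseVoxelKernel:
        values = np.asarray(values, dtype=float)
        return DoseVoxelKernel(
            values=values,
            beta_component=values.copy(),
            photon_component=np.zeros_like(values),
            rel_uncertainty=np.zeros_like(values),
            n_primaries=1,
            n_batches=2,
            grid=KernelGrid(values.shape, tuple(voxel)),
            seed=0,
        )

    return make
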