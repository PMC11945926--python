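"""Synthetic "virtual patient" phantoms: brain, tumor VOI and enhancement volume.

Each phantom emulates the products of contrast-enhanced T1-weighted imaging
and manual delineation that an intra-arterial dosimetry study starts from:

* an ellipsoidal **brain** mask on a regular voxel grid;
* a contiguous, irregular **PTV** (tumor) mask strictly inside the brain,
  built as a union of overlapping random spheres trimmed to the requested
  volume to within one voxel;
* optional spherical **organ-at-risk** masks disjoint from the PTV;
* an **intensity** volume where tumor voxels carry right-skewed (log-normal)
  contrast enhancement above a noisy background level — the statistical
  structure the intensity-as-activity-surrogate assumption relies on.

A cohort helper produces phantoms whose PTV/normal-brain volume ratios are
log-spaced over roughly an order of magnitude, mirroring the spread of
recurrence sizes over a small patient cohort.  Everything is deterministic
in the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "OrganAtRisk",
    "PhantomSpec",
    "StructureSet",
    "Phantom",
    "generate_phantom",
    "generate_cohort",
]


@dataclass(frozen=True)
class OrganAtRisk:
    name: str
    center_mm: tuple[float, float, float]  # relative to the brain center
    radius_mm: float


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic patient.

    Volumes are in cm³, lengths in mm.  ``intensity_sigma_log`` is the
    log-scale standard deviation of the within-VOI enhancement (0 gives a
    perfectly uniform tumor); ``enhancement_ratio`` the median tumor-to-
    background intensity ratio.
    """

    shape: tuple[int, int, int] = (192, 224, 160)
    voxel_size_mm: tuple[float, float, float] = (0.8, 0.8, 0.8)
    brain_semiaxes_mm: tuple[float, float, float] = (62.0, 78.0, 55.0)
    tumor_offset_mm: tuple[float, float, float] = (12.0, -18.0, 8.0)
    tumor_volume_cm3: float = 15.0
    tumor_shape: str = "lobed"  # "lobed" | "sphere"
    n_lobes: int = 5
    intensity_sigma_log: float = 0.5
    enhancement_ratio: float = 5.0
    background_level: float = 100.0
    background_noise_sd: float = 5.0
    oars: tuple[OrganAtRisk, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_volume_cm3 <= 0:
            raise ValueError("tumor volume must be positive")
        if self.tumor_shape not in ("lobed", "sphere"):
            raise ValueError("tumor_shape must be 'lobed' or 'sphere'")
        if self.intensity_sigma_log < 0 or self.background_level <= 0:
            raise ValueError("invalid intensity parameters")
        if not (1 <= self.n_lobes <= 12):
            raise ValueError("n_lobes out of range")


@dataclass
class StructureSet:
    """Named binary masks sharing one grid, with provenance metadata."""

    masks: dict[str, np.ndarray]
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("masks must share a single grid shape")
        for name in ("PTV", "Brain", "Brain-PTV"):
            if name not in self.masks:
                raise ValueError(f"required structure '{name}' missing")
        expected = self.masks["Brain"] & ~self.masks["PTV"]
        if not np.array_equal(self.masks["Brain-PTV"], expected):
            raise ValueError("Brain-PTV must equal Brain AND NOT PTV exactly")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size_mm)) * 1e-3

    def volume_cm3(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.voxel_volume_cm3

    @property
    def ptv_brain_ratio(self) -> float:
        """PTV volume over normal-brain (Brain-PTV) volume."""
        return float(self.masks["PTV"].sum()) / float(self.masks["Brain-PTV"].sum())


@dataclass
class Phantom:
    spec: PhantomSpec
    intensity: np.ndarray
    structures: StructureSet

    @property
    def ptv_brain_ratio(self) -> float:
        return self.structures.ptv_brain_ratio


def _axis_coords_mm(spec: PhantomSpec) -> list[np.ndarray]:
    """Per-axis voxel-center coordinates (mm) relative to the grid center."""
    return [
        (np.arange(s) - (s - 1) / 2.0) * v
        for s, v in zip(spec.shape, spec.voxel_size_mm)
    ]


def _ellipsoid_mask(coords: list[np.ndarray], center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    return (
        ((x - center[0]) / semiaxes[0]) ** 2
        + ((y - center[1]) / semiaxes[1]) ** 2
        + ((z - center[2]) / semiaxes[2]) ** 2
    ) <= 1.0


def _sphere_mask(coords: list[np.ndarray], center: np.ndarray, radius: float) -> np.ndarray:
    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    return ((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2) <= radius**2


def _tumor_mask(
    spec: PhantomSpec,
    coords: list[np.ndarray],
    tumor_center: np.ndarray,
    brain_interior: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Contiguous tumor mask of exactly the requested voxel count.

    A scalar field phi = min over lobes of (distance / lobe radius) is
    thresholded at the k-th smallest value inside the brain interior, so the
    voxel count is exact; the largest connected component is kept and trimmed
    back to k by dropping its largest-phi voxels if smaller satellites occur.
    """
    target = int(round(spec.tumor_volume_cm3 / (float(np.prod(spec.voxel_size_mm)) * 1e-3)))
    if target < 1:
        raise ValueError("tumor volume below one voxel")
    if target >= int(brain_interior.sum()):
        raise ValueError("tumor too large for brain")

    r0 = (3.0 * spec.tumor_volume_cm3 * 1e3 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    if spec.tumor_shape == "sphere":
        centers = tumor_center[None, :]
        radii = np.array([r0])
    else:
        n_lobes = spec.n_lobes
        offsets = rng.uniform(-0.45, 0.45, size=(n_lobes, 3)) * r0
        centers = tumor_center[None, :] + offsets
        radii = r0 * rng.uniform(0.7, 1.0, size=n_lobes)

    x, y, z = np.meshgrid(*coords, indexing="ij", sparse=True)
    phi = np.full(brain_interior.shape, np.inf)
    for c, rad in zip(centers, radii):
        d = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) / rad
        np.minimum(phi, d, out=phi)
    phi = np.where(brain_interior, phi, np.inf)

    flat = phi.ravel()
    pool = target
    for _ in range(10):
        idx = np.argpartition(flat, pool - 1)[:pool]
        mask = np.zeros(flat.size, dtype=bool)
        mask[idx] = True
        mask = mask.reshape(phi.shape)
        labels, n_comp = ndimage.label(mask)
        if n_comp == 1:
            break
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_comp + 1))
        keep = int(np.argmax(sizes)) + 1
        mask = labels == keep
        if mask.sum() >= target:
            break
        pool += target - int(mask.sum())
    count = int(mask.sum())
    if count > target:  # trim the outermost (largest-phi) voxels back to target
        inside = np.flatnonzero(mask.ravel())
        order = inside[np.argsort(flat[inside])]
        mask = np.zeros(flat.size, dtype=bool)
        mask[order[:target]] = True
        mask = mask.reshape(phi.shape)
    elif count < target:
        raise RuntimeError("could not realise a contiguous tumor of the requested volume")
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, StructureSet]:
    """Generate one phantom: (intensity volume, structure set).

    The PTV voxel count matches the requested volume to within one voxel;
    tumor intensities are log-normal around ``enhancement_ratio x background``;
    non-tumor brain sits at the background level with clipped Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    coords = _axis_coords_mm(spec)
    brain_center = np.zeros(3)
    semiaxes = np.asarray(spec.brain_semiaxes_mm, dtype=float)
    extent = np.array([c[-1] for c in coords])
    if np.any(semiaxes >= extent):
        raise ValueError("brain ellipsoid does not fit inside the grid")

    brain = _ellipsoid_mask(coords, brain_center, semiaxes)
    brain_interior = ndimage.binary_erosion(brain)
    tumor_center = brain_center + np.asarray(spec.tumor_offset_mm, dtype=float)
    ptv = _tumor_mask(spec, coords, tumor_center, brain_interior, rng)

    masks: dict[str, np.ndarray] = {
        "PTV": ptv,
        "Brain": brain,
        "Brain-PTV": brain & ~ptv,
    }
    for oar in spec.oars:
        m = _sphere_mask(coords, brain_center + np.asarray(oar.center_mm), oar.radius_mm)
        if not m.any():
            raise ValueError(f"OAR '{oar.name}' lies outside the grid")
        if (m & ptv).any():
            raise ValueError(f"OAR '{oar.name}' collides with the PTV")
        masks[oar.name] = m

    intensity = np.zeros(spec.shape, dtype=float)
    n_brain = int(brain.sum())
    intensity[brain] = np.clip(
        spec.background_level + rng.normal(0.0, spec.background_noise_sd, n_brain), 0.0, None
    )
    median_enh = spec.enhancement_ratio * spec.background_level
    intensity[ptv] = median_enh * np.exp(
        spec.intensity_sigma_log * rng.standard_normal(int(ptv.sum()))
    )

    affine = np.diag(list(spec.voxel_size_mm) + [1.0])
    structures = StructureSet(
        masks=masks,
        voxel_size_mm=spec.voxel_size_mm,
        affine=affine,
        provenance={"generator": "y90dose.phantom", "seed": spec.seed},
    )
    return intensity, structures


def generate_cohort(
    n: int,
    ratio_range: tuple[float, float] = (0.005, 0.15),
    seed: int = 0,
    base: PhantomSpec | None = None,
) -> list[Phantom]:
    """Generate ``n`` phantoms with log-spaced PTV/normal-brain volume ratios.

    Each phantom gets a distinct child seed derived from the master ``seed``;
    the tumor volume for ratio ``q`` is ``V_brain * q / (1 + q)`` so that
    PTV / (Brain - PTV) lands at ``q`` up to voxelization.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = ratio_range
    if not (0 < lo <= hi):
        raise ValueError("ratio range must be positive and ordered")
    base = base if base is not None else PhantomSpec()
    ratios = np.geomspace(lo, hi, n) if n > 1 else np.array([lo])
    child_seeds = (np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF).tolist()
    brain_vol_cm3 = 4.0 / 3.0 * np.pi * float(np.prod(base.brain_semiaxes_mm)) * 1e-3
    phantoms = []
    for q, s in zip(ratios, child_seeds):
        spec = replace(
            base,
            tumor_volume_cm3=brain_vol_cm3 * q / (1.0 + q),
            seed=int(s),
        )
        intensity, structures = generate_phantom(spec)
        phantoms.append(Phantom(spec=spec, intensity=intensity, structures=structures))
    return phantoms
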