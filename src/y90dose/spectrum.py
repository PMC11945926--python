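"""Beta emission spectra for the dose-kernel Monte Carlo.

:sup:`90`Y decays almost exclusively (>99.98%) through a single allowed
beta transition to the ground state of :sup:`90`Zr, with an endpoint energy
of 2.2801 MeV.  The emission spectrum is modelled with the allowed-transition
Fermi shape

.. math::

    f(E) \\propto p\\,W\\,(W_0 - W)^2\\,F(Z, W)

where ``W`` and ``p`` are the electron's total energy and momentum in units
of the electron rest mass, ``W_0`` the endpoint total energy, and ``F(Z, W)``
the (non-relativistic) Fermi Coulomb correction for the daughter nucleus
(Z = 40).  The spectrum is tabulated on a dense energy grid, so a published
tabulation can be substituted for the analytic shape by constructing a
:class:`BetaSpectrum` directly from ``(energies, density)`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BetaSpectrum",
    "fermi_beta_spectrum",
    "y90_spectrum",
    "sample_beta_energies",
    "Y90_ENDPOINT_MEV",
    "Y90_DAUGHTER_Z",
]

ELECTRON_MASS_MEV = 0.510998950
FINE_STRUCTURE_CONST = 7.2973525693e-3

#: Endpoint energy of the 90Y -> 90Zr ground-state beta branch (MeV).
Y90_ENDPOINT_MEV = 2.2801
#: Atomic number of the daughter nucleus (zirconium).
Y90_DAUGHTER_Z = 40


@dataclass(frozen=True)
class BetaSpectrum:
    """Tabulated beta emission spectrum, normalised to a unit integral.

    Parameters
    ----------
    energies_mev:
        Strictly increasing emission-energy grid in MeV; all values must be
        positive and the last entry is the spectrum endpoint.
    density:
        Non-negative probability density over ``energies_mev``.  It is
        renormalised so that the trapezoidal integral is exactly 1.
    emitter_label:
        Free-text identifier of the emitter (e.g. ``"Y-90"``).
    """

    energies_mev: np.ndarray
    density: np.ndarray
    emitter_label: str = "unknown"
    _cdf: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_mev, dtype=float)
        f = np.asarray(self.density, dtype=float)
        if e.ndim != 1 or f.ndim != 1 or e.shape != f.shape or e.size < 2:
            raise ValueError("energies and density must be matching 1-D arrays of length >= 2")
        if not np.all(np.diff(e) > 0) or e[0] <= 0:
            raise ValueError("energies must be strictly increasing and positive")
        if np.any(f < 0) or not np.all(np.isfinite(f)):
            raise ValueError("density must be finite and non-negative")
        norm = np.trapezoid(f, e)
        if norm <= 0:
            raise ValueError("density integrates to zero")
        f = f / norm
        # cumulative trapezoid, anchored at 0 for inverse-CDF sampling
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(e) * 0.5 * (f[1:] + f[:-1]))])
        cdf /= cdf[-1]
        object.__setattr__(self, "energies_mev", e)
        object.__setattr__(self, "density", f)
        object.__setattr__(self, "_cdf", cdf)

    @property
    def endpoint_mev(self) -> float:
        """Maximum emission energy (MeV)."""
        return float(self.energies_mev[-1])

    @property
    def mean_energy_mev(self) -> float:
        """Mean emission energy from deterministic quadrature of ``E f(E)``."""
        return float(np.trapezoid(self.energies_mev * self.density, self.energies_mev))

    def normalization_defect(self) -> float:
        """Absolute deviation of the tabulated integral from 1 (always ~0 after construction)."""
        return abs(float(np.trapezoid(self.density, self.energies_mev)) - 1.0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` emission energies (MeV) by inverse-CDF interpolation."""
        if n < 1:
            raise ValueError("n must be >= 1")
        u = rng.random(n)
        return np.interp(u, self._cdf, self.energies_mev)


def _fermi_function(z_daughter: int, w: np.ndarray) -> np.ndarray:
    """Non-relativistic Fermi Coulomb correction F(Z, W) for beta-minus decay."""
    p = np.sqrt(w * w - 1.0)
    eta = FINE_STRUCTURE_CONST * z_daughter * w / p
    x = 2.0 * np.pi * eta
    return x / -np.expm1(-x)


def fermi_beta_spectrum(
    endpoint_mev: float,
    z_daughter: int,
    n_points: int = 400,
    label: str = "beta-",
) -> BetaSpectrum:
    """Build an allowed-shape beta spectrum with the Fermi Coulomb correction.

    The shape is ``p W (W0 - W)^2 F(Z, W)`` evaluated on ``n_points`` energies
    spanning (0, endpoint]; normalisation is handled by :class:`BetaSpectrum`.
    """
    if endpoint_mev <= 0:
        raise ValueError("endpoint must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    e = np.linspace(endpoint_mev / n_points, endpoint_mev, n_points)
    w = 1.0 + e / ELECTRON_MASS_MEV
    w0 = 1.0 + endpoint_mev / ELECTRON_MASS_MEV
    p = np.sqrt(w * w - 1.0)
    shape = p * w * (w0 - w) ** 2 * _fermi_function(z_daughter, w)
    shape[-1] = 0.0  # density vanishes at the endpoint
    return BetaSpectrum(e, shape, emitter_label=label)


def y90_spectrum(n_points: int = 400) -> BetaSpectrum:
    """The default 90Y spectrum (allowed Fermi shape, endpoint 2.2801 MeV, Z=40)."""
    return fermi_beta_spectrum(Y90_ENDPOINT_MEV, Y90_DAUGHTER_Z, n_points, label="Y-90")


def sample_beta_energies(spectrum: BetaSpectrum, n: int, seed: int) -> np.ndarray:
    """Sample ``n`` emission energies (MeV) reproducibly from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return spectrum.sample(n, rng)
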