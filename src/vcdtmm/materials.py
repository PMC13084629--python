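"""Dispersive chiral material models.

An isotropic chiral (Pasteur) medium is described by three scalar,
frequency-dependent constitutive parameters: the permittivity ``eps``, the
permeability ``mu`` (unity for molecular films) and the chirality parameter
``kappa``.  The two circular-polarization eigenmodes propagate with refractive
indices ``n_pm = sqrt(eps * mu) +/- kappa``; the impedance ``eta =
sqrt(mu / eps)`` is helicity-independent.

Conventions used throughout the package:

* wavenumbers ``nu`` in cm^-1, strictly positive;
* time dependence ``exp(-i omega t)``, so passive absorption means
  ``Im eps >= 0`` and ``Im n >= 0``;
* ``sqrt(eps * mu)`` is taken on the branch with ``Im >= 0`` (forward waves
  decay), ``sqrt(mu / eps)`` on the branch with ``Re >= 0`` (passive
  impedance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Oscillator",
    "OscillatorSet",
    "DispersionTable",
    "ChiralMaterial",
    "lorentz_permittivity",
    "pasteur_chirality",
    "eigen_indices",
    "ideal_absorber",
    "IDEAL_ABSORBER_OSCILLATORS",
    "vacuum",
]


class Oscillator(NamedTuple):
    """A single Lorentzian resonance (wavenumber units, cm^-1)."""

    nu_0: float
    f: float
    gamma: float


@dataclass(frozen=True)
class OscillatorSet:
    """Parameters of a multi-oscillator Lorentzian dispersion model.

    ``eps_inf`` is the high-frequency permittivity, ``nu_p`` an effective
    plasma wavenumber shared by all oscillators, and ``kappa_0`` the
    dimensionless scale of the chiral response.
    """

    eps_inf: float
    nu_p: float
    kappa_0: float
    oscillators: tuple[Oscillator, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.eps_inf < 1.0:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if self.nu_p <= 0.0:
            raise ValueError(f"nu_p must be > 0, got {self.nu_p}")
        osc = tuple(Oscillator(*o) for o in self.oscillators)
        for j, o in enumerate(osc):
            if o.nu_0 <= 0.0:
                raise ValueError(f"oscillator {j}: nu_0 must be > 0, got {o.nu_0}")
            if o.gamma <= 0.0:
                raise ValueError(f"oscillator {j}: gamma must be > 0, got {o.gamma}")
            if o.f < 0.0:
                raise ValueError(f"oscillator {j}: f must be >= 0, got {o.f}")
        object.__setattr__(self, "oscillators", osc)

    def with_kappa_0(self, kappa_0: float) -> "OscillatorSet":
        """Return a copy with a different chirality scale."""
        return replace(self, kappa_0=kappa_0)


def _check_wavenumbers(nu: np.ndarray) -> np.ndarray:
    nu = np.asarray(nu, dtype=float)
    if np.any(nu <= 0.0):
        raise ValueError("wavenumbers must be strictly positive (cm^-1)")
    return nu


def lorentz_permittivity(osc: OscillatorSet, nu) -> np.ndarray:
    """Complex permittivity of a Lorentzian oscillator series.

    eps(nu) = eps_inf + sum_j f_j nu_p^2 / (nu_0j^2 - nu^2 - i gamma_j nu)

    With the exp(-i omega t) convention this yields Im eps >= 0 for nu > 0.
    """
    nu = _check_wavenumbers(nu)
    eps = np.full(nu.shape, osc.eps_inf, dtype=complex)
    for nu_0, f, gamma in osc.oscillators:
        eps += f * osc.nu_p**2 / (nu_0**2 - nu**2 - 1j * gamma * nu)
    return eps


def pasteur_chirality(osc: OscillatorSet, nu) -> np.ndarray:
    """Complex Pasteur parameter of the same oscillator series.

    kappa(nu) = kappa_0 sum_j f_j nu_p^2 nu / [nu_0j (nu_0j^2 - nu^2 - i gamma_j nu)]

    Re kappa carries optical rotation, Im kappa circular dichroism; the
    result is odd in ``kappa_0`` (enantiomer sign flip).
    """
    nu = _check_wavenumbers(nu)
    kappa = np.zeros(nu.shape, dtype=complex)
    for nu_0, f, gamma in osc.oscillators:
        kappa += f * osc.nu_p**2 * nu / (nu_0 * (nu_0**2 - nu**2 - 1j * gamma * nu))
    return osc.kappa_0 * kappa


def sqrt_im_nonneg(z) -> np.ndarray:
    """Square root on the branch with non-negative imaginary part."""
    w = np.sqrt(np.asarray(z, dtype=complex))
    return np.where(w.imag < 0.0, -w, w)


def sqrt_re_nonneg(z) -> np.ndarray:
    """Square root on the branch with non-negative real part."""
    w = np.sqrt(np.asarray(z, dtype=complex))
    return np.where(w.real < 0.0, -w, w)


@dataclass(frozen=True)
class DispersionTable:
    """Tabulated complex dispersion on a strictly increasing wavenumber grid.

    Queries between grid points interpolate real and imaginary parts
    linearly; queries outside the tabulated range raise (no extrapolation).
    """

    nu_grid: np.ndarray
    eps: np.ndarray
    kappa: np.ndarray
    mu: np.ndarray | None = None

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu_grid, dtype=float)
        eps = np.asarray(self.eps, dtype=complex)
        kappa = np.asarray(self.kappa, dtype=complex)
        mu = np.ones_like(eps) if self.mu is None else np.asarray(self.mu, dtype=complex)
        if nu.ndim != 1 or nu.size < 2:
            raise ValueError("nu_grid must be 1-D with at least 2 points")
        if not (eps.shape == kappa.shape == mu.shape == nu.shape):
            raise ValueError("eps, kappa, mu must match nu_grid in shape")
        if np.any(np.diff(nu) <= 0.0):
            raise ValueError("nu_grid must be strictly increasing")
        if np.any(eps.imag < 0.0):
            raise ValueError("Im eps < 0 on the grid: medium must be passive")
        object.__setattr__(self, "nu_grid", nu)
        object.__setattr__(self, "eps", eps)
        object.__setattr__(self, "kappa", kappa)
        object.__setattr__(self, "mu", mu)

    def interpolate(self, nu) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nu = _check_wavenumbers(nu)
        lo, hi = self.nu_grid[0], self.nu_grid[-1]
        if np.any(nu < lo) or np.any(nu > hi):
            raise ValueError(
                f"query wavenumbers outside tabulated range [{lo}, {hi}] cm^-1"
            )

        def lerp(values: np.ndarray) -> np.ndarray:
            re = np.interp(nu, self.nu_grid, values.real)
            im = np.interp(nu, self.nu_grid, values.imag)
            return re + 1j * im

        return lerp(self.eps), lerp(self.mu), lerp(self.kappa)


class ChiralMaterial:
    """Evaluable (eps, mu, kappa) provider for one isotropic chiral medium.

    Construct from an :class:`OscillatorSet`, a :class:`DispersionTable` or
    constant values; :meth:`evaluate` returns the three constitutive
    parameters on any positive wavenumber grid.
    """

    def __init__(self, source: OscillatorSet | DispersionTable | tuple, name: str = ""):
        if isinstance(source, (OscillatorSet, DispersionTable)):
            self.source = source
        else:
            eps, mu, kappa = source
            self.source = (complex(eps), complex(mu), complex(kappa))
        self.name = name

    @classmethod
    def from_oscillators(cls, osc: OscillatorSet, name: str = "") -> "ChiralMaterial":
        return cls(osc, name=name)

    @classmethod
    def from_table(cls, table: DispersionTable, name: str = "") -> "ChiralMaterial":
        return cls(table, name=name)

    @classmethod
    def from_constants(cls, eps, mu=1.0, kappa=0.0, name: str = "") -> "ChiralMaterial":
        return cls((eps, mu, kappa), name=name)

    def evaluate(self, nu) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(eps, mu, kappa)`` arrays broadcast to the shape of ``nu``."""
        nu = _check_wavenumbers(nu)
        if isinstance(self.source, OscillatorSet):
            eps = lorentz_permittivity(self.source, nu)
            kappa = pasteur_chirality(self.source, nu)
            mu = np.ones_like(eps)
            return eps, mu, kappa
        if isinstance(self.source, DispersionTable):
            return self.source.interpolate(nu)
        eps0, mu0, kappa0 = self.source
        shape = np.shape(nu)
        return (
            np.full(shape, eps0, dtype=complex),
            np.full(shape, mu0, dtype=complex),
            np.full(shape, kappa0, dtype=complex),
        )

    def impedance(self, nu) -> np.ndarray:
        """Relative impedance eta = sqrt(mu/eps), branch Re eta >= 0."""
        eps, mu, _ = self.evaluate(nu)
        return sqrt_re_nonneg(mu / eps)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        label = self.name or type(self.source).__name__
        return f"ChiralMaterial({label})"


def eigen_indices(material: ChiralMaterial, nu) -> tuple[np.ndarray, np.ndarray]:
    """Circular-eigenmode refractive indices ``n_pm = sqrt(eps mu) +/- kappa``.

    The square root of ``eps * mu`` is taken with ``Im >= 0`` so that forward
    waves decay in a passive medium.
    """
    eps, mu, kappa = material.evaluate(nu)
    n_bar = sqrt_im_nonneg(eps * mu)
    return n_bar + kappa, n_bar - kappa


# Equidistant Lorentzian oscillator rows (nu_0 cm^-1, f, gamma cm^-1) chosen so
# the thin-film Beer-Lambert spectrum shows evenly spaced, equal-height bands.
IDEAL_ABSORBER_OSCILLATORS: tuple[Oscillator, ...] = (
    Oscillator(500.0, 0.3000, 26.91),
    Oscillator(1000.0, 0.4119, 37.17),
    Oscillator(1500.0, 0.6374, 57.56),
    Oscillator(2000.0, 0.2882, 26.18),
    Oscillator(2500.0, 0.5695, 51.47),
    Oscillator(3000.0, 0.2043, 18.51),
    Oscillator(3500.0, 0.3678, 33.28),
    Oscillator(4000.0, 0.5413, 48.91),
)

_IDEAL_EPS_INF = 2.15
_IDEAL_NU_P = 107.0
_IDEAL_KAPPA_0 = 1.0e-5


def ideal_absorber(kappa_0: float = _IDEAL_KAPPA_0) -> ChiralMaterial:
    """Packaged eight-band ideal-absorber preset.

    Defaults reproduce the reference parameter set (eps_inf = 2.15,
    nu_p = 107 cm^-1, kappa_0 = 1e-5); pass ``kappa_0=0`` for the achiral
    twin or a negative value for the enantiomer.
    """
    osc = OscillatorSet(
        eps_inf=_IDEAL_EPS_INF,
        nu_p=_IDEAL_NU_P,
        kappa_0=kappa_0,
        oscillators=IDEAL_ABSORBER_OSCILLATORS,
    )
    return ChiralMaterial.from_oscillators(osc, name="ideal_absorber")


def vacuum() -> ChiralMaterial:
    """Non-dispersive ambient with eps = mu = 1, kappa = 0."""
    return ChiralMaterial.from_constants(1.0, 1.0, 0.0, name="vacuum")
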