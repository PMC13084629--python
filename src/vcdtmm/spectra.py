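"""Absorbance, VCD and artifact-decomposition observables.

All absorbances are decadic (A = -log10 T) and VCD is reported in the same
units, VCD = -log10(T_-/T_+) = A_- - A_+.  The sign convention makes VCD
negative at absorption bands where Im kappa > 0.

The decomposition maps contrast three progressively simplified models of the
same stack:

* ``vcd_full``     - full 4x4 transfer-matrix result (interference and
                     helicity coupling included);
* ``vcd_parallel`` - copolarized-only result, cross terms t_+- = t_-+ zeroed
                     (interference without helicity coupling);
* ``vcd_bl``       - Beer-Lambert baseline from the layer material alone
                     with slant path d / cos(theta_in).

Relative deviations (vcd_bl - vcd_parallel)/vcd_bl and
(vcd_full - vcd_parallel)/vcd_bl isolate the interference and coupling
artifacts respectively; cells where the baseline is too close to zero for
the ratio to be meaningful are masked (NaN) rather than reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .materials import ChiralMaterial, eigen_indices
from .tmm import (
    JonesT2,
    Stack,
    UM_TO_CM,
    helicity_transmittances,
    stack_jones,
)

__all__ = [
    "SpectrumSet",
    "AngularMap",
    "absorbance",
    "beer_lambert_absorbance",
    "vcd_from_transmittances",
    "vcd_alternative",
    "beer_lambert_vcd",
    "copolarized_vcd",
    "compute_spectrum",
    "deviation_maps",
]

LN10 = np.log(10.0)


def _masked_log10(x: np.ndarray, what: str) -> np.ndarray:
    """-log10 with non-positive inputs masked to NaN (never clamped)."""
    x = np.asarray(x, dtype=float)
    bad = ~(x > 0.0)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} non-positive {what} value(s) masked "
            "(total extinction or numerical underflow)",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.log10(np.where(bad, np.nan, x))
    return out


def absorbance(T) -> np.ndarray:
    """Decadic absorbance A = -log10 T; T <= 0 masked with a warning."""
    return _masked_log10(T, "transmittance")


def _check_geometry(d_um: float, theta_deg: float) -> float:
    if d_um <= 0.0:
        raise ValueError(f"thickness must be > 0 um, got {d_um}")
    if not 0.0 <= theta_deg < 90.0:
        raise ValueError(f"incidence angle must be in [0, 90) deg, got {theta_deg}")
    return np.cos(np.deg2rad(theta_deg))


def beer_lambert_absorbance(n_imag, d_um: float, nu, theta_deg: float = 0.0) -> np.ndarray:
    """Beer-Lambert decadic absorbance A = 4 pi nu n'' (d / cos theta) / ln 10.

    ``theta_deg`` is the incidence angle; oblique paths scale the optical
    thickness by 1/cos(theta).
    """
    cos_t = _check_geometry(d_um, theta_deg)
    nu = np.asarray(nu, dtype=float)
    path_cm = d_um * UM_TO_CM / cos_t
    return 4.0 * np.pi * nu * np.asarray(n_imag, dtype=float) * path_cm / LN10


def vcd_from_transmittances(T_plus, T_minus) -> np.ndarray:
    """VCD = -log10(T_-/T_+) = A_- - A_+ (decadic units)."""
    return _masked_log10(T_minus, "T_minus") - _masked_log10(T_plus, "T_plus")


def vcd_alternative(T_plus, T_minus) -> np.ndarray:
    """Alternative VCD measure dT / mean(T) with dT = T_+ - T_-.

    For |dT| << mean(T) this equals ln(10) times the log-ratio definition to
    first order; it is exposed under its own name and never silently
    substituted for the decadic definition.
    """
    T_plus = np.asarray(T_plus, dtype=float)
    T_minus = np.asarray(T_minus, dtype=float)
    mean = 0.5 * (T_plus + T_minus)
    bad = ~(mean > 0.0)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} cell(s) with non-positive mean transmittance masked",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(bad, np.nan, (T_plus - T_minus) / mean)


def beer_lambert_vcd(
    material: ChiralMaterial, d_um: float, nu, theta_deg: float = 0.0
) -> np.ndarray:
    """Beer-Lambert baseline VCD of a single layer.

    Forms the per-helicity absorbances from n''_pm = Im[sqrt(eps mu) +/- kappa]
    via the slant-path Beer-Lambert law and takes the decadic log-ratio.
    Algebraically this collapses to
    VCD_BL = 4 pi nu (d / cos theta) (n''_- - n''_+) / ln 10
           = -8 pi nu (d / cos theta) Im(kappa) / ln 10.
    """
    n_p, n_m = eigen_indices(material, nu)
    A_p = beer_lambert_absorbance(n_p.imag, d_um, nu, theta_deg)
    A_m = beer_lambert_absorbance(n_m.imag, d_um, nu, theta_deg)
    return A_m - A_p


def copolarized_vcd(t: JonesT2) -> np.ndarray:
    """VCD with helicity conversion suppressed: T_pm = |t_pmpm|^2 only."""
    return vcd_from_transmittances(np.abs(t.t_pp) ** 2, np.abs(t.t_mm) ** 2)


@dataclass(frozen=True)
class SpectrumSet:
    """Helicity-resolved transmittance/absorbance spectra plus VCD."""

    nu_grid: np.ndarray
    T_plus: np.ndarray
    T_minus: np.ndarray
    A_plus: np.ndarray
    A_minus: np.ndarray
    vcd: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.nu_grid).size
        for name in ("T_plus", "T_minus", "A_plus", "A_minus", "vcd"):
            if np.asarray(getattr(self, name)).size != n:
                raise ValueError(f"{name} does not match the wavenumber grid length")


def compute_spectrum(stack: Stack, nu, theta_deg: float = 0.0) -> SpectrumSet:
    """Full-pipeline spectrum of a stack at one incidence angle."""
    nu = np.asarray(nu, dtype=float)
    t = stack_jones(stack, nu, theta_deg)
    T_p, T_m = helicity_transmittances(t)
    A_p = absorbance(T_p)
    A_m = absorbance(T_m)
    return SpectrumSet(
        nu_grid=nu, T_plus=T_p, T_minus=T_m, A_plus=A_p, A_minus=A_m, vcd=A_m - A_p
    )


@dataclass(frozen=True)
class AngularMap:
    """(theta, nu) maps of the three VCD models and their deviations.

    2-D arrays are indexed [theta, nu].  ``mask`` is True where the
    Beer-Lambert baseline magnitude falls below the configured floor and the
    relative deviations are therefore undefined (set to NaN there).
    """

    theta_grid: np.ndarray
    nu_grid: np.ndarray
    vcd_bl: np.ndarray
    vcd_parallel: np.ndarray
    vcd_full: np.ndarray
    dev_itf: np.ndarray
    dev_cpl: np.ndarray
    mask: np.ndarray


def deviation_maps(
    stack: Stack,
    theta_grid,
    nu_grid,
    floor: float = 1.0e-3,
) -> AngularMap:
    """Angular-spectral decomposition of VCD into interference and coupling.

    ``floor`` masks cells where |vcd_bl| < floor * max|vcd_bl| (the baseline
    changes sign inside each band, and the normalized deviations blow up at
    its zero crossings).  The Beer-Lambert baseline uses the total layer
    thickness of the stack and the material of its first layer.
    """
    theta_grid = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    nu_grid = np.asarray(nu_grid, dtype=float)
    if theta_grid.size == 0 or nu_grid.size == 0:
        raise ValueError("theta_grid and nu_grid must be non-empty")
    if floor <= 0.0:
        raise ValueError(f"floor must be > 0, got {floor}")
    if not stack.layers:
        raise ValueError("deviation maps need at least one layer")
    material = stack.layers[0].material
    d_um = sum(ly.thickness_um for ly in stack.layers)

    shape = (theta_grid.size, nu_grid.size)
    vcd_bl = np.empty(shape)
    vcd_par = np.empty(shape)
    vcd_full = np.empty(shape)
    for i, theta in enumerate(theta_grid):
        t = stack_jones(stack, nu_grid, theta)
        T_p, T_m = helicity_transmittances(t)
        vcd_full[i] = vcd_from_transmittances(T_p, T_m)
        vcd_par[i] = copolarized_vcd(t)
        vcd_bl[i] = beer_lambert_vcd(material, d_um, nu_grid, theta)

    bl_max = np.nanmax(np.abs(vcd_bl))
    if bl_max == 0.0:
        mask = np.ones(shape, dtype=bool)  # identically zero baseline
    else:
        mask = ~(np.abs(vcd_bl) >= floor * bl_max)
    if mask.all():
        warnings.warn(
            "all map cells masked: Beer-Lambert baseline is identically "
            "negligible (achiral material?)",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_itf = np.where(mask, np.nan, (vcd_bl - vcd_par) / vcd_bl)
        dev_cpl = np.where(mask, np.nan, (vcd_full - vcd_par) / vcd_bl)
    return AngularMap(
        theta_grid=theta_grid,
        nu_grid=nu_grid,
        vcd_bl=vcd_bl,
        vcd_parallel=vcd_par,
        vcd_full=vcd_full,
        dev_itf=dev_itf,
        dev_cpl=dev_cpl,
        mask=mask,
    )
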