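"""Independent reference implementations used as test oracles.

These deliberately avoid the package's 4x4 matrix machinery: the scalar
transfer matrix is the textbook 2x2 method with s/p Fresnel coefficients,
and the slab transmission is the Airy multiple-reflection geometric series.
Conventions match the package (time dependence exp(-i omega t), forward
fields ~ exp(+i k z), wavenumbers cm^-1, thicknesses converted to cm).
"""

from __future__ import annotations

import numpy as np


def _cos_transmitted(n1, n2, theta_deg):
    theta = np.deg2rad(theta_deg)
    c1 = np.cos(theta) * np.ones_like(np.asarray(n2, dtype=complex))
    s = n1 * np.sin(theta)
    c2 = np.sqrt((1.0 - (s / n2) ** 2).astype(complex))
    kz = n2 * c2
    c2 = np.where((kz.imag < 0) | ((kz.imag == 0) & (kz.real < 0)), -c2, c2)
    return c1, c2


def fresnel(n1, n2, c1, c2, pol: str):
    """Amplitude (r, t) for incidence 1 -> 2 at the given polarization."""
    if pol == "s":
        den = n1 * c1 + n2 * c2
        return (n1 * c1 - n2 * c2) / den, 2.0 * n1 * c1 / den
    den = n2 * c1 + n1 * c2
    return (n2 * c1 - n1 * c2) / den, 2.0 * n1 * c1 / den


def scalar_slab_amplitudes(n1, n2, n3, d_um, nu, theta_deg, pol):
    """(t, r) of an isotropic slab via the scalar 2x2 transfer matrix."""
    nu = np.asarray(nu, dtype=float)
    d_cm = d_um * 1.0e-4
    c1, c2 = _cos_transmitted(n1, n2, theta_deg)
    # transmitted cosine in the exit medium shares the invariant n1 sin(theta)
    _, c3 = _cos_transmitted(n1, n3, theta_deg)
    r12, t12 = fresnel(n1, n2, c1, c2, pol)
    r23, t23 = fresnel(n2, n3, c2, c3, pol)
    phi = 2.0 * np.pi * nu * n2 * c2 * d_cm

    def iface(r, t):
        m = np.empty(np.shape(r) + (2, 2), dtype=complex)
        m[..., 0, 0] = 1.0
        m[..., 0, 1] = r
        m[..., 1, 0] = r
        m[..., 1, 1] = 1.0
        return m / t[..., None, None]

    prop = np.zeros(np.shape(phi) + (2, 2), dtype=complex)
    prop[..., 0, 0] = np.exp(-1j * phi)
    prop[..., 1, 1] = np.exp(1j * phi)
    m = iface(r12, t12) @ prop @ iface(r23, t23)
    t = 1.0 / m[..., 0, 0]
    r = m[..., 1, 0] * t
    return t, r


def scalar_slab_transmittance_unpolarized(n1, n2, n3, d_um, nu, theta_deg):
    """Mean of the s- and p-polarized intensity transmittances."""
    ts, _ = scalar_slab_amplitudes(n1, n2, n3, d_um, nu, theta_deg, "s")
    tp, _ = scalar_slab_amplitudes(n1, n2, n3, d_um, nu, theta_deg, "p")
    return 0.5 * (np.abs(ts) ** 2 + np.abs(tp) ** 2)


def airy_chiral_slab_normal(eps, mu, kappa, d_um, nu):
    """(t_pp, t_mm) of a chiral slab in vacuum at normal incidence.

    Multiple-reflection (Airy) series: the Fresnel factors are set by the
    helicity-independent impedance eta = sqrt(mu/eps), the single-pass phases
    by n_pm = sqrt(eps mu) +/- kappa, and each internal reflection flips
    helicity so the round-trip phase is phi_+ + phi_-.
    """
    nu = np.asarray(nu, dtype=float)
    d_cm = d_um * 1.0e-4
    n_bar = np.sqrt(np.asarray(eps * mu, dtype=complex))
    n_bar = np.where(n_bar.imag < 0, -n_bar, n_bar)
    eta = np.sqrt(np.asarray(mu, dtype=complex) / np.asarray(eps, dtype=complex))
    eta = np.where(eta.real < 0, -eta, eta)
    n_p, n_m = n_bar + kappa, n_bar - kappa
    r = (eta - 1.0) / (eta + 1.0)  # vacuum -> slab, squared below so sign-free
    t_in = 2.0 * eta / (1.0 + eta)
    t_out = 2.0 * 1.0 / (1.0 + eta)
    phi_p = 2.0 * np.pi * nu * n_p * d_cm
    phi_m = 2.0 * np.pi * nu * n_m * d_cm
    denom = 1.0 - r**2 * np.exp(1j * (phi_p + phi_m))
    t_pp = t_in * t_out * np.exp(1j * phi_p) / denom
    t_mm = t_in * t_out * np.exp(1j * phi_m) / denom
    return t_pp, t_mm


def lorentz_eps_direct(eps_inf, nu_p, rows, nu):
    """Straightforward per-term Lorentzian permittivity summation."""
    nu = np.asarray(nu, dtype=float)
    total = np.zeros(nu.shape, dtype=complex) + eps_inf
    for nu_0, f, gamma in rows:
        total = total + f * nu_p**2 / (nu_0**2 - nu**2 - 1j * gamma * nu)
    return total


def pasteur_kappa_direct(kappa_0, nu_p, rows, nu):
    """Straightforward per-term Pasteur chirality summation."""
    nu = np.asarray(nu, dtype=float)
    total = np.zeros(nu.shape, dtype=complex)
    for nu_0, f, gamma in rows:
        total = total + f * nu_p**2 * nu / (nu_0 * (nu_0**2 - nu**2 - 1j * gamma * nu))
    return kappa_0 * total
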