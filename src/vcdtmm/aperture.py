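"""Incoherent plane-wave averaging over illumination/collection cones.

Focused illumination is modeled as an incoherent superposition of plane waves
with incidence angles uniformly sampled in theta within the illumination
cone; the collection optics accept transmitted rays within the detection
cone.  For the symmetric ambient/exit configuration the transmitted angle
equals the incident one, so the double angular sum collapses to a single sum
over theta in [0, min(theta_max_in, theta_max_out)] — the implementation uses
this reduction whenever the two half-spaces have identical optical response.

VCD under focused illumination is average-then-log: the helicity
transmittances are averaged over the cone first and the decadic log-ratio is
taken afterwards (the order matters for thick films and is fixed by
contract).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import vcd_from_transmittances
from .tmm import Stack, stack_transmittances

__all__ = ["ApertureConfig", "na_averaged_transmittances", "na_averaged_vcd"]


@dataclass(frozen=True)
class ApertureConfig:
    """Illumination/collection numerical apertures and angular sampling.

    ``n_in``/``n_out`` angular samples are uniform in theta and always
    include theta = 0.
    """

    na_in: float
    na_out: float
    n_in: int = 64
    n_out: int = 64
    solid_angle_weighted: bool = False

    def __post_init__(self) -> None:
        for name in ("na_in", "na_out"):
            na = getattr(self, name)
            if not 0.0 < na < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {na}")
        for name in ("n_in", "n_out"):
            n = getattr(self, name)
            if n < 1:
                raise ValueError(f"{name} must be >= 1, got {n}")

    @property
    def theta_max_in(self) -> float:
        return float(np.rad2deg(np.arcsin(self.na_in)))

    @property
    def theta_max_out(self) -> float:
        return float(np.rad2deg(np.arcsin(self.na_out)))


def _thetas(theta_max_deg: float, n: int) -> np.ndarray:
    if n == 1:
        return np.array([0.0])
    return np.linspace(0.0, theta_max_deg, n)


def _weights(thetas: np.ndarray, solid_angle: bool) -> np.ndarray:
    """Per-sample weights: uniform mean by default, sin(theta)-weighted on request."""
    if solid_angle:
        w = np.sin(np.deg2rad(thetas))
        if w.sum() > 0.0:
            return w / w.sum()
    return np.full(thetas.size, 1.0 / thetas.size)


def _media_match(stack: Stack, nu: np.ndarray) -> bool:
    if stack.ambient is stack.exit:
        return True
    probe = np.array([nu.min(), nu.max()]) if nu.size > 1 else nu
    a = stack.ambient.evaluate(probe)
    b = stack.exit.evaluate(probe)
    return all(np.array_equal(x, y) for x, y in zip(a, b))


def na_averaged_transmittances(
    stack: Stack, nu_grid, cfg: ApertureConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Cone-averaged helicity transmittances (mean over sampled angles).

    Symmetric stacks average over the single cone bounded by the smaller
    aperture.  For asymmetric half-spaces every illumination angle is
    propagated and a ray contributes only where its transmitted angle falls
    inside the collection cone (rejected rays count as zero transmittance).
    """
    nu = np.asarray(nu_grid, dtype=float)
    if _media_match(stack, nu):
        theta_max = min(cfg.theta_max_in, cfg.theta_max_out)
        thetas = _thetas(theta_max, cfg.n_in)
        weights = _weights(thetas, cfg.solid_angle_weighted)
        acc_p = np.zeros(nu.shape)
        acc_m = np.zeros(nu.shape)
        for theta, w in zip(thetas, weights):
            T_p, T_m = stack_transmittances(stack, nu, theta)
            acc_p += w * T_p
            acc_m += w * T_m
        return acc_p, acc_m

    # Asymmetric fallback: acceptance test per transmitted angle.  The
    # transmitted direction follows from the conserved in-plane invariant,
    # sin(theta_out) = Re(n_in) sin(theta_in) / Re(n_out), per wavenumber.
    from .materials import eigen_indices

    thetas = _thetas(cfg.theta_max_in, cfg.n_in)
    weights = _weights(thetas, cfg.solid_angle_weighted)
    n_in_p, n_in_m = eigen_indices(stack.ambient, nu)
    n_out_p, n_out_m = eigen_indices(stack.exit, nu)
    n_in_re = 0.5 * (n_in_p + n_in_m).real
    n_out_re = 0.5 * (n_out_p + n_out_m).real
    sin_max_out = float(np.sin(np.deg2rad(cfg.theta_max_out)))
    acc_p = np.zeros(nu.shape)
    acc_m = np.zeros(nu.shape)
    for theta, w in zip(thetas, weights):
        T_p, T_m = stack_transmittances(stack, nu, theta)
        sin_out = n_in_re * np.sin(np.deg2rad(theta)) / n_out_re
        accepted = np.abs(sin_out) <= sin_max_out
        acc_p += w * np.where(accepted, T_p, 0.0)
        acc_m += w * np.where(accepted, T_m, 0.0)
    return acc_p, acc_m


def na_averaged_vcd(stack: Stack, nu_grid, cfg: ApertureConfig) -> np.ndarray:
    """VCD of the cone-averaged transmittances (average-then-log)."""
    T_p, T_m = na_averaged_transmittances(stack, nu_grid, cfg)
    return vcd_from_transmittances(T_p, T_m)
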