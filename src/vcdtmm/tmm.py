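"""4x4 transfer-matrix assembly for stratified isotropic chiral media.

Field amplitudes are ordered ``(E_fwd_plus, E_fwd_minus, E_bwd_plus,
E_bwd_minus)`` where +/- label the circular-polarization eigenmodes.  The
transfer matrix maps exit-side amplitudes to entrance-side amplitudes, so the
2x2 circular-basis transmission operator for incidence from the entrance side
is the inverse of the upper-left block, and the reflection operator is
(lower-left block) @ (upper-left block)^-1.

With the exp(-i omega t) time convention a forward wave is E(z) ~ exp(+i k z)
with Im k >= 0; propagation over a layer therefore contributes exp(-i phi) on
the forward diagonal of the (exit -> entrance) transfer matrix, and the
physical transmission amplitude carries the decaying factor exp(+i phi).

All operations are vectorized over the wavenumber grid: matrices are stacked
as arrays of shape (n_nu, 4, 4), Jones blocks as (n_nu, 2, 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .materials import ChiralMaterial, eigen_indices, vacuum

__all__ = [
    "Layer",
    "Stack",
    "AngleState",
    "TransferMatrix4",
    "JonesT2",
    "SingularGeometryError",
    "ConditioningError",
    "refract",
    "angle_state",
    "interface_matrices",
    "propagation_matrix",
    "total_transfer",
    "transmission_reflection",
    "helicity_transmittances",
    "stack_jones",
    "stack_transmittances",
    "single_layer_stack",
]

# 2 pi nu n d phases need d in cm when nu is in cm^-1
UM_TO_CM = 1.0e-4

# Im(phi) beyond this would overflow exp() in the backward block; the forward
# physical transmission is ~1e-300 there anyway.
_PHASE_CLIP = 690.0


class SingularGeometryError(ValueError):
    """Grazing geometry: a cos(theta) in the entrance medium vanished."""


class ConditioningError(ArithmeticError):
    """The upper-left transfer block is numerically singular."""


@dataclass(frozen=True)
class Layer:
    """Homogeneous chiral layer of finite thickness (micrometres)."""

    material: ChiralMaterial
    thickness_um: float

    def __post_init__(self) -> None:
        if self.thickness_um <= 0.0:
            raise ValueError(f"layer thickness must be > 0, got {self.thickness_um}")


@dataclass(frozen=True)
class Stack:
    """Ambient half-space, zero or more layers, exit half-space."""

    ambient: ChiralMaterial
    layers: tuple[Layer, ...]
    exit: ChiralMaterial

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))


def single_layer_stack(
    material: ChiralMaterial,
    thickness_um: float,
    ambient: ChiralMaterial | None = None,
    exit: ChiralMaterial | None = None,
) -> Stack:
    """Air | layer | air stack, the workhorse geometry."""
    amb = ambient if ambient is not None else vacuum()
    ext = exit if exit is not None else amb
    return Stack(ambient=amb, layers=(Layer(material, thickness_um),), exit=ext)


@dataclass(frozen=True)
class AngleState:
    """Per-medium complex propagation angles for both helicities.

    ``cos_plus/minus`` are the cosines of the (generally complex) propagation
    angles; ``k_plus/minus = 2 pi nu n_pm`` in rad cm^-1.  The evanescent
    flags mark wavenumbers where the refracted wave is non-propagating.
    """

    n_plus: np.ndarray
    n_minus: np.ndarray
    cos_plus: np.ndarray
    cos_minus: np.ndarray
    k_plus: np.ndarray = field(repr=False, kw_only=True)
    k_minus: np.ndarray = field(repr=False, kw_only=True)
    evanescent_plus: np.ndarray = field(repr=False, kw_only=True)
    evanescent_minus: np.ndarray = field(repr=False, kw_only=True)


def _cos_refracted(n: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """cos(theta) from the Snell invariant s = n_in sin(theta_in).

    The branch is fixed so that Im(n cos) >= 0 (transmitted field decays away
    from the interface); for lossless propagating waves this reduces to the
    principal value with Re cos >= 0.  Exactly-critical radicands resolve to
    the decaying branch.
    """
    sin_ratio = s / n
    radicand = 1.0 - sin_ratio**2
    cos = np.sqrt(radicand.astype(complex))
    kz = n * cos
    flip = (kz.imag < 0.0) | ((kz.imag == 0.0) & (kz.real < 0.0))
    cos = np.where(flip, -cos, cos)
    evanescent = (radicand.real < 0.0) | (np.abs(sin_ratio) > 1.0)
    return cos, evanescent


def angle_state(material: ChiralMaterial, nu, s) -> AngleState:
    """Angle state of one medium given the conserved in-plane invariants.

    ``s`` is the pair ``(s_plus, s_minus)`` of Snell invariants
    ``n_ambient_pm sin(theta_in)``, one per helicity; each is conserved
    across all media (generalized Snell's law for the circular eigenmodes).
    A scalar/array ``s`` is applied to both helicities.
    """
    nu = np.asarray(nu, dtype=float)
    if isinstance(s, tuple):
        s_p, s_m = s
    else:
        s_p = s_m = s
    s_p = np.broadcast_to(np.asarray(s_p, dtype=complex), nu.shape)
    s_m = np.broadcast_to(np.asarray(s_m, dtype=complex), nu.shape)
    n_p, n_m = eigen_indices(material, nu)
    cos_p, ev_p = _cos_refracted(n_p, s_p)
    cos_m, ev_m = _cos_refracted(n_m, s_m)
    return AngleState(
        n_plus=n_p,
        n_minus=n_m,
        cos_plus=cos_p,
        cos_minus=cos_m,
        k_plus=2.0 * np.pi * nu * n_p,
        k_minus=2.0 * np.pi * nu * n_m,
        evanescent_plus=ev_p,
        evanescent_minus=ev_m,
    )


def _snell_invariant(
    ambient: ChiralMaterial, nu, theta_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-helicity in-plane invariants n_amb_pm sin(theta_in)."""
    if not 0.0 <= theta_deg < 90.0:
        raise ValueError(f"incidence angle must be in [0, 90) deg, got {theta_deg}")
    nu = np.asarray(nu, dtype=float)
    n_p, n_m = eigen_indices(ambient, nu)
    sin_t = np.sin(np.deg2rad(theta_deg))
    return n_p * sin_t, n_m * sin_t


def refract(
    mat1: ChiralMaterial, mat2: ChiralMaterial, nu, theta_in: float
) -> tuple[AngleState, AngleState]:
    """Angle states on both sides of an interface for incidence from mat1."""
    s = _snell_invariant(mat1, nu, theta_in)
    return angle_state(mat1, nu, s), angle_state(mat2, nu, s)


def interface_matrices(
    mat1: ChiralMaterial,
    mat2: ChiralMaterial,
    nu,
    st1: AngleState,
    st2: AngleState,
) -> tuple[np.ndarray, np.ndarray]:
    """Transmission- and reflection-type interface submatrices (M_T, M_R).

    M_T(R) = 1/4 [ (1 + h)(1 +/- c2p/c1p)   (h - 1)(1 -/+ c2m/c1p) ]
                 [ (h - 1)(1 -/+ c2p/c1m)   (1 + h)(1 +/- c2m/c1m) ]

    with h = eta1/eta2 and c_jp(m) = cos(theta) of helicity +/- in medium j;
    the upper signs give M_T, the lower M_R.  Both are returned stacked as
    (n_nu, 2, 2).
    """
    nu = np.asarray(nu, dtype=float)
    h = mat1.impedance(nu) / mat2.impedance(nu)
    c1p, c1m = st1.cos_plus, st1.cos_minus
    c2p, c2m = st2.cos_plus, st2.cos_minus
    if np.any(c1p == 0.0) or np.any(c1m == 0.0):
        raise SingularGeometryError(
            "cos(theta) vanished in the entrance medium (grazing geometry)"
        )
    rpp = c2p / c1p
    rmp = c2m / c1p
    rpm = c2p / c1m
    rmm = c2m / c1m

    def build(sign: float) -> np.ndarray:
        m = np.empty(nu.shape + (2, 2), dtype=complex)
        m[..., 0, 0] = (1.0 + h) * (1.0 + sign * rpp)
        m[..., 0, 1] = (h - 1.0) * (1.0 - sign * rmp)
        m[..., 1, 0] = (h - 1.0) * (1.0 - sign * rpm)
        m[..., 1, 1] = (1.0 + h) * (1.0 + sign * rmm)
        return 0.25 * m

    return build(+1.0), build(-1.0)


class TransferMatrix4:
    """Stacked 4x4 transfer matrices with named 2x2 block accessors."""

    __slots__ = ("m",)

    def __init__(self, m: np.ndarray):
        m = np.asarray(m, dtype=complex)
        if m.shape[-2:] != (4, 4):
            raise ValueError(f"expected trailing (4, 4) shape, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("transfer matrix contains non-finite entries")
        self.m = m

    @classmethod
    def from_blocks(cls, ul, ur, ll, lr) -> "TransferMatrix4":
        ul = np.asarray(ul, dtype=complex)
        m = np.empty(ul.shape[:-2] + (4, 4), dtype=complex)
        m[..., :2, :2] = ul
        m[..., :2, 2:] = ur
        m[..., 2:, :2] = ll
        m[..., 2:, 2:] = lr
        return cls(m)

    @classmethod
    def identity(cls, shape=()) -> "TransferMatrix4":
        m = np.zeros(tuple(shape) + (4, 4), dtype=complex)
        m[..., range(4), range(4)] = 1.0
        return cls(m)

    @property
    def fwd_fwd(self) -> np.ndarray:
        """Upper-left block: forward(1) <- forward(2)."""
        return self.m[..., :2, :2]

    @property
    def fwd_bwd(self) -> np.ndarray:
        return self.m[..., :2, 2:]

    @property
    def bwd_fwd(self) -> np.ndarray:
        """Lower-left block, the reflection-generating one."""
        return self.m[..., 2:, :2]

    @property
    def bwd_bwd(self) -> np.ndarray:
        return self.m[..., 2:, 2:]

    def __matmul__(self, other: "TransferMatrix4") -> "TransferMatrix4":
        return TransferMatrix4(self.m @ other.m)


@dataclass(frozen=True)
class JonesT2:
    """2x2 circular-basis amplitude operator; first index output helicity."""

    t_pp: np.ndarray
    t_pm: np.ndarray
    t_mp: np.ndarray
    t_mm: np.ndarray

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "JonesT2":
        return cls(
            t_pp=m[..., 0, 0], t_pm=m[..., 0, 1], t_mp=m[..., 1, 0], t_mm=m[..., 1, 1]
        )

    def as_matrix(self) -> np.ndarray:
        m = np.empty(np.shape(self.t_pp) + (2, 2), dtype=complex)
        m[..., 0, 0] = self.t_pp
        m[..., 0, 1] = self.t_pm
        m[..., 1, 0] = self.t_mp
        m[..., 1, 1] = self.t_mm
        return m


def _interface_transfer(mat1, mat2, nu, st1, st2) -> TransferMatrix4:
    m_t, m_r = interface_matrices(mat1, mat2, nu, st1, st2)
    return TransferMatrix4.from_blocks(m_t, m_r, m_r, m_t)


def propagation_matrix(layer: Layer, nu, st: AngleState) -> TransferMatrix4:
    """Diagonal propagation factor of one layer in the transfer convention.

    diag(e^{-i phi+}, e^{-i phi-}, e^{+i phi+}, e^{+i phi-}) with the
    layer-normal phase phi_pm = 2 pi nu n_pm cos(theta_pm) d.  At normal
    incidence this is the plane-wave phase 2 pi nu n_pm d; the oblique
    generalization is validated against the scalar-TMM achiral limit.

    Absorbing layers make e^{-i phi} grow (the transfer matrix runs against
    the decay direction); exponents are clipped near the overflow limit with
    a warning rather than silently producing inf.
    """
    nu = np.asarray(nu, dtype=float)
    d_cm = layer.thickness_um * UM_TO_CM
    phi_p = 2.0 * np.pi * nu * st.n_plus * st.cos_plus * d_cm
    phi_m = 2.0 * np.pi * nu * st.n_minus * st.cos_minus * d_cm
    big = (np.abs(phi_p.imag) > _PHASE_CLIP) | (np.abs(phi_m.imag) > _PHASE_CLIP)
    if np.any(big):
        warnings.warn(
            "propagation phase exceeds the overflow guard; growing exponentials "
            "clipped (extremely opaque layer)",
            RuntimeWarning,
            stacklevel=2,
        )
        phi_p = phi_p.real + 1j * np.clip(phi_p.imag, -_PHASE_CLIP, _PHASE_CLIP)
        phi_m = phi_m.real + 1j * np.clip(phi_m.imag, -_PHASE_CLIP, _PHASE_CLIP)
    m = np.zeros(nu.shape + (4, 4), dtype=complex)
    m[..., 0, 0] = np.exp(-1j * phi_p)
    m[..., 1, 1] = np.exp(-1j * phi_m)
    m[..., 2, 2] = np.exp(1j * phi_p)
    m[..., 3, 3] = np.exp(1j * phi_m)
    return TransferMatrix4(m)


def total_transfer(stack: Stack, nu, theta_in: float) -> TransferMatrix4:
    """Ordered product of interface and propagation matrices for the stack.

    For one layer: T = T_12 T_phi T_21; for zero layers the bare-interface
    matrix; N layers alternate interface and propagation factors.
    """
    nu = np.asarray(nu, dtype=float)
    s = _snell_invariant(stack.ambient, nu, theta_in)
    media = [stack.ambient] + [ly.material for ly in stack.layers] + [stack.exit]
    states = [angle_state(m, nu, s) for m in media]
    total = _interface_transfer(media[0], media[1], nu, states[0], states[1])
    for i, layer in enumerate(stack.layers):
        total = total @ propagation_matrix(layer, nu, states[i + 1])
        total = total @ _interface_transfer(
            media[i + 1], media[i + 2], nu, states[i + 1], states[i + 2]
        )
    return total


def _inv2(m: np.ndarray, context: str = "") -> np.ndarray:
    """Closed-form inverse of stacked 2x2 matrices with a conditioning check."""
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    scale = np.max(np.abs(m), axis=(-2, -1))
    bad = ~np.isfinite(det) | (np.abs(det) <= 1e-300 * np.maximum(scale, 1.0) ** 2)
    if np.any(bad):
        raise ConditioningError(
            f"singular upper-left transfer block{context}; cannot extract t/r"
        )
    inv = np.empty_like(m)
    inv[..., 0, 0] = m[..., 1, 1]
    inv[..., 0, 1] = -m[..., 0, 1]
    inv[..., 1, 0] = -m[..., 1, 0]
    inv[..., 1, 1] = m[..., 0, 0]
    return inv / det[..., None, None]


def transmission_reflection(total: TransferMatrix4) -> tuple[JonesT2, JonesT2]:
    """Extract circular-basis transmission and reflection operators.

    Imposing no incoming wave on the exit side gives t = (upper-left)^-1 and
    r = (lower-left) @ (upper-left)^-1.
    """
    t = _inv2(total.fwd_fwd)
    r = total.bwd_fwd @ t
    return JonesT2.from_matrix(t), JonesT2.from_matrix(r)


def helicity_transmittances(t: JonesT2) -> tuple[np.ndarray, np.ndarray]:
    """Total transmitted intensity per incident helicity.

    T_+ sums the preserved |t_++|^2 and converted |t_-+|^2 powers for an
    incident + wave (bare squared moduli, no flux projection factors), and
    analogously for T_-.
    """
    T_plus = np.abs(t.t_pp) ** 2 + np.abs(t.t_mp) ** 2
    T_minus = np.abs(t.t_mm) ** 2 + np.abs(t.t_pm) ** 2
    return T_plus, T_minus


def stack_jones(stack: Stack, nu, theta_in: float = 0.0) -> JonesT2:
    """Transmission Jones operator of a stack at one incidence angle."""
    t, _ = transmission_reflection(total_transfer(stack, nu, theta_in))
    return t


def stack_transmittances(
    stack: Stack, nu, theta_in: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Helicity-resolved transmittances (T_+, T_-) of a stack."""
    return helicity_transmittances(stack_jones(stack, nu, theta_in))
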