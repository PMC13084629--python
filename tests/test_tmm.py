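import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vcdtmm import (
    ChiralMaterial,
    Layer,
    Stack,
    TransferMatrix4,
    helicity_transmittances,
    ideal_absorber,
    interface_matrices,
    propagation_matrix,
    refract,
    single_layer_stack,
    stack_jones,
    stack_transmittances,
    total_transfer,
    transmission_reflection,
    vacuum,
)
from vcdtmm.tmm import JonesT2, SingularGeometryError, angle_state

from .oracles import airy_chiral_slab_normal, scalar_slab_transmittance_unpolarized

GLASS = ChiralMaterial.from_constants(2.25)
NU = np.array([1000.0])


class TestRefract:
    def test_normal_incidence_cosines_are_one(self, preset):
        _, st2 = refract(vacuum(), preset, NU, 0.0)
        np.testing.assert_array_equal(st2.cos_plus, 1.0 + 0j)
        np.testing.assert_array_equal(st2.cos_minus, 1.0 + 0j)

    def test_scalar_snell_closed_form(self):
        _, st2 = refract(vacuum(), GLASS, NU, 30.0)
        expected = np.sqrt(1.0 - (np.sin(np.deg2rad(30.0)) / 1.5) ** 2)
        assert st2.cos_plus[0] == pytest.approx(expected, rel=1e-14)
        assert not st2.evanescent_plus[0]

    def test_total_internal_reflection_flags(self):
        rare = ChiralMaterial.from_constants(0.25)  # n = 0.5
        _, st2 = refract(vacuum(), rare, NU, 45.0)
        assert st2.evanescent_plus[0] and st2.evanescent_minus[0]
        assert abs(st2.cos_plus[0].imag) > 0.0

    def test_snell_invariant_conserved_per_helicity(self, preset):
        st1, st2 = refract(vacuum(), preset, np.array([500.0, 2200.0]), 40.0)
        for s1, s2 in (
            (st1.n_plus * np.sqrt(1 - st1.cos_plus**2), st2.n_plus * np.sqrt(1 - st2.cos_plus**2)),
            (st1.n_minus * np.sqrt(1 - st1.cos_minus**2), st2.n_minus * np.sqrt(1 - st2.cos_minus**2)),
        ):
            np.testing.assert_allclose(np.abs(s1), np.abs(s2), rtol=1e-12)

    def test_angle_domain_error(self):
        with pytest.raises(ValueError, match="90"):
            refract(vacuum(), GLASS, NU, 90.0)

    def test_evanescent_branch_decays(self):
        rare = ChiralMaterial.from_constants(0.25)
        _, st2 = refract(vacuum(), rare, NU, 60.0)
        # forward z-wavevector must not grow: Im(n cos) >= 0
        assert (st2.n_plus * st2.cos_plus)[0].imag >= 0.0


class TestInterfaceMatrices:
    def test_identical_media_is_identity(self):
        st1, st2 = refract(GLASS, GLASS, NU, 25.0)
        m_t, m_r = interface_matrices(GLASS, GLASS, NU, st1, st2)
        np.testing.assert_allclose(m_t[0], np.eye(2), atol=1e-15)
        np.testing.assert_allclose(m_r[0], np.zeros((2, 2)), atol=1e-15)

    def test_normal_incidence_diagonal(self, preset):
        st1, st2 = refract(vacuum(), preset, NU, 0.0)
        m_t, m_r = interface_matrices(vacuum(), preset, NU, st1, st2)
        assert m_t[0, 0, 1] == m_t[0, 1, 0] == 0.0
        assert m_r[0, 0, 0] == m_r[0, 1, 1] == 0.0  # reflection flips helicity

    def test_fresnel_amplitude_normal_incidence(self):
        st1, st2 = refract(vacuum(), GLASS, NU, 0.0)
        m_t, _ = interface_matrices(vacuum(), GLASS, NU, st1, st2)
        t = np.linalg.inv(m_t[0])
        assert t[0, 0] == pytest.approx(2.0 / (1.0 + 1.5), rel=1e-14)
        assert t[1, 1] == pytest.approx(2.0 / (1.0 + 1.5), rel=1e-14)

    def test_grazing_singularity_raises(self):
        st1, st2 = refract(vacuum(), GLASS, NU, 30.0)
        broken = angle_state(GLASS, NU, (1.5 + 0j, 1.5 + 0j))  # sin(theta)=1 inside
        assert np.allclose(broken.cos_plus, 0.0)
        with pytest.raises(SingularGeometryError):
            interface_matrices(GLASS, vacuum(), NU, broken, st1)


class TestPropagationMatrix:
    def test_thin_layer_tends_to_identity(self, preset):
        layer = Layer(preset, 1.0e-9)
        _, st2 = refract(vacuum(), preset, NU, 0.0)
        np.testing.assert_allclose(
            propagation_matrix(layer, NU, st2).m[0], np.eye(4), atol=1e-10
        )

    def test_lossless_normal_incidence_pure_phase(self):
        layer = Layer(GLASS, 5.0)
        _, st2 = refract(vacuum(), GLASS, NU, 0.0)
        m = propagation_matrix(layer, NU, st2).m[0]
        np.testing.assert_allclose(np.abs(np.diag(m)), 1.0, rtol=1e-14)

    def test_absorbing_layer_moduli(self, preset):
        # e^{-i phi} runs against the physical decay in the transfer
        # convention; the backward entry e^{+i phi} carries the decay
        layer = Layer(preset, 10.0)
        _, st2 = refract(vacuum(), preset, np.array([500.0]), 0.0)
        m = propagation_matrix(layer, np.array([500.0]), st2).m[0]
        expected = np.exp(-2.0 * np.pi * 500.0 * st2.n_plus[0].imag * 10.0e-4)
        assert abs(m[2, 2]) == pytest.approx(expected, rel=1e-12)
        assert abs(m[2, 2]) < 1.0 < abs(m[0, 0])
        assert abs(m[0, 0]) * abs(m[2, 2]) == pytest.approx(1.0, rel=1e-12)

    def test_overflow_guard_warns(self, preset):
        layer = Layer(preset, 1.0e6)  # a metre of absorber
        _, st2 = refract(vacuum(), preset, np.array([500.0]), 0.0)
        with pytest.warns(RuntimeWarning, match="overflow guard"):
            m = propagation_matrix(layer, np.array([500.0]), st2)
        assert np.all(np.isfinite(m.m))


class TestTotalTransfer:
    def test_zero_layers_identical_media_identity(self):
        stack = Stack(ambient=GLASS, layers=(), exit=GLASS)
        np.testing.assert_allclose(
            total_transfer(stack, NU, 35.0).m[0], np.eye(4), atol=1e-14
        )

    def test_achiral_slab_no_net_dichroism(self, achiral_preset, coarse_grid):
        stack = single_layer_stack(achiral_preset, 5.0)
        for theta in (0.0, 45.0, 70.0):
            T_p, T_m = stack_transmittances(stack, coarse_grid, theta)
            np.testing.assert_allclose(T_p, T_m, atol=5e-15)

    def test_half_wave_slab_transparent(self):
        # phi = 2 pi nu n d = m pi: nu = 1000, n = 1.5 -> d = m * 10/3 um
        d_um = 10.0 / 3.0
        stack = single_layer_stack(GLASS, d_um)
        T_p, T_m = stack_transmittances(stack, np.array([1000.0]), 0.0)
        assert T_p[0] == pytest.approx(1.0, abs=1e-12)
        assert T_m[0] == pytest.approx(1.0, abs=1e-12)


class TestTransmissionReflection:
    def test_identity_matrix(self):
        t, r = transmission_reflection(TransferMatrix4.identity((1,)))
        np.testing.assert_array_equal(t.as_matrix()[0], np.eye(2))
        np.testing.assert_array_equal(r.as_matrix()[0], np.zeros((2, 2)))

    def test_bare_interface_fresnel_reflection(self):
        stack = Stack(ambient=vacuum(), layers=(), exit=GLASS)
        t, r = transmission_reflection(total_transfer(stack, NU, 0.0))
        # reflection flips helicity: the amplitude sits on the anti-diagonal
        # with magnitude |n1 - n2| / (n1 + n2)
        assert abs(r.t_pm[0]) == pytest.approx(0.2, rel=1e-12)
        assert abs(r.t_mp[0]) == pytest.approx(0.2, rel=1e-12)
        assert abs(r.t_pp[0]) < 1e-14 and abs(r.t_mm[0]) < 1e-14
        R = np.abs(r.t_pm[0]) ** 2
        assert R == pytest.approx(0.04, rel=1e-12)
        assert t.t_pp[0] == pytest.approx(0.8, rel=1e-12)

    def test_chiral_slab_matches_airy_oracle(self, preset, coarse_grid):
        stack = single_layer_stack(preset, 1.0)
        t = stack_jones(stack, coarse_grid, 0.0)
        eps, mu, kappa = preset.evaluate(coarse_grid)
        t_pp, t_mm = airy_chiral_slab_normal(eps, mu, kappa, 1.0, coarse_grid)
        np.testing.assert_allclose(t.t_pp, t_pp, rtol=1e-10)
        np.testing.assert_allclose(t.t_mm, t_mm, rtol=1e-10)
        assert np.max(np.abs(t.t_pm)) <= 1e-12
        assert np.max(np.abs(t.t_mp)) <= 1e-12


class TestHelicityTransmittances:
    def test_identity(self):
        t = JonesT2.from_matrix(np.eye(2, dtype=complex)[None])
        T_p, T_m = helicity_transmittances(t)
        assert T_p[0] == T_m[0] == 1.0

    def test_direct_formula_with_conversion(self):
        m = np.array([[[0.6 + 0j, 0.0 + 0j], [0.3 + 0j, 0.0 + 0j]]])
        T_p, T_m = helicity_transmittances(JonesT2.from_matrix(m))
        assert T_p[0] == pytest.approx(0.45)
        assert T_m[0] == 0.0


class TestAchiralScalarOracle:
    @pytest.mark.parametrize("theta", [0.0, 30.0, 50.0, 80.0])
    @pytest.mark.parametrize("d_um", [1.0, 10.0])
    def test_matches_scalar_tmm(self, achiral_preset, coarse_grid, theta, d_um):
        stack = single_layer_stack(achiral_preset, d_um)
        T_p, T_m = stack_transmittances(stack, coarse_grid, theta)
        eps, mu, _ = achiral_preset.evaluate(coarse_grid)
        n2 = np.sqrt(eps * mu)
        n2 = np.where(n2.imag < 0, -n2, n2)
        expected = scalar_slab_transmittance_unpolarized(1.0, n2, 1.0, d_um, coarse_grid, theta)
        np.testing.assert_allclose(T_p, expected, rtol=1e-10)
        np.testing.assert_allclose(T_m, expected, rtol=1e-10)


class TestEnantiomerAntisymmetry:
    @pytest.mark.parametrize("theta", [0.0, 35.0, 70.0])
    def test_helicity_swap(self, coarse_grid, theta):
        right = single_layer_stack(ideal_absorber(1.0e-5), 10.0)
        left = single_layer_stack(ideal_absorber(-1.0e-5), 10.0)
        t_r = stack_jones(right, coarse_grid, theta)
        t_l = stack_jones(left, coarse_grid, theta)
        np.testing.assert_allclose(t_l.t_pp, t_r.t_mm, rtol=1e-12, atol=1e-300)
        np.testing.assert_allclose(t_l.t_mp, t_r.t_pm, rtol=1e-12, atol=1e-300)
        T_r = stack_transmittances(right, coarse_grid, theta)
        T_l = stack_transmittances(left, coarse_grid, theta)
        np.testing.assert_allclose(T_l[0], T_r[1], rtol=1e-12)
        np.testing.assert_allclose(T_l[1], T_r[0], rtol=1e-12)


@given(
    n=st.floats(1.1, 3.0),
    d_um=st.floats(0.1, 20.0),
    theta=st.floats(0.0, 60.0),
    nu=st.floats(300.0, 4000.0),
)
@settings(max_examples=40, deadline=None)
def test_energy_conservation_lossless_slab(n, d_um, theta, nu):
    stack = single_layer_stack(ChiralMaterial.from_constants(n * n), d_um)
    grid = np.array([nu])
    t, r = transmission_reflection(total_transfer(stack, grid, theta))
    T_p, T_m = helicity_transmittances(t)
    R_p = np.abs(r.t_pp) ** 2 + np.abs(r.t_mp) ** 2
    R_m = np.abs(r.t_mm) ** 2 + np.abs(r.t_pm) ** 2
    assert T_p[0] + R_p[0] == pytest.approx(1.0, abs=1e-10)
    assert T_m[0] + R_m[0] == pytest.approx(1.0, abs=1e-10)


def test_layer_thickness_validation(preset):
    with pytest.raises(ValueError, match="thickness"):
        Layer(preset, 0.0)
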