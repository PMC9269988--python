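"""Phase thermodynamics: molar masses, mole fractions, chemical potentials."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcatsim import (
    CompositionState,
    PhaseDef,
    PhaseState,
    SpeciesTable,
    ThermoParams,
    ValidationError,
    chemical_potential,
    mass_fractions_from_mole,
    mole_fractions,
    phase_molecular_weight,
)
from tcatsim.species import sanitize_mass_fractions

AB = SpeciesTable({"a": 0.018, "b": 0.180})


class TestPhaseMolecularWeight:
    def test_single_species_identity(self):
        t = SpeciesTable({"w": 0.018})
        assert phase_molecular_weight({"w": 1.0}, t) == pytest.approx(0.018)

    def test_equal_masses_are_symmetric(self):
        t = SpeciesTable({"a": 0.05, "b": 0.05})
        for wa in (0.1, 0.5, 0.9):
            assert phase_molecular_weight({"a": wa, "b": 1 - wa}, t) == pytest.approx(0.05)

    def test_harmonic_mean_value(self):
        # 1 / (0.5/0.018 + 0.5/0.180)
        mw = phase_molecular_weight({"a": 0.5, "b": 0.5}, AB)
        assert mw == pytest.approx(0.0327273, rel=1e-5)

    def test_bounded_by_member_masses(self, rng):
        w = rng.dirichlet(np.ones(2))
        mw = phase_molecular_weight({"a": w[0], "b": w[1]}, AB)
        assert 0.018 <= mw <= 0.180

    def test_unnormalized_rejected(self):
        with pytest.raises(ValidationError):
            phase_molecular_weight({"a": 0.6, "b": 0.6}, AB)

    def test_agrees_with_mole_fraction_form(self, rng):
        w = rng.dirichlet(np.ones(2))
        omega = {"a": w[0], "b": w[1]}
        x = mole_fractions(omega, AB)
        direct = phase_molecular_weight(omega, AB)
        via_x = sum(AB.mw(sp) * x[sp] for sp in x)
        assert direct == pytest.approx(via_x, abs=1e-12)


class TestMoleFractions:
    def test_single_species(self):
        t = SpeciesTable({"w": 0.018})
        assert mole_fractions({"w": 1.0}, t)["w"] == pytest.approx(1.0)

    def test_equal_masses_give_identity(self):
        t = SpeciesTable({"a": 0.05, "b": 0.05})
        x = mole_fractions({"a": 0.3, "b": 0.7}, t)
        assert x["a"] == pytest.approx(0.3) and x["b"] == pytest.approx(0.7)

    def test_derived_values(self):
        x = mole_fractions({"a": 0.5, "b": 0.5}, AB)
        assert x["a"] == pytest.approx(0.9091, abs=1e-4)
        assert x["b"] == pytest.approx(0.0909, abs=1e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_round_trip_is_identity(self, raw):
        total = sum(raw)
        names = [f"s{i}" for i in range(len(raw))]
        t = SpeciesTable({n: 0.01 + 0.05 * i for i, n in enumerate(names, 1)})
        omega = {n: v / total for n, v in zip(names, raw)}
        x = mole_fractions(omega, t)
        assert sum(x.values()) == pytest.approx(1.0, abs=1e-12)
        back = mass_fractions_from_mole(x, t)
        for n in names:
            assert back[n] == pytest.approx(omega[n], abs=1e-12)


class TestChemicalPotential:
    def test_reference_state(self, thermo, table):
        th = ThermoParams(mu0={("w", "f"): 123.0})
        assert chemical_potential("w", "f", 1.0, th, table) == pytest.approx(123.0)

    def test_doubling_mole_fraction(self, thermo, table):
        # R_g * 310 / 0.018 * ln 2 ~ 9.92e4 J/kg
        d = chemical_potential("w", "f", 0.5, thermo, table) - chemical_potential(
            "w", "f", 0.25, thermo, table
        )
        assert d == pytest.approx(9.92e4, rel=1e-3)

    def test_floor_keeps_potential_finite(self, thermo, table):
        mu = chemical_potential("w", "f", 0.0, thermo, table)
        expected = thermo.gas_constant * 310.0 / 0.018 * np.log(1e-12)
        assert np.isfinite(mu) and mu == pytest.approx(expected)

    def test_monotone_in_mole_fraction(self, thermo, table):
        xs = np.linspace(0.0, 1.0, 25)
        mus = [chemical_potential("o", "f", x, thermo, table) for x in xs]
        assert np.all(np.diff(mus) >= 0.0)


class TestValidation:
    def test_nonpositive_molar_mass_rejected(self):
        with pytest.raises(ValidationError):
            SpeciesTable({"a": 0.0})

    def test_reference_species_must_be_member(self):
        with pytest.raises(ValidationError):
            PhaseDef("f", ("a", "b"), "c")

    def test_temperature_and_floor_bounds(self):
        with pytest.raises(ValidationError):
            ThermoParams(temperature=-1.0)
        with pytest.raises(ValidationError):
            ThermoParams(x_floor=1e-3)

    def test_deeply_negative_mass_fraction_is_error(self):
        with pytest.raises(ValidationError):
            sanitize_mass_fractions({"a": -1e-6})

    def test_tiny_negative_zeroed_with_warning(self):
        with pytest.warns(UserWarning):
            out = sanitize_mass_fractions({"a": -1e-13})
        assert out["a"] == 0.0

    def test_composition_state_invariants(self):
        good = CompositionState({
            "f": PhaseState(0.7, 1000.0, {"w": 1.0}),
            "s": PhaseState(0.3, 1050.0, {"e": 1.0}),
        })
        good.validate()
        bad = CompositionState({
            "f": PhaseState(0.7, 1000.0, {"w": 1.0}),
            "s": PhaseState(0.4, 1050.0, {"e": 1.0}),
        })
        with pytest.raises(ValidationError):
            bad.validate()
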