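"""Affinity kinetics and interphase mass transfer."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcatsim import (
    ReactionSpec,
    SpeciesTable,
    TransferSpec,
    ValidationError,
    affinity,
    balance_stoichiometry,
    reaction_rate,
    species_production,
    transfer_rate,
    validate_reaction,
)
from tcatsim.kinetics import monod, oxygen_switch

T = SpeciesTable({"t": 0.1, "n": 0.1, "e": 0.06, "w": 0.018, "m": 0.09})

LYSIS = ReactionSpec(
    "lysis", "s", {"n": -1.0, "e": 1.0, "w": 0.04 / 0.018}, 1.0
)


class TestValidateReaction:
    def test_isomerization_balances(self):
        r = ReactionSpec("necrosis", "s", {"t": -1.0, "n": 1.0}, 1.0)
        assert validate_reaction(r, T)["ok"]

    def test_constructed_imbalance_reports_residual(self):
        r = ReactionSpec("bad", "s", {"t": -1.0, "m": 1.0}, 1.0)
        rep = validate_reaction(r, T)
        assert not rep["ok"]
        assert rep["residual_mass"] == pytest.approx(-0.01, abs=1e-12)

    def test_lysis_balanced_by_solving_water_coefficient(self):
        assert validate_reaction(LYSIS, T)["ok"]
        solved = balance_stoichiometry({"n": -1.0, "e": 1.0}, "w", T)
        assert solved["w"] == pytest.approx(0.04 / 0.018, abs=1e-12)

    def test_negative_rate_coeff_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            ReactionSpec("bad", "s", {"t": -1.0, "n": 1.0}, -1.0)

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ValidationError):
            ReactionSpec("empty", "s", {}, 1.0)


class TestAffinity:
    def test_equal_potentials_give_zero(self):
        mu = {sp: -42.0 for sp in LYSIS.stoich}
        assert affinity(LYSIS, mu, T) == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_value(self):
        mu = {"n": -100.0, "e": -200.0, "w": -300.0}
        assert affinity(LYSIS, mu, T) == pytest.approx(-14.0, abs=1e-10)

    def test_linearity_in_stoichiometry(self):
        mu = {"n": -100.0, "e": -200.0, "w": -300.0}
        doubled = ReactionSpec(
            "lysis2", "s", {sp: 2 * nu for sp, nu in LYSIS.stoich.items()}, 1.0
        )
        assert affinity(doubled, mu, T) == pytest.approx(2 * affinity(LYSIS, mu, T))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-1e6, 1e6))
    def test_invariant_under_uniform_shift(self, shift):
        mu = {"n": -100.0, "e": -200.0, "w": -300.0}
        shifted = {sp: v + shift for sp, v in mu.items()}
        assert affinity(LYSIS, shifted, T) == pytest.approx(
            affinity(LYSIS, mu, T), abs=1e-6
        )

    def test_missing_potential_is_error(self):
        with pytest.raises(ValidationError):
            affinity(LYSIS, {"n": 0.0}, T)


class TestReactionRate:
    def test_zero_at_equilibrium(self):
        assert reaction_rate(LYSIS, 0.0) == 0.0

    def test_linear_closure_value(self):
        r = ReactionSpec("lysis", "s", LYSIS.stoich, 2.0)
        assert reaction_rate(r, -14.0) == pytest.approx(28.0)

    def test_frozen_reaction(self):
        r = ReactionSpec("lysis", "s", LYSIS.stoich, 0.0)
        assert reaction_rate(r, 12345.6) == 0.0

    def test_entropy_production_nonnegative(self, rng):
        for _ in range(100):
            k = float(rng.uniform(0.0, 10.0))
            a = float(rng.normal(0.0, 100.0))
            r = ReactionSpec("r", "s", LYSIS.stoich, k)
            rate = reaction_rate(r, a)
            assert -rate * a >= 0.0  # eps/theta factors are positive


class TestSpeciesProduction:
    def test_empty_network(self):
        assert species_production([], {"s": {}}, T) == {}

    def test_single_reaction_mass_conserved(self):
        mu = {"n": -100.0, "e": -200.0, "w": -300.0}
        rxn = ReactionSpec("lysis", "s", LYSIS.stoich, 2.0)
        out = species_production([rxn], {"s": mu}, T)
        # R = +28, nu_n = -1, MW_n = 0.1
        assert out[("n", "s")] == pytest.approx(-2.8)
        assert sum(out.values()) == pytest.approx(0.0, abs=1e-12)

    def test_two_half_rate_copies_are_additive(self):
        mu = {"n": -100.0, "e": -200.0, "w": -300.0}
        full = species_production(
            [ReactionSpec("a", "s", LYSIS.stoich, 2.0)], {"s": mu}, T
        )
        halves = species_production(
            [ReactionSpec("a", "s", LYSIS.stoich, 1.0),
             ReactionSpec("b", "s", LYSIS.stoich, 1.0)],
            {"s": mu}, T,
        )
        for key in full:
            assert halves[key] == pytest.approx(full[key], rel=1e-14)

    def test_reaction_in_phase_lacking_species_is_error(self):
        from tcatsim import PhaseDef

        phases = {"s": PhaseDef("s", ("n", "e"), "e")}
        mu = {"n": 0.0, "e": 0.0, "w": 0.0}
        with pytest.raises(ValidationError):
            species_production([LYSIS], {"s": mu}, T, phases=phases)


class TestTransfer:
    def test_zero_at_matched_augmented_potentials(self):
        spec = TransferSpec("o", "f", "s", 2.0)
        assert transfer_rate(spec, -60.0, 10.0, -80.0, 30.0) == pytest.approx(0.0)

    def test_direct_value_and_antisymmetry(self):
        spec = TransferSpec("o", "f", "s", 2.0)
        m = transfer_rate(spec, -50.0, 0.0, -80.0, 0.0)
        assert m == pytest.approx(60.0)
        assert transfer_rate(spec, -80.0, 0.0, -50.0, 0.0) == pytest.approx(-60.0)

    def test_negative_coefficient_rejected(self):
        with pytest.raises(ValidationError):
            TransferSpec("o", "f", "s", -1.0)

    def test_entropy_production_nonnegative(self, rng):
        for _ in range(100):
            spec = TransferSpec("o", "f", "s", float(rng.uniform(0.0, 1e-6)))
            mu_d, mu_r = rng.normal(0.0, 1e4, 2)
            m = transfer_rate(spec, mu_d, 0.0, mu_r, 0.0)
            assert m * (mu_d - mu_r) >= 0.0


class TestModulations:
    def test_oxygen_switch_activates_under_hypoxia(self):
        sw = oxygen_switch(omega_crit=1e-5, delta=1e-6)
        assert sw({"o": 0.0}) > 0.99
        assert sw({"o": 1e-4}) < 0.01

    def test_monod_saturates_and_vanishes(self):
        m = monod("g", 1e-4)
        assert m({"g": 0.0}) == 0.0
        assert m({"g": 1.0}) > 0.99
        # rate coefficient stays nonnegative under any modulation
        r = ReactionSpec("r", "s", {"t": -1.0, "n": 1.0}, 2.0, (m,))
        assert r.effective_coeff({"g": 0.3, "t": 0.0, "n": 0.0}) >= 0.0
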