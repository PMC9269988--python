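"""Built-in scenario generators: avascular spheroid, equilibrium states,
analytic-limit configurations and seeded random thermodynamic states.

The spheroid fixture emulates an avascular tumor spheroid: an ECM + tumor
solid phase bathed in interstitial fluid, glucose and oxygen supplied at the
outer boundary, affinity-driven tumor formation, an optional hypoxia switch
for necrotic formation and necrotic lysis, and an optional chemotherapeutic
transfer + destruction pathway.  Default parameter choices are documented in
the methods note; all randomness is seeded and recorded.
"""

from __future__ import annotations

import numpy as np

from .closure import ClosureCoefficients
from .config import (
    GeometryParams,
    SolverParams,
    ThreePhaseConfig,
    ThreePhaseInitial,
    TwoPhaseBoundary,
    TwoPhaseConfig,
    TwoPhaseInitial,
)
from .entropy import EntropyLedger, audit_three_phase, audit_two_phase
from .grid import Grid1D
from .kinetics import (
    ReactionSpec,
    TransferSpec,
    balance_stoichiometry,
    monod,
    oxygen_switch,
)
from .species import PhaseDef, SpeciesTable, ThermoParams, ValidationError

__all__ = [
    "default_species_table",
    "two_phase_phases",
    "three_phase_phases",
    "build_spheroid_fixture",
    "build_closed_fixture",
    "build_diffusion_fixture",
    "build_darcy_fixture",
    "build_twobox_transfer_fixture",
    "build_reaction_recovery_fixture",
    "build_equilibrium_fixture_2p",
    "build_threephase_fixture",
    "build_threephase_equilibrium_fixture",
    "random_two_phase_ledger",
    "random_three_phase_ledger",
]

#: Molar masses (kg/mol) of the model species: effective values for the
#: lumped biological species, literature values for glucose, oxygen, water.
DEFAULT_MOLAR_MASS = {
    "l": 0.1,    # living tumor species (lumped macromolecular unit)
    "n": 0.1,    # necrotic tumor species
    "e": 0.09,   # extra-cellular matrix species
    "g": 0.180,  # glucose
    "o": 0.032,  # oxygen
    "c": 0.3,    # chemotherapeutic drug
    "w": 0.018,  # water
    "x": 0.025,  # fluid background
    "y": 0.12,   # solid background
}


def default_species_table(three_phase: bool = False) -> SpeciesTable:
    mm = dict(DEFAULT_MOLAR_MASS)
    if three_phase:
        mm["z"] = 0.025  # wetting-phase background
    return SpeciesTable(mm)


def two_phase_phases() -> dict[str, PhaseDef]:
    """Fluid carries {g,o,c,w,x} (reference w); solid all but x (reference e)."""
    return {
        "f": PhaseDef("f", ("g", "o", "c", "w", "x"), "w"),
        "s": PhaseDef("s", ("l", "n", "e", "g", "o", "c", "w", "y"), "e"),
    }


def three_phase_phases() -> dict[str, PhaseDef]:
    """Wetting {g,o,c,w,z} (ref w); non-wetting {l,n,g,o,c,w,x} (ref l);
    solid {e,g,o,w,y} (ref e)."""
    return {
        "w": PhaseDef("w", ("g", "o", "c", "w", "z"), "w"),
        "n": PhaseDef("n", ("l", "n", "g", "o", "c", "w", "x"), "l"),
        "s": PhaseDef("s", ("e", "g", "o", "w", "y"), "e"),
    }


def _mole_fracs(omega, table):
    moles = {sp: np.asarray(w, dtype=float) / table.mw(sp) for sp, w in omega.items()}
    tot = sum(moles.values())
    return {sp: m / tot for sp, m in moles.items()}


def _transfer_mu0_offsets(
    omega_src,
    omega_dst,
    table,
    species_list,
    src_phase: str,
    dst_phase: str,
    thermo: ThermoParams | None = None,
    mu0_src=None,
    psi_src: float = 0.0,
    psi_dst: float = 0.0,
):
    """Destination-side reference potentials equilibrating interphase transfer.

    Sets ``mu0`` in the destination phase so the augmented potentials of the
    listed species match across the pair at the given compositions.  This is
    the physical statement that the reference (solvation/binding) state of a
    species differs between phases; a dilute fluid and a dense solid cannot
    equilibrate water by matching mole fractions alone.
    """
    th = thermo or ThermoParams()
    x_src = _mole_fracs(omega_src, table)
    x_dst = _mole_fracs(omega_dst, table)
    out = {}
    for sp in species_list:
        base = 0.0 if mu0_src is None else mu0_src.get((sp, src_phase), 0.0)
        rt = th.gas_constant * th.temperature / table.mw(sp)
        ratio = np.log(np.maximum(x_src[sp], th.x_floor)) - np.log(
            np.maximum(x_dst[sp], th.x_floor)
        )
        out[(sp, dst_phase)] = float(base + rt * ratio + psi_src - psi_dst)
    return out


def two_phase_reactions(
    table: SpeciesTable,
    *,
    k_formation: float = 3e-11,
    k_necrosis: float = 0.0,
    k_destruction: float = 0.0,
    k_lysis: float = 1e-12,
    omega_crit: float = 1e-5,
    switch_delta: float = 3e-6,
    phase: str = "s",
) -> list[ReactionSpec]:
    """The four-reaction tumor network (formation, destruction, necrosis, lysis).

    Stoichiometric coefficients are solved per reaction so that
    ``sum nu MW = 0`` for the configured molar masses; the living tumor
    species plays the role of the generic tumor species of the network.
    """
    rxns = [
        ReactionSpec(
            "tumor_formation", phase,
            balance_stoichiometry({"g": -1.0, "o": -1.0}, "l", table),
            k_formation,
            (monod("g", 1e-4), monod("o", 2e-6)),
        ),
        ReactionSpec(
            "tumor_destruction", phase,
            balance_stoichiometry({"l": -1.0, "c": -0.1, "w": 2.0}, "e", table),
            k_destruction,
            (monod("c", 1e-7), monod("l", 1e-3)),
        ),
        ReactionSpec(
            "necrotic_formation", phase,
            balance_stoichiometry({"l": -1.0}, "n", table),
            k_necrosis,
            (oxygen_switch(omega_crit, switch_delta), monod("l", 1e-3)),
        ),
        ReactionSpec(
            "necrotic_lysis", phase,
            balance_stoichiometry({"n": -1.0, "w": 1.5}, "e", table),
            k_lysis,
            (monod("n", 1e-6),),
        ),
    ]
    return rxns


def _base_mu0_two_phase() -> dict[tuple[str, str], float]:
    """Reference potentials making the tumor network spontaneous forward.

    The living tumor species sits well below the nutrient baseline so tumor
    formation remains exergonic over the whole feasible composition range;
    necrosis and lysis are mildly downhill; ECM sits low so drug-driven
    destruction is downhill when drug is present.
    """
    mu0_l = -3.0e6
    mu0_n = mu0_l - 2.0e6
    mu0_e = -8.0e6
    return {
        ("l", "s"): mu0_l,
        ("n", "s"): mu0_n,
        ("e", "s"): mu0_e,
    }


_FLUID_BASE = {"g": 5e-4, "o": 1e-5, "c": 0.0, "x": 1e-3}


def _fluid_composition(overrides=None) -> dict[str, float]:
    comp = dict(_FLUID_BASE)
    if overrides:
        comp.update(overrides)
    comp["w"] = 1.0 - sum(comp.values())
    return comp


def _solid_composition(omega_l=0.08, omega_n=0.0, omega_c=0.0):
    """Solid-phase composition: mostly ECM with tumor, background and
    dissolved small species; the ECM species absorbs the remainder."""
    comp = {
        "l": omega_l,
        "n": omega_n,
        "c": omega_c,
        "y": 0.05,
        "g": 5e-4,
        "o": 1e-5,
        "w": 0.02,
    }
    rest = 1.0 - sum(np.asarray(v, dtype=float) for v in comp.values())
    if np.any(np.asarray(rest) <= 0.0):
        raise ValidationError("solid composition over-filled")
    comp["e"] = rest
    return {sp: (v if np.ndim(v) else float(v)) for sp, v in comp.items()}


def _default_closure_2p(d_scale: float = 1.0) -> ClosureCoefficients:
    return ClosureCoefficients(
        diffusivity={
            "f": {"g": 7e-10, "o": 2e-9, "c": 5e-10, "x": 1e-9},
            "s": {"l": 1e-14, "n": 1e-14, "g": 1e-10, "o": 1e-10,
                  "c": 1e-10, "w": 1e-10, "y": 1e-14},
        },
        resistance={"f": 1e12},  # tissue-scale hydraulic resistance, Pa s/m^2
        tension={"fs": 0.0},
    )


def build_spheroid_fixture(
    radius_m: float = 1e-3,
    n_cells: int = 32,
    nutrient_boundary_values: dict[str, float] | None = None,
    seed: int = 0,
    *,
    bump_amplitude: float = 0.04,
    oxygen_switch_enabled: bool = False,
    drug_enabled: bool = False,
    t_end: float = 2e4,
    n_out: int = 41,
) -> TwoPhaseConfig:
    """Avascular spheroid scenario on a spherical grid.

    A living-tumor mass-fraction bump sits at the center of the solid phase;
    glucose and oxygen are held at the outer boundary of the interstitial
    fluid.  ``oxygen_switch_enabled`` activates the hypoxia-modulated
    necrotic pathway; ``drug_enabled`` activates drug supply, fluid-to-solid
    drug transfer and the destruction reaction.  Deterministic given
    ``seed`` (which perturbs the tumor bump by a small relative noise).
    """
    if radius_m <= 0.0:
        raise ValidationError("spheroid radius must be positive")
    if n_cells < 8:
        raise ValidationError("need at least 8 cells")
    table = default_species_table()
    phases = two_phase_phases()
    grid = Grid1D.uniform("spherical", 0.0, radius_m, n_cells)
    bc_omega = dict(nutrient_boundary_values or {"g": 5e-4, "o": 1e-5})
    for sp in bc_omega:
        if sp not in phases["f"].members:
            raise ValidationError(f"boundary species {sp!r} is not a fluid species")
    if drug_enabled:
        bc_omega.setdefault("c", 1e-5)

    omega_f = _fluid_composition()

    rng = np.random.default_rng(seed)
    r = grid.centers
    noise = 1.0 + 1e-3 * rng.standard_normal(n_cells)
    bump = bump_amplitude * np.exp(-((r / (0.3 * radius_m)) ** 2)) * noise
    omega_s = _solid_composition(omega_l=0.08 + bump)
    omega_s_base = _solid_composition(omega_l=0.08)

    mu0 = dict(_base_mu0_two_phase())
    mu0.update(
        _transfer_mu0_offsets(omega_f, omega_s_base, table,
                              ("g", "o", "c", "w"), "f", "s")
    )

    transfers = [
        TransferSpec("g", "f", "s", 1e-7),
        TransferSpec("o", "f", "s", 1e-7),
        TransferSpec("w", "f", "s", 1e-8),
    ]
    if drug_enabled:
        transfers.append(TransferSpec("c", "f", "s", 1e-7))

    reactions = two_phase_reactions(
        table,
        k_necrosis=1e-12 if oxygen_switch_enabled else 0.0,
        k_destruction=4e-12 if drug_enabled else 0.0,
    )

    return TwoPhaseConfig(
        grid=grid,
        species_table=table,
        phases=phases,
        thermo=ThermoParams(mu0=mu0),
        densities={"f": 1000.0, "s": 1050.0},
        reactions=reactions,
        transfers=transfers,
        closure=_default_closure_2p(),
        initial=TwoPhaseInitial(eps_s=0.3, omega_f=dict(omega_f), omega_s=omega_s),
        boundary=TwoPhaseBoundary(omega_f_outer=bc_omega, pressure_outer=0.0),
        solver=SolverParams(t_end=t_end, rtol=1e-8, atol=1e-12, n_out=n_out),
        seed=seed,
    )


def build_closed_fixture(seed: int = 0, n_cells: int = 16, t_end: float = 5e3) -> TwoPhaseConfig:
    """Closed-domain scenario: no-flux everywhere, reactions + transfer active.

    Phase densities are equal so interphase mass transfer is volumetrically
    neutral; a rigid closed domain with incompressible phases requires this
    compatibility (the all-Neumann pressure problem is gauged at cell 0).
    """
    cfg = build_spheroid_fixture(
        n_cells=n_cells, seed=seed, t_end=t_end, n_out=101, bump_amplitude=0.0
    )
    return cfg.with_updates(
        densities={"f": 1000.0, "s": 1000.0},
        boundary=TwoPhaseBoundary(
            omega_f_outer={}, pressure_outer=None, gauge_cell=0, gauge_pressure=0.0
        ),
    )


def build_diffusion_fixture(
    n_cells: int = 128,
    length: float = 1e-3,
    diffusivity: float = 1e-9,
    amplitude: float = 1e-5,
    background: float = 1e-7,
    t0: float = 1.25,
    t_end: float = 3.75,
    seed: int = 0,
) -> TwoPhaseConfig:
    """Dilute-solute configuration matching the 1-D Gaussian heat kernel.

    A Gaussian glucose pulse (initial spreading time ``t0``) diffuses in a
    quiescent uniform fluid on a Cartesian slab; no flow, no transfer, no
    reactions.  In the dilute limit the potential-driven closure reduces to
    Fickian diffusion with the configured diffusivity, so the profile follows
    ``bg + amp*sqrt(t0/(t0+t))*exp(-x^2/(4 D (t0+t)))`` about the center.
    """
    table = default_species_table()
    phases = two_phase_phases()
    grid = Grid1D.uniform("cartesian", 0.0, length, n_cells)
    x = grid.centers - 0.5 * length
    pulse = background + amplitude * np.exp(-x**2 / (4.0 * diffusivity * t0))
    omega_f = {
        "g": pulse,
        "o": np.full(n_cells, 1e-6),
        "c": np.zeros(n_cells),
        "x": np.full(n_cells, 1e-3),
    }
    omega_f["w"] = 1.0 - sum(omega_f[k] for k in ("g", "o", "c", "x"))
    omega_s = {"l": 0.1, "n": 0.0, "g": 0.0, "o": 0.0, "c": 0.0, "w": 0.0,
               "y": 0.05, "e": 0.75}
    closure = ClosureCoefficients(
        diffusivity={"f": {"g": diffusivity}, "s": {}},
        resistance={"f": 1e12},
    )
    return TwoPhaseConfig(
        grid=grid,
        species_table=table,
        phases=phases,
        thermo=ThermoParams(),
        densities={"f": 1000.0, "s": 1000.0},
        reactions=[],
        transfers=[],
        closure=closure,
        initial=TwoPhaseInitial(eps_s=0.3, omega_f=omega_f, omega_s=omega_s),
        boundary=TwoPhaseBoundary(
            omega_f_outer={}, pressure_outer=0.0, pressure_inner=0.0
        ),
        solver=SolverParams(t_end=t_end, rtol=1e-10, atol=1e-14, n_out=6),
        seed=seed,
    )


def build_darcy_fixture(
    n_cells: int = 32,
    length: float = 1e-3,
    p_left: float = 100.0,
    p_right: float = 0.0,
    gravity: float = 0.0,
    seed: int = 0,
) -> TwoPhaseConfig:
    """Steady two-point Dirichlet pressure problem on a uniform Cartesian slab."""
    table = default_species_table()
    phases = two_phase_phases()
    grid = Grid1D.uniform("cartesian", 0.0, length, n_cells)
    omega_f = _fluid_composition()
    omega_s = {"l": 0.1, "n": 0.0, "g": 0.0, "o": 0.0, "c": 0.0, "w": 0.0,
               "y": 0.05, "e": 0.85}
    return TwoPhaseConfig(
        grid=grid,
        species_table=table,
        phases=phases,
        thermo=ThermoParams(),
        densities={"f": 1000.0, "s": 1000.0},
        reactions=[],
        transfers=[],
        closure=ClosureCoefficients(resistance={"f": 1e12}),
        initial=TwoPhaseInitial(eps_s=0.4, omega_f=omega_f, omega_s=omega_s),
        boundary=TwoPhaseBoundary(
            omega_f_outer={}, pressure_outer=p_right, pressure_inner=p_left
        ),
        solver=SolverParams(t_end=1.0, n_out=2),
        gravity=gravity,
        seed=seed,
    )


def build_twobox_transfer_fixture(
    k_transfer: float = 1.5e-11,
    species: str = "o",
    perturbation: float = 0.3,
    t_end: float = 1e4,
    n_out: int = 201,
    seed: int = 0,
) -> TwoPhaseConfig:
    """One-cell scenario with a single transferring species (two-compartment limit).

    The fluid starts with the species enriched by ``perturbation`` relative
    to the transfer-equilibrated composition, everything else frozen; the
    trajectory approaches the equal-augmented-potential equilibrium.
    """
    table = default_species_table()
    phases = two_phase_phases()
    grid = Grid1D.uniform("cartesian", 0.0, 1e-3, 1)
    omega_f = _fluid_composition()
    omega_s = _solid_composition(omega_l=0.1)
    mu0 = _transfer_mu0_offsets(omega_f, omega_s, table, (species,), "f", "s")
    # enrich the fluid-side species away from equilibrium
    omega_f[species] *= (1.0 + perturbation)
    omega_f["w"] = 1.0 - sum(omega_f[k] for k in ("g", "o", "c", "x"))
    return TwoPhaseConfig(
        grid=grid,
        species_table=table,
        phases=phases,
        thermo=ThermoParams(mu0=mu0),
        densities={"f": 1000.0, "s": 1000.0},
        reactions=[],
        transfers=[TransferSpec(species, "f", "s", k_transfer)],
        closure=ClosureCoefficients(resistance={"f": 1e12}),
        initial=TwoPhaseInitial(eps_s=0.3, omega_f=omega_f, omega_s=omega_s),
        boundary=TwoPhaseBoundary(
            omega_f_outer={}, pressure_outer=None, gauge_cell=0
        ),
        solver=SolverParams(t_end=t_end, rtol=1e-10, atol=1e-14, n_out=n_out),
        seed=seed,
    )


def build_reaction_recovery_fixture(
    k_reaction: float = 2e-12,
    t_end: float = 2e4,
    n_out: int = 51,
    seed: int = 0,
) -> TwoPhaseConfig:
    """One-cell scenario with a single active reaction (necrotic formation)."""
    cfg = build_twobox_transfer_fixture(t_end=t_end, n_out=n_out, seed=seed)
    table = cfg.species_table
    rxn = ReactionSpec(
        "necrotic_formation", "s",
        balance_stoichiometry({"l": -1.0}, "n", table),
        k_reaction,
        (monod("l", 1e-3),),
    )
    thermo = ThermoParams(mu0=_base_mu0_two_phase())
    return cfg.with_updates(reactions=[rxn], transfers=[], thermo=thermo)


def solve_equilibrium_mu0(reactions, mu_known, table, unknowns):
    """Reference potentials zeroing every reaction affinity at a given state.

    ``mu_known`` maps (species, phase) to the full chemical potential with
    the unknowns' mu0 set to zero; ``unknowns`` is a list of (species, phase)
    whose mu0 are solved from the linear system A_k = 0.
    """
    m = np.zeros((len(reactions), len(unknowns)))
    b = np.zeros(len(reactions))
    for k, rxn in enumerate(reactions):
        a0 = 0.0
        for sp, nu in rxn.stoich.items():
            a0 += mu_known[(sp, rxn.phase)] * nu * table.mw(sp)
            if (sp, rxn.phase) in unknowns:
                m[k, unknowns.index((sp, rxn.phase))] += nu * table.mw(sp)
        b[k] = -a0
    sol, res, rank, _ = np.linalg.lstsq(m, b, rcond=None)
    check = m @ sol - b
    if np.max(np.abs(check)) > 1e-6 * (1.0 + np.max(np.abs(b))):
        raise ValidationError("equilibrium mu0 system is inconsistent")
    return dict(zip(unknowns, sol))


def build_equilibrium_fixture_2p(n_cells: int = 8, seed: int = 0,
                                 t_end: float = 1e3) -> TwoPhaseConfig:
    """Constructed chemical + mechanical equilibrium state (exact fixed point).

    Shared species have matched mole fractions across the phases (zero
    transfer driving force), reference potentials are solved so every
    affinity vanishes, the pressure is uniform with matching Dirichlet data,
    and there is no gravity: the right-hand side vanishes identically.
    """
    table = default_species_table()
    phases = two_phase_phases()
    grid = Grid1D.uniform("spherical", 0.0, 1e-3, n_cells)
    omega_f = _fluid_composition({"c": 1e-6})
    omega_s = _solid_composition(omega_l=0.1, omega_n=0.02, omega_c=1e-6)
    reactions = two_phase_reactions(
        table, k_formation=2e-12, k_necrosis=1e-12, k_destruction=2e-12,
        k_lysis=1e-12,
    )
    thermo0 = ThermoParams()
    # step 1: equilibrate the nutrient/water transfers by solid-side mu0
    mu0 = _transfer_mu0_offsets(omega_f, omega_s, table, ("g", "o", "w"), "f", "s")
    # step 2: solve the remaining mu0 so every reaction affinity vanishes
    x_s = _mole_fracs(omega_s, table)

    def mu_full(sp):
        comp = (thermo0.gas_constant * thermo0.temperature / table.mw(sp)) * np.log(
            max(float(x_s[sp]), thermo0.x_floor)
        )
        return mu0.get((sp, "s"), 0.0) + comp

    mu_known = {(sp, "s"): mu_full(sp) for sp in phases["s"].members}
    unknowns = [("l", "s"), ("n", "s"), ("e", "s"), ("c", "s")]
    for u in unknowns:
        mu_known[u] -= mu0.get(u, 0.0)  # composition part only for the unknowns
    mu0.update(solve_equilibrium_mu0(reactions, mu_known, table, unknowns))
    # step 3: equilibrate the drug transfer from the solid side
    mu0.update(
        _transfer_mu0_offsets(
            omega_s, omega_f, table, ("c",), "s", "f",
            mu0_src=mu0,
        )
    )
    transfers = [TransferSpec(sp, "f", "s", 1e-7) for sp in ("g", "o", "c", "w")]
    return TwoPhaseConfig(
        grid=grid,
        species_table=table,
        phases=phases,
        thermo=ThermoParams(mu0=mu0),
        densities={"f": 1000.0, "s": 1050.0},
        reactions=reactions,
        transfers=transfers,
        closure=_default_closure_2p(),
        initial=TwoPhaseInitial(eps_s=0.3, omega_f=omega_f, omega_s=omega_s),
        boundary=TwoPhaseBoundary(omega_f_outer={}, pressure_outer=0.0),
        solver=SolverParams(t_end=t_end, rtol=1e-10, atol=1e-14, n_out=11),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Three-phase fixtures
# ---------------------------------------------------------------------------


def three_phase_reactions(
    table: SpeciesTable,
    *,
    k_formation: float = 3e-12,
    k_necrosis: float = 1e-12,
    k_destruction: float = 0.0,
    k_lysis: float = 1e-12,
    omega_crit: float = 1e-5,
) -> list[ReactionSpec]:
    """Tumor reaction network in the non-wetting (tumor fluid) phase.

    The destruction and lysis debris is lumped into the non-wetting
    background species (together with water), keeping every participant a
    member of the phase.
    """
    return [
        ReactionSpec(
            "tumor_formation", "n",
            balance_stoichiometry({"g": -1.0, "o": -1.0}, "l", table),
            k_formation, (monod("g", 1e-4), monod("o", 2e-6)),
        ),
        ReactionSpec(
            "tumor_destruction", "n",
            balance_stoichiometry({"l": -1.0, "c": -0.1, "w": 2.0}, "x", table),
            k_destruction, (monod("c", 1e-7), monod("l", 1e-3)),
        ),
        ReactionSpec(
            "necrotic_formation", "n",
            balance_stoichiometry({"l": -1.0}, "n", table),
            k_necrosis, (oxygen_switch(omega_crit, 3e-6), monod("l", 1e-3)),
        ),
        ReactionSpec(
            "necrotic_lysis", "n",
            balance_stoichiometry({"n": -1.0, "w": 1.5}, "x", table),
            k_lysis, (monod("n", 1e-6),),
        ),
    ]


def _three_phase_compositions(table):
    omega_w = {"g": 5e-4, "o": 1e-5, "c": 0.0, "z": 1e-3}
    omega_w["w"] = 1.0 - sum(omega_w.values())
    omega_n = {"n": 0.0, "c": 0.0, "x": 0.05, "g": 5e-4, "o": 1e-5, "w": 0.03}
    omega_n["l"] = 1.0 - sum(omega_n.values())
    omega_s = {"y": 0.05, "g": 5e-4, "o": 1e-5, "w": 0.02}
    omega_s["e"] = 1.0 - sum(omega_s.values())
    return omega_w, omega_n, omega_s


def _three_phase_transfer_mu0(omega_w, omega_n, omega_s, table):
    """Reference potentials equilibrating every shared-species transfer
    (w<->n and w<->s; n<->s follows transitively)."""
    mu0 = _transfer_mu0_offsets(omega_w, omega_n, table,
                                ("g", "o", "c", "w"), "w", "n")
    mu0.update(_transfer_mu0_offsets(omega_w, omega_s, table,
                                     ("g", "o", "w"), "w", "s"))
    return mu0


def build_threephase_fixture(
    seed: int = 0,
    *,
    t_end: float = 2e4,
    n_out: int = 41,
    k_necrosis: float = 1e-12,
    reactions_only: bool = False,
    transfers_only_species: str | None = None,
    perturbation: float = 0.3,
) -> ThreePhaseConfig:
    """Well-mixed three-phase tumor scenario (Table-like structure).

    Phase densities are equal (water-like tissue) so interphase transfer is
    volumetrically consistent in the closed well-mixed box.
    """
    table = default_species_table(three_phase=True)
    phases = three_phase_phases()
    omega_w, omega_n, omega_s = _three_phase_compositions(table)
    mu0 = _three_phase_transfer_mu0(omega_w, omega_n, omega_s, table)

    transfers = []
    if transfers_only_species is not None:
        transfers = [TransferSpec(transfers_only_species, "w", "n", 1.5e-11)]
        # push the wetting-phase concentration off equilibrium
        omega_w[transfers_only_species] *= (1.0 + perturbation)
        omega_w["w"] = 1.0 - sum(
            v for sp, v in omega_w.items() if sp != "w"
        )
    elif not reactions_only:
        transfers = [
            TransferSpec("g", "w", "n", 1e-7),
            TransferSpec("o", "w", "n", 1e-7),
            TransferSpec("w", "w", "n", 1e-8),
            TransferSpec("g", "w", "s", 5e-8),
            TransferSpec("o", "w", "s", 5e-8),
            TransferSpec("o", "n", "s", 5e-8),
        ]
    reactions = [] if transfers_only_species else three_phase_reactions(
        table, k_necrosis=k_necrosis
    )
    mu0.update({("l", "n"): -3.0e6, ("n", "n"): -5.0e6, ("x", "n"): -8.0e6})

    eps_w, eps_n = 0.45, 0.25
    s_w = eps_w / (eps_w + eps_n)
    area_wn0 = 1.0e4  # 1/m, ~0.1 mm structural scale
    geometry = GeometryParams(
        chi_ws=0.6, eps_ws=8e3, eps_ns=5e3, k_ns=0.0,
        contact_angle=0.5, eps_eq_kind="quadratic",
        eps_eq_param=area_wn0 / (s_w * (1.0 - s_w)) * 1.05,
    )
    closure = ClosureCoefficients(
        diffusivity={},
        resistance={"w": 1e12, "n": 5e12},
        tension={"wn": 5e-4, "ws": 4e-4, "ns": 6e-4},
        area_relaxation=1e-3,
        capillary_relaxation=1e-8,
    )
    return ThreePhaseConfig(
        species_table=table,
        phases=phases,
        thermo=ThermoParams(mu0=mu0),
        densities={"w": 1000.0, "n": 1000.0, "s": 1000.0},
        reactions=reactions,
        transfers=transfers,
        closure=closure,
        geometry=geometry,
        initial=ThreePhaseInitial(
            eps_w=eps_w, eps_n=eps_n,
            omega={"w": omega_w, "n": omega_n, "s": omega_s},
            eps_wn=area_wn0, curvature_k=1e8, pressure_n=0.0,
        ),
        solver=SolverParams(t_end=t_end, rtol=1e-11, atol=1e-16, n_out=n_out),
        seed=seed,
    )


def build_threephase_equilibrium_fixture(seed: int = 0, t_end: float = 1e3) -> ThreePhaseConfig:
    """Exact stationary three-phase state: chemical, transfer, capillary and
    interfacial-area equilibrium simultaneously."""
    cfg = build_threephase_fixture(seed=seed, t_end=t_end, n_out=11)
    table = cfg.species_table
    phases = cfg.phases
    omega_w, omega_n, omega_s = _three_phase_compositions(table)
    reactions = three_phase_reactions(table, k_destruction=2e-12)
    thermo0 = ThermoParams()
    mu0 = _three_phase_transfer_mu0(omega_w, omega_n, omega_s, table)
    x_n = _mole_fracs(omega_n, table)

    def mu_full(sp):
        comp = (thermo0.gas_constant * thermo0.temperature / table.mw(sp)) * np.log(
            max(float(x_n[sp]), thermo0.x_floor)
        )
        return mu0.get((sp, "n"), 0.0) + comp

    mu_known = {(sp, "n"): mu_full(sp) for sp in phases["n"].members}
    unknowns = [("l", "n"), ("n", "n"), ("x", "n"), ("c", "n")]
    for u in unknowns:
        mu_known[u] -= mu0.get(u, 0.0)
    mu0.update(solve_equilibrium_mu0(reactions, mu_known, table, unknowns))
    # re-equilibrate the drug transfer from the non-wetting side
    mu0.update(
        _transfer_mu0_offsets(omega_n, omega_w, table, ("c",), "n", "w",
                              mu0_src=mu0)
    )

    s_w = cfg.initial.eps_w / (cfg.initial.eps_w + cfg.initial.eps_n)
    area_eq = cfg.initial.eps_wn
    geometry = GeometryParams(
        chi_ws=cfg.geometry.chi_ws, eps_ws=cfg.geometry.eps_ws,
        eps_ns=cfg.geometry.eps_ns, k_ns=cfg.geometry.k_ns,
        contact_angle=cfg.geometry.contact_angle,
        eps_eq_kind="quadratic",
        eps_eq_param=area_eq / (s_w * (1.0 - s_w)),
    )
    return cfg.with_updates(
        reactions=reactions,
        thermo=ThermoParams(mu0=mu0),
        geometry=geometry,
        initial=ThreePhaseInitial(
            eps_w=cfg.initial.eps_w, eps_n=cfg.initial.eps_n,
            omega={"w": omega_w, "n": omega_n, "s": omega_s},
            eps_wn=area_eq, curvature_k=cfg.initial.curvature_k,
            pressure_n=0.0,
        ),
    )


# ---------------------------------------------------------------------------
# Seeded random thermodynamic states for the entropy audit
# ---------------------------------------------------------------------------


def _random_composition(rng, members):
    w = rng.dirichlet(np.ones(len(members)))
    return dict(zip(members, w))


def random_two_phase_ledger(rng: np.random.Generator) -> EntropyLedger:
    """Entropy ledger of a random non-equilibrium two-phase state.

    Random compositions, potentials, nonnegative coefficients and gradients
    are drawn; rates follow the closures, so every group is a nonnegative
    quadratic form by construction — the property the audit certifies.
    """
    table = default_species_table()
    phases = two_phase_phases()
    thermo = ThermoParams(
        mu0={(sp, ph): float(rng.normal(0.0, 1e5))
             for ph in ("f", "s") for sp in phases[ph].members}
    )
    from .species import phase_potentials

    omega = {ph: _random_composition(rng, phases[ph].members) for ph in ("f", "s")}
    mu = {ph: phase_potentials(phases[ph], omega[ph], thermo, table) for ph in ("f", "s")}
    eps_s = float(rng.uniform(0.1, 0.9))
    eps = {"f": 1.0 - eps_s, "s": eps_s}
    psi = {"f": float(rng.normal(0.0, 1e3)), "s": float(rng.normal(0.0, 1e3))}

    reactions = two_phase_reactions(
        table,
        k_formation=float(rng.uniform(0.0, 1e-11)),
        k_necrosis=float(rng.uniform(0.0, 1e-11)),
        k_destruction=float(rng.uniform(0.0, 1e-11)),
        k_lysis=float(rng.uniform(0.0, 1e-11)),
    )
    reaction_terms = []
    for rxn in reactions:
        aff = sum(mu[rxn.phase][sp] * nu * table.mw(sp) for sp, nu in rxn.stoich.items())
        k_eff = float(rxn.effective_coeff(omega[rxn.phase]))
        reaction_terms.append((eps[rxn.phase] * k_eff, aff))

    transfer_terms = []
    for sp in ("g", "o", "c", "w"):
        coeff = float(rng.uniform(0.0, 1e-6))
        delta = mu["f"][sp] + psi["f"] - mu["s"][sp] - psi["s"]
        transfer_terms.append((coeff, delta))

    diffusion_terms = [
        (eps["f"] * 1000.0 * float(rng.uniform(0.0, 1e-9)), float(rng.normal(0.0, 1e4)))
        for _ in range(4)
    ]
    momentum_terms = [(float(rng.uniform(0.0, 1e12)), float(rng.normal(0.0, 1e-6)))]
    porosity_terms = [(float(rng.uniform(0.0, 1e-10)), float(rng.normal(0.0, 1e2)))]
    return audit_two_phase(
        thermo.temperature,
        reaction_terms=reaction_terms,
        transfer_terms=transfer_terms,
        diffusion_terms=diffusion_terms,
        momentum_fluid_terms=momentum_terms,
        porosity_terms=porosity_terms,
    )


def random_three_phase_ledger(rng: np.random.Generator) -> EntropyLedger:
    """Entropy ledger of a random non-equilibrium three-phase state."""
    table = default_species_table(three_phase=True)
    phases = three_phase_phases()
    thermo = ThermoParams(
        mu0={(sp, ph): float(rng.normal(0.0, 1e5))
             for ph in ("w", "n", "s") for sp in phases[ph].members}
    )
    from .species import phase_potentials

    omega = {ph: _random_composition(rng, phases[ph].members) for ph in ("w", "n", "s")}
    mu = {ph: phase_potentials(phases[ph], omega[ph], thermo, table)
          for ph in ("w", "n", "s")}
    e = rng.dirichlet(np.ones(3))
    eps = {"w": float(e[0]), "n": float(e[1]), "s": float(e[2])}
    psi = {ph: float(rng.normal(0.0, 1e3)) for ph in ("w", "n", "s")}

    reactions = three_phase_reactions(
        table,
        k_formation=float(rng.uniform(0.0, 1e-11)),
        k_necrosis=float(rng.uniform(0.0, 1e-11)),
        k_destruction=float(rng.uniform(0.0, 1e-11)),
        k_lysis=float(rng.uniform(0.0, 1e-11)),
    )
    reaction_terms = []
    for rxn in reactions:
        aff = sum(mu[rxn.phase][sp] * nu * table.mw(sp) for sp, nu in rxn.stoich.items())
        reaction_terms.append(
            (eps[rxn.phase] * float(rxn.effective_coeff(omega[rxn.phase])), aff)
        )

    def pair_terms(a, b, species_list):
        out = []
        for sp in species_list:
            coeff = float(rng.uniform(0.0, 1e-6))
            delta = mu[a][sp] + psi[a] - mu[b][sp] - psi[b]
            out.append((coeff, delta))
        return out

    return audit_three_phase(
        thermo.temperature,
        reaction_terms=reaction_terms,
        transfer_wn_terms=pair_terms("w", "n", ("g", "o", "c", "w")),
        transfer_ws_terms=pair_terms("w", "s", ("g", "o", "w")),
        transfer_ns_terms=pair_terms("n", "s", ("g", "o", "w")),
        diffusion_terms=[(float(rng.uniform(0.0, 1e-6)), float(rng.normal(0.0, 1e4)))
                         for _ in range(3)],
        momentum_w_terms=[(float(rng.uniform(0.0, 1e12)), float(rng.normal(0.0, 1e-6)))],
        momentum_n_terms=[(float(rng.uniform(0.0, 1e12)), float(rng.normal(0.0, 1e-6)))],
        capillary_terms=[(float(rng.uniform(0.0, 1e-7)), float(rng.normal(0.0, 10.0)))],
        porosity_ws_terms=[(float(rng.uniform(0.0, 1e-10)), float(rng.normal(0.0, 1e2)))],
        porosity_ns_terms=[(float(rng.uniform(0.0, 1e-10)), float(rng.normal(0.0, 1e2)))],
    )
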