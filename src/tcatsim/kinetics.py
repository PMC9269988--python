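"""Affinity-based homogeneous reactions and conjugate flux-force mass transfer.

Each reaction k in phase alpha is closed linearly in its chemical affinity,

    R_k = -Khat_k * A_k,      A_k = sum_i mu_i * nu_ik * MW_i,

with ``Khat_k >= 0``, so the entropy production of the reaction group,
``(eps / theta) * Khat * A**2``, is nonnegative identically.  Mass balance
of the stoichiometry, ``sum_i nu_i MW_i = 0``, makes the affinity invariant
under a uniform additive shift of all potentials.

Interphase mass transfer of a shared species is driven by the difference in
augmented potential (chemical plus body-force potential):

    M(donor->receiver) = Khat_M * (mu_d + psi_d - mu_r - psi_r),

again with a nonnegative coefficient so the transfer entropy production is
a nonnegative quadratic form.

Rate coefficients may carry a state-dependent, nonnegative modulation
factor (e.g. an oxygen switch for necrotic formation, or a Monod-type
nutrient factor); any nonnegative modulation preserves the entropy sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .species import PhaseDef, SpeciesTable, ValidationError

__all__ = [
    "ReactionSpec",
    "TransferSpec",
    "Modulation",
    "oxygen_switch",
    "monod",
    "balance_stoichiometry",
    "validate_reaction",
    "affinity",
    "reaction_rate",
    "species_production",
    "transfer_rate",
]

_MASS_BALANCE_TOL = 1e-12

ArrayLike = np.ndarray | float
OmegaMap = Mapping[str, ArrayLike]


@dataclass(frozen=True)
class Modulation:
    """Named, serializable nonnegative rate-coefficient modulation factor."""

    kind: str
    species: str
    params: tuple[tuple[str, float], ...]

    def __call__(self, omega: OmegaMap) -> ArrayLike:
        w = np.asarray(omega[self.species], dtype=float)
        p = dict(self.params)
        if self.kind == "oxygen_switch":
            # Smooth sigmoid switch: ~1 when omega << omega_crit, ~0 when
            # omega >> omega_crit; width delta.
            z = (p["omega_crit"] - w) / p["delta"]
            out = 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))
        elif self.kind == "monod":
            wp = np.maximum(w, 0.0)
            out = wp / (wp + p["half_sat"])
        else:  # pragma: no cover - guarded at construction
            raise ValidationError(f"unknown modulation kind {self.kind!r}")
        return out if np.ndim(out) else float(out)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "species": self.species, **dict(self.params)}


def oxygen_switch(omega_crit: float, delta: float, species: str = "o") -> Modulation:
    """Hypoxia switch: activates a reaction as the local oxygen fraction drops."""
    if delta <= 0.0:
        raise ValidationError("oxygen_switch width delta must be positive")
    return Modulation(
        "oxygen_switch", species, (("omega_crit", float(omega_crit)), ("delta", float(delta)))
    )


def monod(species: str, half_sat: float) -> Modulation:
    """Saturable factor omega/(omega + K) that freezes a reaction as a reactant vanishes."""
    if half_sat <= 0.0:
        raise ValidationError("monod half_sat must be positive")
    return Modulation("monod", species, (("half_sat", float(half_sat)),))


@dataclass(frozen=True)
class ReactionSpec:
    """One homogeneous reaction: signed molar stoichiometry and a linear rate coefficient.

    Reactants carry negative ``nu``, products positive.  ``rate_coeff`` is the
    baseline Khat (mol^2/(J m^3 s) scale); ``modulations`` multiply it by
    nonnegative state-dependent factors.
    """

    id: str
    phase: str
    stoich: Mapping[str, float]
    rate_coeff: float
    modulations: tuple[Modulation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.stoich:
            raise ValidationError(f"reaction {self.id!r}: stoichiometry is empty")
        if self.rate_coeff < 0.0:
            raise ValidationError(
                f"reaction {self.id!r}: rate coefficient must be nonnegative, "
                f"got {self.rate_coeff}"
            )

    def effective_coeff(self, omega: OmegaMap | None = None) -> ArrayLike:
        k = self.rate_coeff
        if omega is not None:
            for m in self.modulations:
                k = k * m(omega)
        return k


@dataclass(frozen=True)
class TransferSpec:
    """Interphase mass transfer of one species between a phase pair."""

    species: str
    donor: str
    receiver: str
    coeff: float  # Khat_M >= 0, kg^2/(J m^3 s) scale

    def __post_init__(self) -> None:
        if self.coeff < 0.0:
            raise ValidationError(
                f"transfer {self.species!r} {self.donor}->{self.receiver}: "
                f"coefficient must be nonnegative, got {self.coeff}"
            )
        if self.donor == self.receiver:
            raise ValidationError("transfer donor and receiver phases must differ")


def balance_stoichiometry(
    stoich: Mapping[str, float],
    free_species: str,
    species_table: SpeciesTable,
) -> dict[str, float]:
    """Solve the coefficient of ``free_species`` so that ``sum nu_i MW_i = 0``."""
    residual = sum(
        nu * species_table.mw(sp) for sp, nu in stoich.items() if sp != free_species
    )
    out = dict(stoich)
    out[free_species] = -residual / species_table.mw(free_species)
    return out


def validate_reaction(
    reaction: ReactionSpec, species_table: SpeciesTable
) -> dict:
    """Mass-balance and sign report for one reaction.

    Returns ``{"ok": bool, "residual_mass": kg/mol, "messages": [...]}``;
    raises nothing so callers can aggregate reports.
    """
    messages: list[str] = []
    residual = sum(nu * species_table.mw(sp) for sp, nu in reaction.stoich.items())
    if abs(residual) > _MASS_BALANCE_TOL:
        messages.append(
            f"reaction {reaction.id!r}: stoichiometry not mass balanced, "
            f"residual mass {residual:+.6e} kg/mol"
        )
    if reaction.rate_coeff < 0.0:  # unreachable through the constructor
        messages.append(f"reaction {reaction.id!r}: negative rate coefficient")
    return {"ok": not messages, "residual_mass": residual, "messages": messages}


def require_valid(reactions: Iterable[ReactionSpec], species_table: SpeciesTable) -> None:
    problems = []
    for rxn in reactions:
        rep = validate_reaction(rxn, species_table)
        if not rep["ok"]:
            problems.extend(rep["messages"])
    if problems:
        raise ValidationError("; ".join(problems))


def affinity(
    reaction: ReactionSpec,
    chemical_potentials: Mapping[str, ArrayLike],
    species_table: SpeciesTable,
) -> ArrayLike:
    """Chemical affinity A = sum_i mu_i nu_i MW_i (J/mol); zero at equilibrium."""
    a: ArrayLike = 0.0
    for sp, nu in reaction.stoich.items():
        if sp not in chemical_potentials:
            raise ValidationError(
                f"reaction {reaction.id!r}: missing chemical potential for {sp!r}"
            )
        a = a + np.asarray(chemical_potentials[sp], dtype=float) * nu * species_table.mw(sp)
    return a if np.ndim(a) else float(a)


def reaction_rate(
    reaction: ReactionSpec,
    affinity_value: ArrayLike,
    omega: OmegaMap | None = None,
) -> ArrayLike:
    """Molar reaction rate R = -Khat_eff * A (mol/(m^3 s))."""
    k = reaction.effective_coeff(omega)
    if np.any(np.asarray(k) < 0.0):
        raise ValidationError(f"reaction {reaction.id!r}: negative effective coefficient")
    r = -np.asarray(k, dtype=float) * np.asarray(affinity_value, dtype=float)
    return r if np.ndim(r) else float(r)


def species_production(
    reactions: Sequence[ReactionSpec],
    potentials_by_phase: Mapping[str, Mapping[str, ArrayLike]],
    species_table: SpeciesTable,
    omega_by_phase: Mapping[str, OmegaMap] | None = None,
    phases: Mapping[str, PhaseDef] | None = None,
) -> dict[tuple[str, str], ArrayLike]:
    """Net mass production r^{i,alpha} = sum_k nu_ik MW_i R_k (kg/(m^3 s)).

    Each reaction contributes zero net mass (``sum_i nu_i MW_i = 0``), so the
    per-phase sum over species vanishes to machine precision.
    """
    out: dict[tuple[str, str], ArrayLike] = {}
    for rxn in reactions:
        if phases is not None:
            members = phases[rxn.phase].members
            missing = [sp for sp in rxn.stoich if sp not in members]
            if missing:
                raise ValidationError(
                    f"reaction {rxn.id!r} assigned to phase {rxn.phase!r} which "
                    f"lacks species {missing}"
                )
        mu = potentials_by_phase[rxn.phase]
        omega = None if omega_by_phase is None else omega_by_phase.get(rxn.phase)
        rate = reaction_rate(rxn, affinity(rxn, mu, species_table), omega)
        for sp, nu in rxn.stoich.items():
            key = (sp, rxn.phase)
            contrib = nu * species_table.mw(sp) * np.asarray(rate, dtype=float)
            prev = out.get(key, 0.0)
            tot = prev + contrib
            out[key] = tot if np.ndim(tot) else float(tot)
    return out


def transfer_rate(
    spec: TransferSpec,
    mu_donor: ArrayLike,
    psi_donor: ArrayLike,
    mu_receiver: ArrayLike,
    psi_receiver: ArrayLike,
) -> ArrayLike:
    """Mass transfer density rate donor -> receiver (kg/(m^3 s)).

    Positive when the donor's augmented potential exceeds the receiver's;
    antisymmetric under swapping the two phases.
    """
    delta = (
        np.asarray(mu_donor, dtype=float)
        + np.asarray(psi_donor, dtype=float)
        - np.asarray(mu_receiver, dtype=float)
        - np.asarray(psi_receiver, dtype=float)
    )
    m = spec.coeff * delta
    return m if np.ndim(m) else float(m)
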