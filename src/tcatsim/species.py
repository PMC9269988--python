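"""Species registry, phase composition bookkeeping, and macroscale thermodynamics.

The macroscale state of each phase is described by a volume fraction, an
intrinsic mass density, species mass fractions, a pressure and a velocity.
Chemical potentials follow the ideal (unit activity coefficient) form

    mu_i = mu0_i + (R_g * theta / MW_i) * ln(x_i),

with ``x_i`` the mole fraction, ``MW_i`` the molar mass, and ``mu0_i`` a
per-(species, phase) reference potential.  The system is isothermal, so
``mu0`` is carried as a constant supplied by the scenario configuration.

All quantities are SI: molar masses in kg/mol, potentials in J/kg,
temperature in K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SpeciesTable",
    "PhaseDef",
    "ThermoParams",
    "PhaseState",
    "CompositionState",
    "TWO_PHASE_SPECIES",
    "THREE_PHASE_SPECIES",
    "phase_molecular_weight",
    "mole_fractions",
    "mass_fractions_from_mole",
    "chemical_potential",
    "phase_potentials",
]

#: Nine-species set used by two-phase scenarios: living tumor (l), necrotic
#: tumor (n), extra-cellular matrix (e), glucose (g), oxygen (o),
#: chemotherapeutic drug (c), water (w), fluid background (x), solid
#: background (y).
TWO_PHASE_SPECIES = ("l", "n", "e", "g", "o", "c", "w", "x", "y")

#: Ten-species set for three-phase scenarios; adds the wetting-phase
#: background species z.
THREE_PHASE_SPECIES = TWO_PHASE_SPECIES + ("z",)

_MASS_FRACTION_SUM_TOL = 1e-8
_NEGATIVE_OMEGA_TOL = 1e-12


class ValidationError(ValueError):
    """Raised when a state or parameter set violates a structural invariant."""


@dataclass(frozen=True)
class SpeciesTable:
    """Registry of chemical species and their molar masses (kg/mol)."""

    molar_mass: Mapping[str, float]

    def __post_init__(self) -> None:
        for sp, mw in self.molar_mass.items():
            if not np.isfinite(mw) or mw <= 0.0:
                raise ValidationError(
                    f"molar mass of species {sp!r} must be strictly positive, got {mw}"
                )

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(self.molar_mass)

    def mw(self, species: str) -> float:
        try:
            return float(self.molar_mass[species])
        except KeyError:
            raise ValidationError(f"unknown species {species!r}") from None


@dataclass(frozen=True)
class PhaseDef:
    """Phase membership and the dominant reference species.

    The reference species N is the one eliminated by the closure constraint
    ``sum_i omega_i = 1``; its deviation velocity is completed from the
    others so that ``sum_i omega_i u_i = 0`` holds exactly.
    """

    phase_id: str
    members: tuple[str, ...]
    reference_species: str

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"phase {self.phase_id!r} has duplicate members")
        if self.reference_species not in self.members:
            raise ValidationError(
                f"reference species {self.reference_species!r} is not a member of "
                f"phase {self.phase_id!r}"
            )

    @property
    def transported(self) -> tuple[str, ...]:
        """Members other than the reference species (independent unknowns)."""
        return tuple(s for s in self.members if s != self.reference_species)


@dataclass(frozen=True)
class ThermoParams:
    """Isothermal macroscale thermodynamic parameters.

    ``mu0`` maps ``(species, phase_id)`` to the reference-state chemical
    potential in J/kg.  ``x_floor`` bounds mole fractions away from zero
    inside the logarithm only, keeping potentials finite for vanishing
    species without perturbing any mass balance.
    """

    temperature: float = 310.0
    gas_constant: float = 8.314
    mu0: Mapping[tuple[str, str], float] = field(default_factory=dict)
    x_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.temperature <= 0.0:
            raise ValidationError(f"temperature must be positive, got {self.temperature}")
        if not (0.0 < self.x_floor <= 1e-6):
            raise ValidationError(f"x_floor must lie in (0, 1e-6], got {self.x_floor}")

    def mu0_of(self, species: str, phase: str) -> float:
        return float(self.mu0.get((species, phase), 0.0))


def _check_normalized(mass_fractions: Mapping[str, np.ndarray | float]) -> None:
    total = sum(np.asarray(v, dtype=float) for v in mass_fractions.values())
    if np.any(np.abs(total - 1.0) > _MASS_FRACTION_SUM_TOL):
        worst = float(np.max(np.abs(total - 1.0)))
        raise ValidationError(
            f"mass fractions must sum to 1 within {_MASS_FRACTION_SUM_TOL}; "
            f"worst residual {worst:.3e}"
        )


def sanitize_mass_fractions(
    mass_fractions: Mapping[str, np.ndarray | float],
) -> dict[str, np.ndarray | float]:
    """Zero values in [-1e-12, 0) with a warning; reject anything below."""
    out: dict[str, np.ndarray | float] = {}
    for sp, v in mass_fractions.items():
        arr = np.asarray(v, dtype=float)
        if np.any(arr < -_NEGATIVE_OMEGA_TOL):
            raise ValidationError(
                f"mass fraction of {sp!r} below -{_NEGATIVE_OMEGA_TOL:g}: "
                f"min {float(np.min(arr)):.3e}"
            )
        if np.any(arr < 0.0):
            warnings.warn(
                f"zeroing tiny negative mass fraction(s) of {sp!r}", stacklevel=2
            )
            arr = np.where(arr < 0.0, 0.0, arr)
        out[sp] = arr if arr.ndim else float(arr)
    return out


def phase_molecular_weight(
    mass_fractions: Mapping[str, np.ndarray | float],
    species_table: SpeciesTable,
) -> np.ndarray | float:
    """Molar mass of a phase: ``MW = (sum_i omega_i / MW_i)^(-1)`` (kg/mol).

    Equivalently the mole-fraction weighted mean ``sum_i MW_i x_i``; the two
    expressions agree identically for normalized compositions.
    """
    _check_normalized(mass_fractions)
    inv = sum(
        np.asarray(v, dtype=float) / species_table.mw(sp)
        for sp, v in mass_fractions.items()
    )
    out = 1.0 / inv
    return out if np.ndim(out) else float(out)


def mole_fractions(
    mass_fractions: Mapping[str, np.ndarray | float],
    species_table: SpeciesTable,
) -> dict[str, np.ndarray | float]:
    """Convert mass fractions to mole fractions within a phase.

    ``x_i = (omega_i / MW_i) / sum_j (omega_j / MW_j)``; the result sums to 1.
    """
    _check_normalized(mass_fractions)
    moles = {
        sp: np.asarray(v, dtype=float) / species_table.mw(sp)
        for sp, v in mass_fractions.items()
    }
    total = sum(moles.values())
    if np.any(np.asarray(total) <= 0.0):
        raise ValidationError("zero total moles in phase composition")
    out: dict[str, np.ndarray | float] = {}
    for sp, m in moles.items():
        x = m / total
        out[sp] = x if np.ndim(x) else float(x)
    return out


def mass_fractions_from_mole(
    mole_fracs: Mapping[str, np.ndarray | float],
    species_table: SpeciesTable,
) -> dict[str, np.ndarray | float]:
    """Inverse of :func:`mole_fractions` (uses ``omega_i = x_i MW_i / MW^alpha``)."""
    mw_alpha = sum(
        np.asarray(x, dtype=float) * species_table.mw(sp)
        for sp, x in mole_fracs.items()
    )
    out: dict[str, np.ndarray | float] = {}
    for sp, x in mole_fracs.items():
        w = np.asarray(x, dtype=float) * species_table.mw(sp) / mw_alpha
        out[sp] = w if np.ndim(w) else float(w)
    return out


def chemical_potential(
    species: str,
    phase: str,
    mole_fraction: np.ndarray | float,
    thermo: ThermoParams,
    species_table: SpeciesTable,
) -> np.ndarray | float:
    """Macroscale chemical potential (J/kg) with unit activity coefficient.

    ``mu = mu0 + (R_g theta / MW_i) ln(max(x, x_floor))``.  The floor is
    applied inside the logarithm only, so vanishing species have a finite
    (very negative) potential.
    """
    x = np.maximum(np.asarray(mole_fraction, dtype=float), thermo.x_floor)
    mu = thermo.mu0_of(species, phase) + (
        thermo.gas_constant * thermo.temperature / species_table.mw(species)
    ) * np.log(x)
    return mu if np.ndim(mu) else float(mu)


def phase_potentials(
    phase: PhaseDef,
    mass_fractions: Mapping[str, np.ndarray | float],
    thermo: ThermoParams,
    species_table: SpeciesTable,
) -> dict[str, np.ndarray | float]:
    """Chemical potentials for every member of a phase from its composition."""
    x = mole_fractions(mass_fractions, species_table)
    return {
        sp: chemical_potential(sp, phase.phase_id, x[sp], thermo, species_table)
        for sp in phase.members
    }


@dataclass
class PhaseState:
    """Macroscale state of one phase (fields may be scalars or cell arrays)."""

    volume_fraction: np.ndarray | float
    density: np.ndarray | float
    mass_fractions: dict[str, np.ndarray | float]
    pressure: np.ndarray | float = 0.0
    velocity: np.ndarray | float = 0.0
    body_potential: float = 0.0  # psi, identical for all species in a phase


@dataclass
class CompositionState:
    """Joint state of all phases; validates the closure constraints."""

    phases: dict[str, PhaseState]

    def validate(self) -> None:
        eps_total = sum(
            np.asarray(p.volume_fraction, dtype=float) for p in self.phases.values()
        )
        if np.any(np.abs(eps_total - 1.0) > 1e-12):
            raise ValidationError(
                "phase volume fractions must sum to 1 within 1e-12; worst "
                f"residual {float(np.max(np.abs(eps_total - 1.0))):.3e}"
            )
        for pid, p in self.phases.items():
            eps = np.asarray(p.volume_fraction, dtype=float)
            if np.any((eps < 0.0) | (eps > 1.0)):
                raise ValidationError(f"volume fraction of phase {pid!r} outside [0, 1]")
            total = sum(np.asarray(v, dtype=float) for v in p.mass_fractions.values())
            if np.any(np.abs(total - 1.0) > 1e-10):
                raise ValidationError(
                    f"mass fractions of phase {pid!r} must sum to 1 within 1e-10"
                )
            for sp, v in p.mass_fractions.items():
                if np.any(np.asarray(v, dtype=float) < -_NEGATIVE_OMEGA_TOL):
                    raise ValidationError(
                        f"negative mass fraction of {sp!r} in phase {pid!r}"
                    )
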