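"""Entropy-production auditor for the restricted entropy inequalities.

Each closure, substituted back into its flux-force pair, contributes a
quadratic production density ``coeff * force**2 / theta`` with a nonnegative
coefficient: reaction (eps * Khat * A^2), transfer (Khat_M * dmu^2), diffusion
(eps rho grad(dmu) . Dhat . grad(dmu)), momentum ((v - v_s) . Rhat . (v - v_s)),
porosity (chat * bracket^2) and capillary relaxation (chat_wn * diseq^2).
Groups closed at zero order (phase and interface stresses) are reported as
structurally zero so the ledger mirrors the line structure of the inequality.

The audit certifies closure consistency: if every coefficient is nonnegative,
every group — and hence the total production Lambda — is nonnegative for any
state; a negative group flags a coefficient that violates the inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .species import ValidationError

__all__ = ["EntropyLedger", "quadratic_group", "audit_two_phase", "audit_three_phase"]

TWO_PHASE_GROUPS = (
    "stress_fluid",
    "stress_solid",
    "stress_interface",
    "diffusion",
    "reaction",
    "transfer",
    "momentum_fluid",
    "momentum_interface",
    "porosity",
)

THREE_PHASE_GROUPS = (
    "stress_fluid",
    "stress_solid",
    "stress_interface",
    "diffusion",
    "reaction",
    "transfer_wn",
    "transfer_ws",
    "transfer_ns",
    "momentum_w",
    "momentum_n",
    "momentum_interface",
    "capillary_relaxation",
    "porosity_ws",
    "porosity_ns",
)

_FLAG_TOL = 1e-14


@dataclass
class EntropyLedger:
    """Named entropy-production term groups (density per time) and their total."""

    groups: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.groups.values()))

    @property
    def min_group(self) -> float:
        return float(min(self.groups.values())) if self.groups else 0.0

    @property
    def flagged(self) -> list[str]:
        """Groups with production below -1e-14: second-law violations."""
        return sorted(name for name, v in self.groups.items() if v < -_FLAG_TOL)

    def to_dict(self) -> dict[str, float]:
        out = {name: float(v) for name, v in self.groups.items()}
        out["total"] = self.total
        return out


def quadratic_group(terms: Iterable[tuple[float, float]], theta: float) -> float:
    """Sum of coeff * force^2 / theta over (coeff, force) pairs."""
    return float(sum(c * f * f for c, f in terms)) / theta


def _base_audit(
    theta: float,
    group_names: Sequence[str],
    contributions: dict[str, Iterable[tuple[float, float]]],
) -> EntropyLedger:
    if theta <= 0.0:
        raise ValidationError(f"temperature must be positive, got {theta}")
    groups = {name: 0.0 for name in group_names}
    for name, terms in contributions.items():
        if name not in groups:
            raise ValidationError(f"unknown entropy ledger group {name!r}")
        groups[name] = quadratic_group(terms, theta)
    return EntropyLedger(groups)


def audit_two_phase(
    theta: float,
    *,
    reaction_terms: Iterable[tuple[float, float]] = (),
    transfer_terms: Iterable[tuple[float, float]] = (),
    diffusion_terms: Iterable[tuple[float, float]] = (),
    momentum_fluid_terms: Iterable[tuple[float, float]] = (),
    momentum_interface_terms: Iterable[tuple[float, float]] = (),
    porosity_terms: Iterable[tuple[float, float]] = (),
) -> EntropyLedger:
    """Two-phase restricted-inequality ledger from (coefficient, force) pairs.

    Reaction pairs are ``(eps * Khat_eff, A)``; transfer pairs
    ``(Khat_M, d(mu+psi))``; diffusion pairs ``(eps rho Dhat_i, |grad d mu|)``;
    momentum pairs ``(Rhat, |v_f - v_s|)``; porosity pairs
    ``(chat, normal-force bracket)``.  Stress groups are structurally zero.
    """
    return _base_audit(
        theta,
        TWO_PHASE_GROUPS,
        {
            "reaction": reaction_terms,
            "transfer": transfer_terms,
            "diffusion": diffusion_terms,
            "momentum_fluid": momentum_fluid_terms,
            "momentum_interface": momentum_interface_terms,
            "porosity": porosity_terms,
        },
    )


def audit_three_phase(
    theta: float,
    *,
    reaction_terms: Iterable[tuple[float, float]] = (),
    transfer_wn_terms: Iterable[tuple[float, float]] = (),
    transfer_ws_terms: Iterable[tuple[float, float]] = (),
    transfer_ns_terms: Iterable[tuple[float, float]] = (),
    diffusion_terms: Iterable[tuple[float, float]] = (),
    momentum_w_terms: Iterable[tuple[float, float]] = (),
    momentum_n_terms: Iterable[tuple[float, float]] = (),
    momentum_interface_terms: Iterable[tuple[float, float]] = (),
    capillary_terms: Iterable[tuple[float, float]] = (),
    porosity_ws_terms: Iterable[tuple[float, float]] = (),
    porosity_ns_terms: Iterable[tuple[float, float]] = (),
) -> EntropyLedger:
    """Three-phase ledger; adds per-pair transfer, capillary and wetting groups."""
    return _base_audit(
        theta,
        THREE_PHASE_GROUPS,
        {
            "reaction": reaction_terms,
            "transfer_wn": transfer_wn_terms,
            "transfer_ws": transfer_ws_terms,
            "transfer_ns": transfer_ns_terms,
            "diffusion": diffusion_terms,
            "momentum_w": momentum_w_terms,
            "momentum_n": momentum_n_terms,
            "momentum_interface": momentum_interface_terms,
            "capillary_relaxation": capillary_terms,
            "porosity_ws": porosity_ws_terms,
            "porosity_ns": porosity_ns_terms,
        },
    )
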