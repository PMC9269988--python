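"""Algebraic constitutive closures derived from the restricted entropy inequalities.

Every closure here is a zero- or first-order conjugate flux-force form whose
entropy production is a nonnegative quadratic: isotropic phase stress,
interfacial stress from tension and orientation, chemical-potential-driven
diffusion with reference-species completion, quasi-static momentum balance
(Darcy-like resistance), porosity evolution from the normal force balance on
the solid surface, and capillary-pressure relaxation toward Young-Laplace
equilibrium.

Mobility parameterization: the diffusion tensor for species i is taken as

    Dhat_i = d_i * omega_i * MW_i / (R_g * theta) * I,

so that in the dilute limit the closure degenerates to Fickian diffusion
with diffusivity ``d_i`` (standard Maxwell-Stefan-to-Fick reduction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .species import PhaseDef, SpeciesTable, ThermoParams, ValidationError

__all__ = [
    "ClosureCoefficients",
    "phase_stress",
    "interface_stress",
    "mobility",
    "diffusive_flux",
    "fluid_velocity",
    "porosity_rate",
    "capillary_relaxation_rate",
    "invert_capillary_pressure",
]

ArrayLike = np.ndarray | float


def _as_matrix(value: ArrayLike | np.ndarray, dim: int = 3) -> np.ndarray:
    """Coerce a scalar / diagonal / full symmetric input to a (dim, dim) matrix."""
    a = np.asarray(value, dtype=float)
    if a.ndim == 0:
        return float(a) * np.eye(dim)
    if a.ndim == 1:
        if a.shape[0] != dim:
            raise ValidationError(f"diagonal tensor must have length {dim}")
        return np.diag(a)
    if a.shape != (dim, dim):
        raise ValidationError(f"tensor must be {dim}x{dim}, got {a.shape}")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValidationError("tensor must be symmetric")
    return a


@dataclass(frozen=True)
class ClosureCoefficients:
    """Closure coefficients for one scenario (all SI units).

    diffusivity: per-phase map of species -> d_i (m^2/s).
    resistance: per fluid phase, scalar/diagonal/full PSD tensor (Pa s/m^2).
    cross_resistance: optional coupling between the two fluids (3P).
    compressibility: chat (2P) / chat_ss (3P), nonnegative (1/(Pa s)).
    tension: interfacial tensions per interface id ('fs', 'wn', 'ws', 'ns') (N/m).
    orientation: per interface, diagonal tensor of trace 1 (isotropic I/3).
    area_relaxation: khat_wn (1/s); capillary_relaxation: chat_wn (nonnegative).
    area_capillary_coupling: khat1_wn in the capillary relaxation closure.
    contact_angle: constant wetting contact angle (rad).
    """

    diffusivity: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    resistance: Mapping[str, ArrayLike] = field(default_factory=dict)
    cross_resistance: Mapping[tuple[str, str], ArrayLike] = field(default_factory=dict)
    compressibility: float = 0.0
    tension: Mapping[str, float] = field(default_factory=dict)
    orientation: Mapping[str, np.ndarray] = field(default_factory=dict)
    area_relaxation: float = 0.0
    capillary_relaxation: float = 0.0
    area_capillary_coupling: float = 0.0
    contact_angle: float = 0.0

    def __post_init__(self) -> None:
        for ph, per_species in self.diffusivity.items():
            for sp, d in per_species.items():
                if d < 0.0:
                    raise ValidationError(
                        f"diffusivity[{ph!r}][{sp!r}] must be nonnegative, got {d}"
                    )
        for name, val in (
            ("compressibility", self.compressibility),
            ("area_relaxation", self.area_relaxation),
            ("capillary_relaxation", self.capillary_relaxation),
            ("area_capillary_coupling", self.area_capillary_coupling),
        ):
            if val < 0.0:
                raise ValidationError(f"{name} must be nonnegative, got {val}")
        for ph, r in self.resistance.items():
            m = _as_matrix(r)
            eig = np.linalg.eigvalsh(m)
            if np.min(eig) < -1e-12:
                raise ValidationError(f"resistance tensor of phase {ph!r} is not PSD")

    def d_of(self, phase: str, species: str) -> float:
        return float(self.diffusivity.get(phase, {}).get(species, 0.0))

    def resistance_of(self, phase: str) -> np.ndarray:
        if phase not in self.resistance:
            raise ValidationError(f"no resistance tensor configured for phase {phase!r}")
        return _as_matrix(self.resistance[phase])

    def orientation_of(self, interface: str) -> np.ndarray:
        g = self.orientation.get(interface)
        if g is None:
            return np.eye(3) / 3.0
        m = _as_matrix(g)
        if abs(np.trace(m) - 1.0) > 1e-10:
            raise ValidationError(
                f"orientation tensor of interface {interface!r} must have trace 1"
            )
        return m


def phase_stress(pressure: float) -> np.ndarray:
    """Zero-order fluid stress closure: t = -p I (Pa)."""
    return -float(pressure) * np.eye(3)


def interface_stress(tension: float, orientation: np.ndarray | ArrayLike) -> np.ndarray:
    """Interfacial stress t = gamma (I - G) (N/m); trace equals 2*gamma."""
    g = _as_matrix(orientation)
    if abs(np.trace(g) - 1.0) > 1e-10:
        raise ValidationError("orientation tensor must have trace 1")
    return float(tension) * (np.eye(3) - g)


def mobility(
    species: str,
    omega: ArrayLike,
    thermo: ThermoParams,
    species_table: SpeciesTable,
    d: float,
) -> ArrayLike:
    """Scalar mobility Dhat_i = d_i omega_i MW_i / (R_g theta) (isotropic)."""
    return (
        d
        * np.asarray(omega, dtype=float)
        * species_table.mw(species)
        / (thermo.gas_constant * thermo.temperature)
    )


def diffusive_flux(
    phase: PhaseDef,
    eps: ArrayLike,
    rho: ArrayLike,
    omega: Mapping[str, ArrayLike],
    potential_gradients: Mapping[str, ArrayLike],
    coeffs: ClosureCoefficients,
    thermo: ThermoParams,
    species_table: SpeciesTable,
) -> dict[str, ArrayLike]:
    """Diffusive mass fluxes eps*rho*omega_i*u_i (kg/(m^2 s)) for one phase.

    Non-reference species follow the first-order closure
    ``-eps rho Dhat_i grad(mu_i - mu_N)``; the reference-species flux is the
    negative sum of the others so ``sum_i omega_i u_i = 0`` holds exactly.
    """
    for sp in potential_gradients:
        if sp not in phase.members:
            raise ValidationError(
                f"potential gradient supplied for {sp!r}, not a member of "
                f"phase {phase.phase_id!r}"
            )
    ref = phase.reference_species
    if ref not in potential_gradients:
        raise ValidationError(
            f"reference-species potential gradient required for phase {phase.phase_id!r}"
        )
    grad_ref = np.asarray(potential_gradients[ref], dtype=float)
    fluxes: dict[str, ArrayLike] = {}
    total: ArrayLike = 0.0
    for sp in phase.transported:
        dhat = mobility(sp, omega[sp], thermo, species_table, coeffs.d_of(phase.phase_id, sp))
        grad = np.asarray(potential_gradients[sp], dtype=float) - grad_ref
        j = -np.asarray(eps, dtype=float) * np.asarray(rho, dtype=float) * dhat * grad
        fluxes[sp] = j if np.ndim(j) else float(j)
        total = total + j
    ref_flux = -total
    fluxes[ref] = ref_flux if np.ndim(ref_flux) else float(ref_flux)
    return fluxes


def fluid_velocity(
    eps: float,
    rho: float,
    pressure_gradient: np.ndarray | float,
    resistance: np.ndarray | ArrayLike,
    gravity: np.ndarray | float = 0.0,
    v_solid: np.ndarray | float = 0.0,
    transfer_terms: list[tuple[float, np.ndarray | float]] | None = None,
    tol: float = 1e-12,
    max_iter: int = 50,
) -> np.ndarray:
    """Quasi-static fluid velocity from the closed momentum balance.

    Solves ``eps grad p - eps rho g + Rhat (v_f - v_s) + sum_i M_i (v_f + u_i) = 0``
    for ``v_f``.  ``transfer_terms`` is a list of ``(M_i, u_i)`` pairs; with
    none given the closed form ``v_f = v_s - Rhat^-1 (eps grad p - eps rho g)``
    is returned.  With transfer the equation is solved by Picard iteration
    lagging ``v_f`` (the transfer-momentum term is quadratic in small
    quantities, so the iteration contracts strongly).
    """
    grad_p = np.atleast_1d(np.asarray(pressure_gradient, dtype=float))
    dim = grad_p.shape[0]
    r = _as_matrix(resistance, dim=dim)
    g = np.broadcast_to(np.atleast_1d(np.asarray(gravity, dtype=float)), (dim,))
    vs = np.broadcast_to(np.atleast_1d(np.asarray(v_solid, dtype=float)), (dim,)).astype(float)
    drive = eps * grad_p - eps * rho * g
    terms = transfer_terms or []

    def solve(rhs: np.ndarray) -> np.ndarray:
        try:
            return np.linalg.solve(r, rhs)
        except np.linalg.LinAlgError:
            if np.linalg.norm(rhs) <= tol:
                return np.zeros(dim)
            raise ValidationError(
                "singular resistance tensor with nonzero driving force"
            ) from None

    v = vs - solve(drive)
    if not terms:
        return v
    for _ in range(max_iter):
        extra = np.zeros(dim)
        for m_i, u_i in terms:
            u = np.broadcast_to(np.atleast_1d(np.asarray(u_i, dtype=float)), (dim,))
            extra = extra + m_i * (v + u)
        v_new = vs - solve(drive + extra)
        if np.linalg.norm(v_new - v) <= tol * (1.0 + np.linalg.norm(v_new)):
            return v_new
        v = v_new
    raise ValidationError("fluid_velocity Picard iteration did not converge")


def porosity_rate(
    pressure: float,
    solid_normal_stress: float,
    tension_curvature: float,
    compressibility: float,
) -> float:
    """Porosity material derivative chat * [p + (n.t.n)_s + gamma*J_s] (1/s).

    Zero exactly at the normal-force mechanical equilibrium on the solid
    surface, or for a rigid solid (chat = 0).
    """
    if compressibility < 0.0:
        raise ValidationError("compressibility must be nonnegative")
    return compressibility * (pressure + solid_normal_stress + tension_curvature)


def capillary_relaxation_rate(
    p_w: float,
    p_n: float,
    gamma_wn: float,
    curvature_j: float,
    chat_wn: float,
) -> float:
    """Kinematic capillary relaxation rate chat_wn (p_w - p_n - gamma J) (1/s).

    Vanishes exactly at Young-Laplace equilibrium ``p_w - p_n = gamma J``.
    """
    if chat_wn < 0.0:
        raise ValidationError("capillary relaxation coefficient must be nonnegative")
    return chat_wn * (p_w - p_n - gamma_wn * curvature_j)


def invert_capillary_pressure(
    kinematic_rate: float,
    area_term: float,
    gamma_j: float,
    chat_wn: float,
) -> float:
    """Solve the capillary relaxation closure for the capillary pressure.

    The closure reads ``a - b / dp = chat (dp - gamma J)`` with ``a`` the
    kinematic volume-fraction rate combination, ``b`` the area-relaxation
    coupling term and ``dp = p_w - p_n``.  With ``b = 0`` the inversion is
    linear; otherwise the quadratic root on the physical branch (continuous
    with the ``b -> 0`` limit near Young-Laplace equilibrium) is returned.
    """
    if chat_wn <= 0.0:
        raise ValidationError("capillary inversion requires chat_wn > 0")
    a, b = float(kinematic_rate), float(area_term)
    if b == 0.0:
        return gamma_j + a / chat_wn
    # chat dp^2 - (chat gamma_j + a) dp + b = 0
    coeff_b = -(chat_wn * gamma_j + a)
    disc = coeff_b * coeff_b - 4.0 * chat_wn * b
    if disc < 0.0:
        raise ValidationError("capillary pressure inversion has no real root")
    sq = np.sqrt(disc)
    r1 = (-coeff_b + sq) / (2.0 * chat_wn)
    r2 = (-coeff_b - sq) / (2.0 * chat_wn)
    # pick the root continuous with the b=0 limit (gamma_j + a/chat)
    ref = gamma_j + a / chat_wn
    return r1 if abs(r1 - ref) <= abs(r2 - ref) else r2
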