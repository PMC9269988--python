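"""Three-phase geometric state, evolution closures, and the well-mixed model.

The three-phase system is a wetting interstitial fluid ``w``, a non-wetting
tumor-cell fluid ``n`` and a solid ECM-scaffold phase ``s``.  Beyond the
compositional state, the macroscale geometry carries specific interfacial
areas, mean and Gaussian curvatures, the solid-surface wetted fraction and
the Euler-characteristic density of the non-wetting phase; the Gauss-Bonnet
theorem links the last to curvature-weighted areas, and an integral-geometry
state function relates volume fractions to areas and curvatures.

The well-mixed (0-D) dynamical system evolves phase compositions and volume
fractions from affinity reactions and potential-driven mass transfer, the
fluid-fluid interfacial area from its evolution closure (common-curve terms
dropped), the Gaussian curvature from the 0-D curvature transport reduction
(conserving the product area x curvature), and obtains the capillary
pressure each step by inverting the capillary relaxation closure given the
mass-balance-determined wetting-volume rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .closure import invert_capillary_pressure
from .config import ThreePhaseConfig
from .entropy import EntropyLedger, audit_three_phase
from .kinetics import require_valid
from .species import ValidationError

__all__ = [
    "GeometryState",
    "sphere_pack_state",
    "gauss_bonnet_residual",
    "interfacial_area_rate",
    "curvature_rate_0d",
    "interface_normal_velocity",
    "galilean_residual",
    "StateFunction",
    "fit_state_function",
    "ThreePhaseResult",
    "simulate_threephase_0d",
]


@dataclass
class GeometryState:
    """Macroscale geometric state of a three-phase region.

    Volume fractions are dimensionless, specific areas 1/m, mean curvatures
    1/m, Gaussian curvatures 1/m^2, the Euler-characteristic density 1/m^3.
    A single solid curvature is stored (the solid curvature does not depend
    on which fluid wets it).
    """

    eps_w: float
    eps_n: float
    eps_s: float
    area_wn: float
    area_ws: float
    area_ns: float
    mean_curv_wn: float  # J_w^{wn}
    mean_curv_s: float = 0.0  # J_s^{ss} = J_s^{ws} = J_s^{ns}
    gauss_curv_wn: float = 0.0  # K_n^{wn}
    gauss_curv_ns: float = 0.0  # K_n^{ns}
    euler_density: float = 0.0  # chi-bar^n
    wetted_fraction: float = 1.0  # chi_s^{ws}
    contact_angle: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.eps_w + self.eps_n + self.eps_s - 1.0) > 1e-10:
            raise ValidationError("phase volume fractions must sum to 1")
        for name in ("area_wn", "area_ws", "area_ns"):
            if getattr(self, name) < 0.0:
                raise ValidationError(f"{name} must be nonnegative")
        if not (0.0 <= self.wetted_fraction <= 1.0):
            raise ValidationError("wetted fraction must lie in [0, 1]")

    @property
    def wetted_fraction_ns(self) -> float:
        return 1.0 - self.wetted_fraction


def sphere_pack_state(number_density: float, radius: float) -> GeometryState:
    """Geometry of a dilute pack of non-wetting spheres in a wetting fluid.

    ``eps_n = (4/3) pi r^3 N``, ``area_wn = 4 pi r^2 N``, mean curvature
    ``2/r``, Gaussian curvature ``1/r^2`` and Euler-characteristic density
    ``N`` (each sphere is one closed component).  No solid contact.
    """
    if number_density < 0.0 or radius <= 0.0:
        raise ValidationError("need number_density >= 0 and radius > 0")
    eps_n = (4.0 / 3.0) * np.pi * radius**3 * number_density
    if eps_n >= 0.3:
        raise ValidationError(
            f"packing fraction {eps_n:.3f} too high for the dilute sphere model"
        )
    return GeometryState(
        eps_w=1.0 - eps_n,
        eps_n=eps_n,
        eps_s=0.0,
        area_wn=4.0 * np.pi * radius**2 * number_density,
        area_ws=0.0,
        area_ns=0.0,
        mean_curv_wn=2.0 / radius if number_density > 0 else 0.0,
        gauss_curv_wn=1.0 / radius**2 if number_density > 0 else 0.0,
        gauss_curv_ns=0.0,
        euler_density=number_density,
        wetted_fraction=1.0,
    )


def gauss_bonnet_residual(state: GeometryState) -> float:
    """Residual of 4 pi chi = area_wn * K_wn + area_ns * K_ns (1/m^3)."""
    return 4.0 * np.pi * state.euler_density - (
        state.area_wn * state.gauss_curv_wn + state.area_ns * state.gauss_curv_ns
    )


def interfacial_area_rate(
    state: GeometryState,
    d_eps_w_dt: float,
    d_eps_s_dt: float,
    d_wetted_dt: float,
    area_relaxation: float,
    area_eq: float,
) -> float:
    """0-D fluid-fluid interfacial area evolution rate (1/(m s)).

    ``d area_wn/dt = J_w^{wn} (d eps_w/dt + chi_s^{ws} d eps_s/dt)
    + khat_wn (area_eq - area_wn)
    + cos(phi) (area_ws + area_ns) d chi_s^{ws}/dt``
    (spatial divergence/strain and common-curve terms vanish in the
    well-mixed reduction).
    """
    return (
        state.mean_curv_wn * (d_eps_w_dt + state.wetted_fraction * d_eps_s_dt)
        + area_relaxation * (area_eq - state.area_wn)
        + np.cos(state.contact_angle) * (state.area_ws + state.area_ns) * d_wetted_dt
    )


def curvature_rate_0d(state: GeometryState, area_rate: float) -> float:
    """Gaussian-curvature rate from the 0-D transport reduction (1/(m^2 s)).

    The reduction conserves the product ``area_wn * K_wn`` (matching the
    Gauss-Bonnet identity at fixed topology):
    ``dK/dt = -K * (d area/dt) / area``.
    """
    if state.area_wn <= 0.0:
        raise ValidationError(
            "curvature evolution undefined at vanishing interfacial area "
            "(topological change is not modeled)"
        )
    return -state.gauss_curv_wn * area_rate / state.area_wn


def interface_normal_velocity(
    d_eps_w_dt: float,
    grad_eps_w: float,
    area_wn: float,
    mean_normal: float = 0.0,
) -> float:
    """Macroscale normal velocity of the fluid-fluid interface (m/s).

    From the averaging-theorem identity
    ``area^2 w = -(d eps_w/dt)(grad eps_w + <n_w>)``; the average interface
    normal ``<n_w>`` vanishes for the isotropic case (the default).
    """
    if area_wn <= 0.0:
        if d_eps_w_dt == 0.0:
            return 0.0
        raise ValidationError("zero interfacial area with nonzero volume-fraction rate")
    return -d_eps_w_dt * (grad_eps_w + mean_normal) / area_wn**2


def _d1(f: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.gradient(f, x, edge_order=2)


def galilean_residual(
    x: np.ndarray,
    eps_n: np.ndarray,
    area_wn: np.ndarray,
    mean_curv: np.ndarray,
    gauss_curv: np.ndarray,
    orientation_diag: float = 1.0 / 3.0,
) -> np.ndarray:
    """Discrete 1-D residual of the Galilean-invariance curvature constraint.

    For an isotropic orientation tensor with diagonal ``g`` the constraint
    reduces to ``-(1 - 2g) d(area J)/dx + 2 K d eps_n/dx - (1 - g) d^3
    eps_n/dx^3 = 0``; spatially uniform states give identically zero.
    Evaluated with second-order central differences.
    """
    x = np.asarray(x, dtype=float)
    g = orientation_diag
    t1 = -(1.0 - 2.0 * g) * _d1(np.asarray(area_wn) * np.asarray(mean_curv), x)
    t2 = 2.0 * np.asarray(gauss_curv) * _d1(np.asarray(eps_n, dtype=float), x)
    t3 = -(1.0 - g) * _d1(_d1(_d1(np.asarray(eps_n, dtype=float), x), x), x)
    return t1 + t2 + t3


# ---------------------------------------------------------------------------
# Integral-geometry state function
# ---------------------------------------------------------------------------


@dataclass
class StateFunction:
    """Smooth predictor eps_n = F(area sum, curvature-weighted area, chi).

    ``kind='loglinear'`` fits a linear model in the logarithms of the three
    arguments — exact for power-law families such as sphere packs, where
    ``eps_n = (32 pi / 3) a1^3 a3 / a2^3``.  ``kind='rbf'`` uses a thin-plate
    radial-basis interpolant for general smooth data.
    """

    kind: str
    _coef: np.ndarray | None = None
    _rbf: object | None = field(default=None, repr=False)
    _const: float | None = None
    in_sample_residual: float = 0.0

    def predict(self, args: np.ndarray) -> np.ndarray:
        a = np.atleast_2d(np.asarray(args, dtype=float))
        if self._const is not None:
            return np.full(a.shape[0], self._const)
        if self.kind == "loglinear":
            z = np.column_stack([np.ones(a.shape[0]), np.log(a)])
            return np.exp(z @ self._coef)
        return np.asarray(self._rbf(a))


def fit_state_function(
    geometry_dataset: np.ndarray | Sequence[Sequence[float]],
    kind: str = "loglinear",
) -> StateFunction:
    """Fit the state function from rows [area_sum, curv_area, chi, eps_n].

    Requires at least 30 states.  A dataset whose arguments do not vary
    while the target does is rejected as degenerate; a fully constant
    dataset yields a constant predictor.  The fit is a least-squares /
    interpolation problem, hence invariant to row permutations.
    """
    data = np.asarray(geometry_dataset, dtype=float)
    if data.ndim != 2 or data.shape[1] != 4:
        raise ValidationError("dataset must have columns [area_sum, curv_area, chi, eps_n]")
    if data.shape[0] < 30:
        raise ValidationError("need at least 30 states to fit the state function")
    args, target = data[:, :3], data[:, 3]
    spread = np.ptp(args, axis=0)
    if np.all(spread < 1e-15 * (1.0 + np.abs(args[0]))):
        if np.ptp(target) > 1e-12 * (1.0 + abs(target[0])):
            raise ValidationError("degenerate argument span: arguments constant but target varies")
        return StateFunction(kind=kind, _const=float(target[0]))
    if kind == "loglinear":
        if np.any(args <= 0.0) or np.any(target <= 0.0):
            raise ValidationError("loglinear state function requires positive data")
        z = np.column_stack([np.ones(args.shape[0]), np.log(args)])
        coef, *_ = np.linalg.lstsq(z, np.log(target), rcond=None)
        resid = float(np.max(np.abs(np.exp(z @ coef) - target)))
        return StateFunction(kind=kind, _coef=coef, in_sample_residual=resid)
    if kind == "rbf":
        from scipy.interpolate import RBFInterpolator

        rbf = RBFInterpolator(args, target, kernel="thin_plate_spline")
        resid = float(np.max(np.abs(rbf(args) - target)))
        return StateFunction(kind=kind, _rbf=rbf, in_sample_residual=resid)
    raise ValidationError(f"unknown state-function kind {kind!r}")


# ---------------------------------------------------------------------------
# Well-mixed three-phase dynamical system
# ---------------------------------------------------------------------------


@dataclass
class ThreePhaseResult:
    """Trajectory of the well-mixed three-phase system."""

    times: np.ndarray
    eps: dict[str, np.ndarray]  # phase -> (nt,)
    omega: dict[str, dict[str, np.ndarray]]  # phase -> species -> (nt,)
    area_wn: np.ndarray
    gauss_curv_wn: np.ndarray
    capillary_pressure: np.ndarray  # p_w - p_n at each output time
    ledgers: list[EntropyLedger]
    metadata: dict = field(default_factory=dict)

    @property
    def ledger_min(self) -> float:
        return min(l.min_group for l in self.ledgers)

    def species_mass(self, species: str, phase: str, densities) -> np.ndarray:
        return self.eps[phase] * densities[phase] * self.omega[phase][species]


class ThreePhaseModel0D:
    """Semi-discrete well-mixed three-phase model."""

    def __init__(self, config: ThreePhaseConfig):
        self.cfg = config
        self.table = config.species_table
        self.phases = config.phases
        require_valid(config.reactions, self.table)
        for tr in config.transfers:
            for pid in (tr.donor, tr.receiver):
                if tr.species not in self.phases[pid].members:
                    raise ValidationError(
                        f"transfer species {tr.species!r} not shared by phase {pid!r}"
                    )
        for rxn in config.reactions:
            missing = [sp for sp in rxn.stoich if sp not in self.phases[rxn.phase].members]
            if missing:
                raise ValidationError(
                    f"reaction {rxn.id!r} in phase {rxn.phase!r} references "
                    f"non-member species {missing}"
                )
        self.mw = {sp: self.table.mw(sp) for sp in self.table.ids}
        self.layout: list[tuple[str, str | None]] = [("eps", "w"), ("eps", "n")]
        for pid in ("w", "n", "s"):
            self.layout += [(pid, sp) for sp in self.phases[pid].transported]
        self.layout += [("geom", "area_wn"), ("geom", "K_wn")]

    def pack(self, ini) -> np.ndarray:
        y = [ini.eps_w, ini.eps_n]
        for pid in ("w", "n", "s"):
            ph = self.phases[pid]
            for sp in ph.transported:
                y.append(ini.omega[pid][sp])
        y += [ini.eps_wn, ini.curvature_k]
        return np.asarray(y, dtype=float)

    def unpack(self, y: np.ndarray):
        eps = {"w": float(y[0]), "n": float(y[1])}
        eps["s"] = 1.0 - eps["w"] - eps["n"]
        omega: dict[str, dict[str, float]] = {}
        off = 2
        for pid in ("w", "n", "s"):
            ph = self.phases[pid]
            m = {}
            for sp in ph.transported:
                m[sp] = float(y[off])
                off += 1
            m[ph.reference_species] = 1.0 - sum(m.values())
            omega[pid] = m
        area_wn = float(y[off])
        k_wn = float(y[off + 1])
        return eps, omega, area_wn, k_wn

    def potentials(self, pid: str, omega: dict[str, float]) -> dict[str, float]:
        th = self.cfg.thermo
        moles = {sp: max(w, 0.0) / self.mw[sp] for sp, w in omega.items()}
        total = max(sum(moles.values()), 1e-300)
        out = {}
        for sp in self.phases[pid].members:
            x = max(moles[sp] / total, th.x_floor)
            out[sp] = th.mu0_of(sp, pid) + (
                th.gas_constant * th.temperature / self.mw[sp]
            ) * np.log(x)
        return out

    def rhs_full(self, t: float, y: np.ndarray, want_diag: bool = False):
        cfg = self.cfg
        geo = cfg.geometry
        eps, omega, area_wn, k_wn = self.unpack(y)
        for pid, e in eps.items():
            if not np.isfinite(e) or e < -1e-9 or e > 1.0 + 1e-9:
                raise ValidationError(
                    f"volume fraction of phase {pid!r} left [0, 1]: {e}"
                )
        mu = {pid: self.potentials(pid, omega[pid]) for pid in ("w", "n", "s")}
        psi = {pid: cfg.body_potentials.get(pid, 0.0) for pid in ("w", "n", "s")}

        m_into: dict[str, dict[str, float]] = {"w": {}, "n": {}, "s": {}}
        transfer_pairs: dict[str, list[tuple[float, float]]] = {
            "wn": [], "ws": [], "ns": []
        }
        for tr in cfg.transfers:
            delta = (mu[tr.donor][tr.species] + psi[tr.donor]
                     - mu[tr.receiver][tr.species] - psi[tr.receiver])
            m = tr.coeff * delta
            m_into[tr.receiver][tr.species] = m_into[tr.receiver].get(tr.species, 0.0) + m
            m_into[tr.donor][tr.species] = m_into[tr.donor].get(tr.species, 0.0) - m
            pair = "".join(sorted((tr.donor, tr.receiver)))
            pair = {"nw": "wn", "sw": "ws", "ns": "ns", "sn": "ns"}.get(pair, pair)
            transfer_pairs[pair].append((tr.coeff, delta))
        m_total = {pid: sum(d.values()) if d else 0.0 for pid, d in m_into.items()}

        production: dict[str, dict[str, float]] = {"w": {}, "n": {}, "s": {}}
        reaction_pairs = []
        for rxn in cfg.reactions:
            aff = sum(mu[rxn.phase][sp] * nu * self.mw[sp] for sp, nu in rxn.stoich.items())
            k_eff = float(rxn.effective_coeff(omega[rxn.phase]))
            rate = -k_eff * aff
            for sp, nu in rxn.stoich.items():
                production[rxn.phase][sp] = (
                    production[rxn.phase].get(sp, 0.0) + nu * self.mw[sp] * rate
                )
            reaction_pairs.append((eps[rxn.phase] * k_eff, aff))

        rho = cfg.densities
        d_eps = {pid: m_total[pid] / rho[pid] for pid in ("w", "n", "s")}

        # porosity rate (porosity = 1 - eps_s)
        d_porosity = -d_eps["s"]
        s_w = eps["w"] / max(eps["w"] + eps["n"], 1e-300)
        area_eq = geo.eps_eq(s_w)
        gamma_wn = cfg.closure.tension.get("wn", 0.0)
        j_wn = 2.0 * np.sqrt(max(k_wn, 0.0))  # sphere-consistent J from K
        gamma_j = gamma_wn * j_wn

        # capillary pressure from the relaxation closure given d eps_w / dt
        chat = cfg.closure.capillary_relaxation
        kinematic = d_eps["w"] - geo.chi_ws * d_porosity
        area_term = gamma_wn * cfg.closure.area_capillary_coupling * (area_wn - area_eq)
        if chat > 0.0:
            dp_c = invert_capillary_pressure(kinematic, area_term, gamma_j, chat)
        else:
            dp_c = gamma_j  # rigid capillary limit: Young-Laplace holds
        diseq = dp_c - gamma_j

        d_area = interfacial_area_rate(
            GeometryState(
                eps_w=eps["w"], eps_n=eps["n"], eps_s=eps["s"],
                area_wn=area_wn, area_ws=geo.eps_ws, area_ns=geo.eps_ns,
                mean_curv_wn=j_wn, gauss_curv_wn=k_wn,
                gauss_curv_ns=geo.k_ns, euler_density=0.0,
                wetted_fraction=geo.chi_ws, contact_angle=geo.contact_angle,
            ),
            d_eps["w"], d_eps["s"], 0.0,
            cfg.closure.area_relaxation, area_eq,
        )
        if area_wn <= 0.0:
            raise ValidationError("fluid-fluid interfacial area vanished")
        d_k = -k_wn * d_area / area_wn

        dy = np.empty_like(y)
        dy[0] = d_eps["w"]
        dy[1] = d_eps["n"]
        off = 2
        for pid in ("w", "n", "s"):
            ph = self.phases[pid]
            c_phase = max(eps[pid] * rho[pid], 1e-300)
            dc = rho[pid] * d_eps[pid]
            for sp in ph.transported:
                rhs_sp = eps[pid] * production[pid].get(sp, 0.0) + m_into[pid].get(sp, 0.0)
                dy[off] = (rhs_sp - omega[pid][sp] * dc) / c_phase
                off += 1
        dy[off] = d_area
        dy[off + 1] = d_k

        if not want_diag:
            return dy, None
        th = cfg.thermo
        ledger = audit_three_phase(
            th.temperature,
            reaction_terms=reaction_pairs,
            transfer_wn_terms=transfer_pairs["wn"],
            transfer_ws_terms=transfer_pairs["ws"],
            transfer_ns_terms=transfer_pairs["ns"],
            capillary_terms=[(chat, diseq)] if chat > 0.0 else [],
        )
        diag = {"ledger": ledger, "capillary_pressure": dp_c,
                "area_eq": area_eq, "mean_curv_wn": j_wn}
        return dy, diag

    def rhs(self, t, y):
        return self.rhs_full(t, y)[0]


def simulate_threephase_0d(config: ThreePhaseConfig) -> ThreePhaseResult:
    """Integrate the well-mixed three-phase system and audit every output state."""
    model = ThreePhaseModel0D(config)
    ini = config.initial
    y0 = model.pack(ini)
    sp_cfg = config.solver
    t_eval = np.linspace(0.0, sp_cfg.t_end, sp_cfg.n_out)
    sol = solve_ivp(
        model.rhs, (0.0, sp_cfg.t_end), y0,
        method=sp_cfg.method, rtol=sp_cfg.rtol, atol=sp_cfg.atol,
        max_step=sp_cfg.max_step, t_eval=t_eval,
    )
    if not sol.success:
        raise ValidationError(f"three-phase integration failed: {sol.message}")

    nt = sol.t.size
    eps_t = {pid: np.empty(nt) for pid in ("w", "n", "s")}
    omega_t = {pid: {sp: np.empty(nt) for sp in config.phases[pid].members}
               for pid in ("w", "n", "s")}
    area_t = np.empty(nt)
    k_t = np.empty(nt)
    pc_t = np.empty(nt)
    ledgers = []
    for k in range(nt):
        eps, omega, area_wn, k_wn = model.unpack(sol.y[:, k])
        _, diag = model.rhs_full(sol.t[k], sol.y[:, k], want_diag=True)
        for pid in ("w", "n", "s"):
            eps_t[pid][k] = eps[pid]
            for sp in config.phases[pid].members:
                omega_t[pid][sp][k] = omega[pid][sp]
        area_t[k] = area_wn
        k_t[k] = k_wn
        pc_t[k] = diag["capillary_pressure"]
        ledgers.append(diag["ledger"])
    return ThreePhaseResult(
        times=sol.t,
        eps=eps_t,
        omega=omega_t,
        area_wn=area_t,
        gauss_curv_wn=k_t,
        capillary_pressure=pc_t,
        ledgers=ledgers,
        metadata={"seed": config.seed, "nfev": int(sol.nfev), "method": sp_cfg.method},
    )
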