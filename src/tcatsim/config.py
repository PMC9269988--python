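"""Scenario configuration objects for the two- and three-phase simulators.

A scenario bundles everything a run needs: the species table, phase
definitions, thermodynamic parameters, reaction network, transfer specs,
closure coefficients, initial and boundary data, and solver tolerances.
Configs are plain dataclasses with ``to_dict``/``from_dict`` round-trip
serialization used by the YAML/JSON loaders in :mod:`tcatsim.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

from .closure import ClosureCoefficients
from .grid import Grid1D
from .kinetics import Modulation, ReactionSpec, TransferSpec
from .species import PhaseDef, SpeciesTable, ThermoParams, ValidationError

__all__ = [
    "SolverParams",
    "TwoPhaseInitial",
    "TwoPhaseBoundary",
    "TwoPhaseConfig",
    "GeometryParams",
    "ThreePhaseInitial",
    "ThreePhaseConfig",
    "ConfigError",
]


class ConfigError(ValidationError):
    """Schema violation; ``problems`` lists every offending key path."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.problems))


@dataclass(frozen=True)
class SolverParams:
    """Method-of-lines integrator contract (adaptive implicit stepping)."""

    t_end: float
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = math.inf
    method: str = "BDF"
    n_out: int = 51

    def to_dict(self) -> dict:
        d = {
            "t_end": self.t_end,
            "rtol": self.rtol,
            "atol": self.atol,
            "method": self.method,
            "n_out": self.n_out,
        }
        if math.isfinite(self.max_step):
            d["max_step"] = self.max_step
        return d


def _field_to_obj(v: float | np.ndarray):
    a = np.asarray(v)
    return a.tolist() if a.ndim else float(a)


@dataclass
class TwoPhaseInitial:
    """Initial fields; scalars broadcast over the grid, arrays are per cell."""

    eps_s: float | np.ndarray
    omega_f: dict[str, float | np.ndarray]
    omega_s: dict[str, float | np.ndarray]

    def to_dict(self) -> dict:
        return {
            "eps_s": _field_to_obj(self.eps_s),
            "omega_f": {k: _field_to_obj(v) for k, v in self.omega_f.items()},
            "omega_s": {k: _field_to_obj(v) for k, v in self.omega_s.items()},
        }


@dataclass(frozen=True)
class TwoPhaseBoundary:
    """Outer-boundary data; species absent from ``omega_f_outer`` are no-flux.

    ``pressure_outer``/``pressure_inner`` of ``None`` mean no-flux; an
    all-Neumann pressure problem requires ``gauge_cell``.  The inner boundary
    of a spherical grid starting at r=0 is a symmetry (no-flux) boundary.
    """

    omega_f_outer: Mapping[str, float] = field(default_factory=dict)
    pressure_outer: float | None = 0.0
    pressure_inner: float | None = None
    gauge_cell: int | None = None
    gauge_pressure: float = 0.0

    def to_dict(self) -> dict:
        return {
            "omega_f_outer": dict(self.omega_f_outer),
            "pressure_outer": self.pressure_outer,
            "pressure_inner": self.pressure_inner,
            "gauge_cell": self.gauge_cell,
            "gauge_pressure": self.gauge_pressure,
        }


@dataclass
class TwoPhaseConfig:
    """Complete two-phase (interstitial fluid + tumor/ECM solid) scenario."""

    grid: Grid1D
    species_table: SpeciesTable
    phases: dict[str, PhaseDef]  # keys 'f' and 's'
    thermo: ThermoParams
    densities: dict[str, float]  # intrinsic phase densities, kg/m^3
    reactions: list[ReactionSpec]
    transfers: list[TransferSpec]
    closure: ClosureCoefficients
    initial: TwoPhaseInitial
    boundary: TwoPhaseBoundary
    solver: SolverParams
    body_potentials: dict[str, float] = field(default_factory=dict)
    gravity: float = 0.0
    v_solid: float = 0.0
    solid_normal_stress: float | str = "hydrostatic"
    include_transfer_momentum: bool = True
    seed: int = 0

    kind = "two_phase"

    def with_updates(self, **kw) -> "TwoPhaseConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "grid": {
                "geometry": self.grid.geometry,
                "edges": self.grid.edges.tolist(),
            },
            "species": {"molar_mass": dict(self.species_table.molar_mass)},
            "phases": {
                pid: {
                    "members": list(p.members),
                    "reference": p.reference_species,
                    "density": self.densities[pid],
                    "body_potential": self.body_potentials.get(pid, 0.0),
                }
                for pid, p in self.phases.items()
            },
            "thermo": {
                "temperature": self.thermo.temperature,
                "gas_constant": self.thermo.gas_constant,
                "x_floor": self.thermo.x_floor,
            },
            "mu0": {
                f"{sp}@{ph}": v for (sp, ph), v in self.thermo.mu0.items()
            },
            "reactions": [_reaction_to_dict(r) for r in self.reactions],
            "transfers": [
                {"species": t.species, "donor": t.donor, "receiver": t.receiver,
                 "coeff": t.coeff}
                for t in self.transfers
            ],
            "closure": _closure_to_dict(self.closure),
            "gravity": self.gravity,
            "v_solid": self.v_solid,
            "solid_normal_stress": self.solid_normal_stress,
            "include_transfer_momentum": self.include_transfer_momentum,
            "initial": self.initial.to_dict(),
            "boundary": self.boundary.to_dict(),
            "solver": self.solver.to_dict(),
        }


@dataclass(frozen=True)
class GeometryParams:
    """Geometric state parameters of the well-mixed three-phase model.

    ``eps_ws``/``eps_ns`` and the ns-interface Gaussian curvature ``k_ns``
    are config-supplied constants.  ``eps_eq_kind`` selects the equilibrium
    fluid-fluid area as a function of wetting saturation: ``'quadratic'``
    uses ``a * s_w * (1 - s_w)``, ``'constant'`` a fixed value.
    """

    chi_ws: float = 1.0  # wetted fraction of the solid surface
    eps_ws: float = 0.0  # specific w-s interfacial area, 1/m
    eps_ns: float = 0.0  # specific n-s interfacial area, 1/m
    k_ns: float = 0.0  # Gaussian curvature of the n-s interface, 1/m^2
    contact_angle: float = 0.0  # rad, constant
    eps_eq_kind: str = "quadratic"
    eps_eq_param: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.chi_ws <= 1.0):
            raise ValidationError("chi_ws must lie in [0, 1]")
        if self.eps_eq_kind not in ("quadratic", "constant"):
            raise ValidationError(f"unknown eps_eq_kind {self.eps_eq_kind!r}")

    def eps_eq(self, s_w: float) -> float:
        if self.eps_eq_kind == "constant":
            return self.eps_eq_param
        return self.eps_eq_param * s_w * (1.0 - s_w)

    def to_dict(self) -> dict:
        return {
            "chi_ws": self.chi_ws,
            "eps_ws": self.eps_ws,
            "eps_ns": self.eps_ns,
            "k_ns": self.k_ns,
            "contact_angle": self.contact_angle,
            "eps_eq_kind": self.eps_eq_kind,
            "eps_eq_param": self.eps_eq_param,
        }


@dataclass
class ThreePhaseInitial:
    eps_w: float
    eps_n: float
    omega: dict[str, dict[str, float]]  # phase -> species -> mass fraction
    eps_wn: float  # specific w-n interfacial area, 1/m
    curvature_k: float  # Gaussian curvature K_n^{wn}, 1/m^2
    pressure_n: float = 0.0  # reference non-wetting pressure, Pa

    def to_dict(self) -> dict:
        return {
            "eps_w": self.eps_w,
            "eps_n": self.eps_n,
            "omega": {ph: dict(m) for ph, m in self.omega.items()},
            "eps_wn": self.eps_wn,
            "curvature_k": self.curvature_k,
            "pressure_n": self.pressure_n,
        }


@dataclass
class ThreePhaseConfig:
    """Well-mixed (0-D) three-phase scenario: wetting fluid, tumor fluid, solid."""

    species_table: SpeciesTable
    phases: dict[str, PhaseDef]  # keys 'w', 'n', 's'
    thermo: ThermoParams
    densities: dict[str, float]
    reactions: list[ReactionSpec]
    transfers: list[TransferSpec]
    closure: ClosureCoefficients
    geometry: GeometryParams
    initial: ThreePhaseInitial
    solver: SolverParams
    body_potentials: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    kind = "three_phase_0d"

    def with_updates(self, **kw) -> "ThreePhaseConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "species": {"molar_mass": dict(self.species_table.molar_mass)},
            "phases": {
                pid: {
                    "members": list(p.members),
                    "reference": p.reference_species,
                    "density": self.densities[pid],
                    "body_potential": self.body_potentials.get(pid, 0.0),
                }
                for pid, p in self.phases.items()
            },
            "thermo": {
                "temperature": self.thermo.temperature,
                "gas_constant": self.thermo.gas_constant,
                "x_floor": self.thermo.x_floor,
            },
            "mu0": {f"{sp}@{ph}": v for (sp, ph), v in self.thermo.mu0.items()},
            "reactions": [_reaction_to_dict(r) for r in self.reactions],
            "transfers": [
                {"species": t.species, "donor": t.donor, "receiver": t.receiver,
                 "coeff": t.coeff}
                for t in self.transfers
            ],
            "closure": _closure_to_dict(self.closure),
            "geometry": self.geometry.to_dict(),
            "initial": self.initial.to_dict(),
            "solver": self.solver.to_dict(),
        }


def _reaction_to_dict(r: ReactionSpec) -> dict:
    d = {
        "id": r.id,
        "phase": r.phase,
        "stoich": dict(r.stoich),
        "rate_coeff": r.rate_coeff,
    }
    if r.modulations:
        d["modulations"] = [m.to_dict() for m in r.modulations]
    return d


def _closure_to_dict(c: ClosureCoefficients) -> dict:
    return {
        "diffusivity": {ph: dict(m) for ph, m in c.diffusivity.items()},
        "resistance": {ph: _field_to_obj(v) for ph, v in c.resistance.items()},
        "compressibility": c.compressibility,
        "tension": dict(c.tension),
        "area_relaxation": c.area_relaxation,
        "capillary_relaxation": c.capillary_relaxation,
        "area_capillary_coupling": c.area_capillary_coupling,
        "contact_angle": c.contact_angle,
    }


# ---------------------------------------------------------------------------
# Deserialization with aggregated error reporting
# ---------------------------------------------------------------------------


class _Collector:
    def __init__(self) -> None:
        self.problems: list[str] = []

    def err(self, path: str, msg: str) -> None:
        self.problems.append(f"{path}: {msg}")

    def finish(self) -> None:
        if self.problems:
            raise ConfigError(self.problems)


def _parse_modulation(d: Mapping[str, Any], path: str, col: _Collector) -> Modulation | None:
    kind = d.get("kind")
    sp = d.get("species")
    params = {k: float(v) for k, v in d.items() if k not in ("kind", "species")}
    try:
        return Modulation(str(kind), str(sp), tuple(sorted(params.items())))
    except Exception as e:  # noqa: BLE001
        col.err(path, str(e))
        return None


def _parse_common(data: Mapping[str, Any], col: _Collector):
    table = None
    try:
        table = SpeciesTable(
            {str(k): float(v) for k, v in data["species"]["molar_mass"].items()}
        )
    except KeyError:
        col.err("species.molar_mass", "missing")
    except ValidationError as e:
        col.err("species.molar_mass", str(e))

    phases: dict[str, PhaseDef] = {}
    densities: dict[str, float] = {}
    body_potentials: dict[str, float] = {}
    for pid, pd in dict(data.get("phases", {})).items():
        try:
            phases[pid] = PhaseDef(pid, tuple(pd["members"]), pd["reference"])
        except (KeyError, ValidationError) as e:
            col.err(f"phases.{pid}", str(e))
            continue
        rho = float(pd.get("density", 0.0))
        if rho <= 0.0:
            col.err(f"phases.{pid}.density", f"must be positive, got {rho}")
        densities[pid] = rho
        body_potentials[pid] = float(pd.get("body_potential", 0.0))
    if not phases:
        col.err("phases", "missing or empty")

    mu0: dict[tuple[str, str], float] = {}
    for key, v in dict(data.get("mu0", {})).items():
        if "@" not in str(key):
            col.err(f"mu0.{key}", "key must look like '<species>@<phase>'")
            continue
        sp, ph = str(key).split("@", 1)
        mu0[(sp, ph)] = float(v)

    thermo = None
    try:
        td = dict(data.get("thermo", {}))
        thermo = ThermoParams(
            temperature=float(td.get("temperature", 310.0)),
            gas_constant=float(td.get("gas_constant", 8.314)),
            mu0=mu0,
            x_floor=float(td.get("x_floor", 1e-12)),
        )
    except ValidationError as e:
        col.err("thermo", str(e))

    reactions: list[ReactionSpec] = []
    for i, rd in enumerate(list(data.get("reactions", []))):
        mods = tuple(
            m
            for m in (
                _parse_modulation(md, f"reactions[{i}].modulations", col)
                for md in rd.get("modulations", [])
            )
            if m is not None
        )
        try:
            reactions.append(
                ReactionSpec(
                    id=str(rd["id"]),
                    phase=str(rd["phase"]),
                    stoich={str(k): float(v) for k, v in rd["stoich"].items()},
                    rate_coeff=float(rd["rate_coeff"]),
                    modulations=mods,
                )
            )
        except (KeyError, ValidationError) as e:
            col.err(f"reactions[{i}]", str(e))

    transfers: list[TransferSpec] = []
    for i, td2 in enumerate(list(data.get("transfers", []))):
        try:
            transfers.append(
                TransferSpec(
                    species=str(td2["species"]),
                    donor=str(td2["donor"]),
                    receiver=str(td2["receiver"]),
                    coeff=float(td2["coeff"]),
                )
            )
        except (KeyError, ValidationError) as e:
            col.err(f"transfers[{i}]", str(e))

    closure = None
    try:
        cd = dict(data.get("closure", {}))
        closure = ClosureCoefficients(
            diffusivity={
                ph: {sp: float(v) for sp, v in m.items()}
                for ph, m in cd.get("diffusivity", {}).items()
            },
            resistance={
                ph: np.asarray(v, dtype=float) if isinstance(v, list) else float(v)
                for ph, v in cd.get("resistance", {}).items()
            },
            compressibility=float(cd.get("compressibility", 0.0)),
            tension={k: float(v) for k, v in cd.get("tension", {}).items()},
            area_relaxation=float(cd.get("area_relaxation", 0.0)),
            capillary_relaxation=float(cd.get("capillary_relaxation", 0.0)),
            area_capillary_coupling=float(cd.get("area_capillary_coupling", 0.0)),
            contact_angle=float(cd.get("contact_angle", 0.0)),
        )
    except ValidationError as e:
        col.err("closure", str(e))

    solver = None
    try:
        sd = dict(data.get("solver", {}))
        solver = SolverParams(
            t_end=float(sd["t_end"]),
            rtol=float(sd.get("rtol", 1e-8)),
            atol=float(sd.get("atol", 1e-10)),
            max_step=float(sd.get("max_step", math.inf)),
            method=str(sd.get("method", "BDF")),
            n_out=int(sd.get("n_out", 51)),
        )
    except KeyError:
        col.err("solver.t_end", "missing")

    return table, phases, densities, body_potentials, thermo, reactions, transfers, closure, solver


def two_phase_from_dict(data: Mapping[str, Any]) -> TwoPhaseConfig:
    col = _Collector()
    (table, phases, densities, body_potentials, thermo, reactions,
     transfers, closure, solver) = _parse_common(data, col)

    grid = None
    try:
        gd = dict(data["grid"])
        if "edges" in gd:
            grid = Grid1D(str(gd["geometry"]), np.asarray(gd["edges"], dtype=float))
        else:
            grid = Grid1D.uniform(
                str(gd["geometry"]), float(gd.get("r_min", 0.0)),
                float(gd["r_max"]), int(gd["n_cells"])
            )
    except (KeyError, ValidationError) as e:
        col.err("grid", str(e))

    initial = None
    try:
        idd = dict(data["initial"])
        initial = TwoPhaseInitial(
            eps_s=np.asarray(idd["eps_s"], dtype=float)
            if isinstance(idd["eps_s"], list) else float(idd["eps_s"]),
            omega_f={
                k: np.asarray(v, dtype=float) if isinstance(v, list) else float(v)
                for k, v in idd["omega_f"].items()
            },
            omega_s={
                k: np.asarray(v, dtype=float) if isinstance(v, list) else float(v)
                for k, v in idd["omega_s"].items()
            },
        )
    except KeyError as e:
        col.err("initial", f"missing key {e}")

    bd = dict(data.get("boundary", {}))
    boundary = TwoPhaseBoundary(
        omega_f_outer={k: float(v) for k, v in bd.get("omega_f_outer", {}).items()},
        pressure_outer=None if bd.get("pressure_outer", 0.0) is None
        else float(bd.get("pressure_outer", 0.0)),
        pressure_inner=None if bd.get("pressure_inner") is None
        else float(bd["pressure_inner"]),
        gauge_cell=None if bd.get("gauge_cell") is None else int(bd["gauge_cell"]),
        gauge_pressure=float(bd.get("gauge_pressure", 0.0)),
    )
    col.finish()
    return TwoPhaseConfig(
        grid=grid,
        species_table=table,
        phases=phases,
        thermo=thermo,
        densities=densities,
        body_potentials=body_potentials,
        reactions=reactions,
        transfers=transfers,
        closure=closure,
        initial=initial,
        boundary=boundary,
        solver=solver,
        gravity=float(data.get("gravity", 0.0)),
        v_solid=float(data.get("v_solid", 0.0)),
        solid_normal_stress=data.get("solid_normal_stress", "hydrostatic"),
        include_transfer_momentum=bool(data.get("include_transfer_momentum", False)),
        seed=int(data.get("seed", 0)),
    )


def three_phase_from_dict(data: Mapping[str, Any]) -> ThreePhaseConfig:
    col = _Collector()
    (table, phases, densities, body_potentials, thermo, reactions,
     transfers, closure, solver) = _parse_common(data, col)

    geometry = None
    try:
        gd = dict(data.get("geometry", {}))
        geometry = GeometryParams(
            chi_ws=float(gd.get("chi_ws", 1.0)),
            eps_ws=float(gd.get("eps_ws", 0.0)),
            eps_ns=float(gd.get("eps_ns", 0.0)),
            k_ns=float(gd.get("k_ns", 0.0)),
            contact_angle=float(gd.get("contact_angle", 0.0)),
            eps_eq_kind=str(gd.get("eps_eq_kind", "quadratic")),
            eps_eq_param=float(gd.get("eps_eq_param", 0.0)),
        )
    except ValidationError as e:
        col.err("geometry", str(e))

    initial = None
    try:
        idd = dict(data["initial"])
        initial = ThreePhaseInitial(
            eps_w=float(idd["eps_w"]),
            eps_n=float(idd["eps_n"]),
            omega={ph: {k: float(v) for k, v in m.items()}
                   for ph, m in idd["omega"].items()},
            eps_wn=float(idd["eps_wn"]),
            curvature_k=float(idd["curvature_k"]),
            pressure_n=float(idd.get("pressure_n", 0.0)),
        )
    except KeyError as e:
        col.err("initial", f"missing key {e}")

    col.finish()
    return ThreePhaseConfig(
        species_table=table,
        phases=phases,
        thermo=thermo,
        densities=densities,
        body_potentials=body_potentials,
        reactions=reactions,
        transfers=transfers,
        closure=closure,
        geometry=geometry,
        initial=initial,
        solver=solver,
        seed=int(data.get("seed", 0)),
    )


def config_from_dict(data: Mapping[str, Any]) -> TwoPhaseConfig | ThreePhaseConfig:
    kind = data.get("kind")
    if kind == "two_phase":
        return two_phase_from_dict(data)
    if kind == "three_phase_0d":
        return three_phase_from_dict(data)
    raise ConfigError([f"kind: must be 'two_phase' or 'three_phase_0d', got {kind!r}"])
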