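"""Least-squares recovery of rate coefficients from observed trajectories.

Given a scenario whose structure is known but whose transfer coefficient
(or one reaction coefficient) is not, the estimator reruns the simulator
for candidate coefficient values and minimizes the misfit to the observed
species trajectory.  Coefficients are optimized on a log scale to enforce
positivity and to cope with their wide magnitude range.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.optimize import least_squares

from .config import TwoPhaseConfig
from .kinetics import TransferSpec
from .model2p import simulate
from .species import ValidationError

__all__ = ["fit_transfer_coefficient", "fit_reaction_coefficient"]


def _observed_trajectory(cfg: TwoPhaseConfig, species: str, phase: str) -> np.ndarray:
    res = simulate(cfg)
    field = res.omega_f if phase == "f" else res.omega_s
    return field[species].mean(axis=1)


def _fit_scalar(build_cfg, observed, x0: float) -> float:
    obs = np.asarray(observed, dtype=float)
    scale = max(float(np.max(np.abs(obs))), 1e-300)

    def residual(log_k):
        try:
            model = build_cfg(float(np.exp(log_k[0])))
        except ValidationError:
            return np.full_like(obs, 1e6)
        return (model - obs) / scale

    sol = least_squares(
        residual, x0=[np.log(x0)], method="lm", xtol=1e-12, ftol=1e-12
    )
    return float(np.exp(sol.x[0]))


def fit_transfer_coefficient(
    config: TwoPhaseConfig,
    observed: np.ndarray,
    species: str,
    phase: str = "f",
    initial_guess: float | None = None,
) -> float:
    """Estimate the transfer coefficient of ``species`` from a trajectory.

    ``observed`` is the cell-averaged mass fraction of the species in
    ``phase`` at the config's output times.  Returns the fitted Khat_M.
    """
    idx = [i for i, t in enumerate(config.transfers) if t.species == species]
    if not idx:
        raise ValidationError(f"config has no transfer for species {species!r}")
    i = idx[0]
    x0 = initial_guess if initial_guess is not None else max(
        config.transfers[i].coeff, 1e-12
    )

    def build(k):
        transfers = list(config.transfers)
        t = transfers[i]
        transfers[i] = TransferSpec(t.species, t.donor, t.receiver, k)
        return _observed_trajectory(
            config.with_updates(transfers=transfers), species, phase
        )

    return _fit_scalar(build, observed, x0)


def fit_reaction_coefficient(
    config: TwoPhaseConfig,
    observed: np.ndarray,
    reaction_id: str,
    species: str,
    phase: str = "s",
    initial_guess: float | None = None,
) -> float:
    """Estimate one reaction rate coefficient from a species trajectory."""
    idx = [i for i, r in enumerate(config.reactions) if r.id == reaction_id]
    if not idx:
        raise ValidationError(f"config has no reaction {reaction_id!r}")
    i = idx[0]
    x0 = initial_guess if initial_guess is not None else max(
        config.reactions[i].rate_coeff, 1e-15
    )

    def build(k):
        reactions = list(config.reactions)
        reactions[i] = replace(reactions[i], rate_coeff=k)
        return _observed_trajectory(
            config.with_updates(reactions=reactions), species, phase
        )

    return _fit_scalar(build, observed, x0)
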