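"""Configuration loading/validation and deterministic result serialization.

The configuration dialect is YAML (JSON, being a YAML subset, is accepted
from the same loader); the schema is documented in
``docs/schema/scenario.schema.json``.  Result tables are written as CSV
with a deterministic column order and full floating-point precision, and
every run emits a manifest (config hash, seeds, package version, timestamps
and the output-file inventory) so reruns can be verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (
    ConfigError,
    ThreePhaseConfig,
    TwoPhaseConfig,
    config_from_dict,
)
from .geometry3p import ThreePhaseResult
from .model2p import SimResult

__all__ = ["load_config", "dump_config", "config_hash", "RunManifest",
           "write_result", "write_threephase_result"]


def load_config(path: str | Path) -> TwoPhaseConfig | ThreePhaseConfig:
    """Load and schema-validate a scenario file (YAML or JSON dialect)."""
    p = Path(path)
    if not p.exists():
        raise ConfigError([f"{p}: file does not exist"])
    with open(p, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError([f"{p}: top level must be a mapping"])
    return config_from_dict(data)


def dump_config(config: TwoPhaseConfig | ThreePhaseConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: TwoPhaseConfig | ThreePhaseConfig) -> str:
    """SHA-256 of the canonical JSON serialization of the config."""
    canon = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one run; every output file is listed."""

    config_hash: str
    seed: int
    code_version: str
    started: str
    finished: str
    outputs: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "code_version": self.code_version,
            "started": self.started,
            "finished": self.finished,
            "outputs": sorted(self.outputs),
        }

    def write(self, path: Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _df_to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def _timestamp() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())


def write_result(
    result: SimResult,
    config: TwoPhaseConfig,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("csv", "json"),
) -> RunManifest:
    """Serialize a two-phase run: time-series tables, diagnostics, manifest.

    ``timeseries.csv`` holds domain totals per species and phase plus the
    entropy ledger; ``fields_<t>.csv`` hold full snapshots when the ``csv``
    format is selected.  Column order is deterministic; floats are written
    at full precision, so identical runs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = _timestamp()
    outputs: list[str] = []

    cols: dict[str, np.ndarray] = {"time_s": result.times}
    for (sp, pid), mass in sorted(result.storage.items()):
        cols[f"mass_{sp}_{pid}_kg"] = mass
    for name in sorted(result.ledgers[0].groups):
        cols[f"entropy_{name}"] = np.array([l.groups[name] for l in result.ledgers])
    cols["entropy_total"] = np.array([l.total for l in result.ledgers])
    ts = pd.DataFrame(cols)
    if "csv" in formats:
        _df_to_csv(ts, out / "timeseries.csv")
        outputs.append("timeseries.csv")
        centers = config.grid.centers
        for k, t in enumerate(result.times):
            snap = {"r_m": centers, "eps_s": result.eps_s[k],
                    "pressure_Pa": result.pressure[k]}
            for sp in sorted(result.omega_f):
                snap[f"omega_f_{sp}"] = result.omega_f[sp][k]
            for sp in sorted(result.omega_s):
                snap[f"omega_s_{sp}"] = result.omega_s[sp][k]
            name = f"fields_{k:04d}.csv"
            _df_to_csv(pd.DataFrame(snap), out / name)
            outputs.append(name)
    if "json" in formats:
        diag = {
            "ledger_min": result.ledger_min,
            "ledger_final": result.ledgers[-1].to_dict(),
            "metadata": result.metadata,
        }
        with open(out / "diagnostics.json", "w", encoding="utf-8") as fh:
            json.dump(diag, fh, indent=2, sort_keys=True)
        outputs.append("diagnostics.json")

    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=config.seed,
        code_version=__version__,
        started=started,
        finished=_timestamp(),
        outputs=outputs + ["manifest.json"],
    )
    manifest.write(out / "manifest.json")
    return manifest


def write_threephase_result(
    result: ThreePhaseResult,
    config: ThreePhaseConfig,
    out_dir: str | Path,
) -> RunManifest:
    """Serialize a well-mixed three-phase run (single time-series table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = _timestamp()
    cols: dict[str, np.ndarray] = {"time_s": result.times}
    for pid in ("w", "n", "s"):
        cols[f"eps_{pid}"] = result.eps[pid]
    for pid in ("w", "n", "s"):
        for sp in sorted(result.omega[pid]):
            cols[f"omega_{pid}_{sp}"] = result.omega[pid][sp]
    cols["area_wn_per_m"] = result.area_wn
    cols["gauss_curv_wn_per_m2"] = result.gauss_curv_wn
    cols["capillary_pressure_Pa"] = result.capillary_pressure
    for name in sorted(result.ledgers[0].groups):
        cols[f"entropy_{name}"] = np.array([l.groups[name] for l in result.ledgers])
    cols["entropy_total"] = np.array([l.total for l in result.ledgers])
    _df_to_csv(pd.DataFrame(cols), out / "timeseries.csv")
    with open(out / "diagnostics.json", "w", encoding="utf-8") as fh:
        json.dump({"ledger_min": result.ledger_min, "metadata": result.metadata},
                  fh, indent=2, sort_keys=True)
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=config.seed,
        code_version=__version__,
        started=started,
        finished=_timestamp(),
        outputs=["timeseries.csv", "diagnostics.json", "manifest.json"],
    )
    manifest.write(out / "manifest.json")
    return manifest
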