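"""Configuration, table and manifest plumbing shared by all modules.

Configs are YAML or JSON with blocks ``parameters``, ``initial_state``,
``simulation`` and ``transfers``; unknown keys are rejected by name and
defaults are filled in and echoed back, so every run is self-describing.
Tables are comma-separated, LF-terminated text with schema enforcement
and full-precision floats (shortest round-trip repr), so written
artifacts re-read without loss.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelParameters, PopulationState

__all__ = [
    "ConfigError", "SchemaError", "SimulationSettings", "ResolvedConfig",
    "load_config", "save_config", "read_table", "write_table",
    "RunManifest", "TRAJECTORY_SCHEMA", "SWEEP_SCHEMA",
    "COMPETITION_SCHEMA", "ECOI_SCHEMA", "OBSERVATION_SCHEMA",
]


class ConfigError(ValueError):
    """Configuration file problem (parse, unknown key, invariant)."""


class SchemaError(ValueError):
    """Tabular data does not match the expected schema."""


@dataclass(frozen=True)
class SimulationSettings:
    t_end: float = 30.0
    n_samples: int = 301
    rtol: float = 1e-8
    atol: float = 1e-10
    extinction_threshold: float = 1e-3

    def __post_init__(self):
        if self.t_end <= 0:
            raise ConfigError(f"t_end must be > 0, got {self.t_end}")
        if self.n_samples < 2:
            raise ConfigError("n_samples must be >= 2")


@dataclass(frozen=True)
class ResolvedConfig:
    """A fully validated and defaulted run configuration."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    initial_state: PopulationState = field(
        default_factory=lambda: PopulationState(W=1e3, V1=100.0, V2=100.0))
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    transfers: tuple = ()

    def as_dict(self) -> dict:
        return {
            "parameters": self.parameters.as_dict(),
            "initial_state": {k: getattr(self.initial_state, k)
                              for k in ("W", "R", "S", "V1", "V2")},
            "simulation": dataclasses.asdict(self.simulation),
            "transfers": [list(t) for t in self.transfers],
        }


_BLOCKS = ("parameters", "initial_state", "simulation", "transfers")
_PARAM_KEYS = set(ModelParameters().as_dict())
_STATE_KEYS = {"W", "R", "S", "V1", "V2"}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationSettings)}


def _reject_unknown(block: str, given: dict, allowed: set):
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {block!r}: {sorted(unknown)} "
            f"(allowed: {sorted(allowed)})")


def resolve_config(raw: dict) -> ResolvedConfig:
    """Validate a raw config mapping and fill defaults."""
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    _reject_unknown("config", raw, set(_BLOCKS))

    params_raw = raw.get("parameters") or {}
    _reject_unknown("parameters", params_raw, _PARAM_KEYS)
    try:
        params = ModelParameters(**params_raw)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    state_raw = raw.get("initial_state")
    if state_raw is None:
        initial = ResolvedConfig().initial_state
    else:
        _reject_unknown("initial_state", state_raw, _STATE_KEYS)
        try:
            initial = PopulationState(t=0.0, **state_raw)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    sim_raw = raw.get("simulation") or {}
    _reject_unknown("simulation", sim_raw, _SIM_KEYS)
    sim = SimulationSettings(**sim_raw)

    transfers_raw = raw.get("transfers") or []
    transfers = []
    for entry in transfers_raw:
        if isinstance(entry, dict):
            _reject_unknown("transfers entry", entry, {"time", "dilution"})
            transfers.append((float(entry["time"]), float(entry["dilution"])))
        else:
            t, d = entry
            transfers.append((float(t), float(d)))
    return ResolvedConfig(parameters=params, initial_state=initial,
                          simulation=sim, transfers=tuple(transfers))


def load_config(path) -> ResolvedConfig:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return resolve_config(raw or {})


def save_config(config: ResolvedConfig, path) -> None:
    """Write the fully resolved config (defaults included) back out."""
    path = Path(path)
    data = config.as_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# Table schemas: column name -> pandas dtype kind ("f" float, "i" int,
# "O" string-like).
TRAJECTORY_SCHEMA = {"t": "f", "W": "f", "R": "f", "S": "f", "V1": "f",
                     "V2": "f", "N": "f", "V": "f"}
SWEEP_SCHEMA = {"grid_value": "f", "ratio": "f", "log_ratio": "f",
                "v1_extinct": "b", "v2_extinct": "b", "integral_S": "f",
                "peak_S": "f"}
COMPETITION_SCHEMA = {"replicate": "i", "timepoint": "f", "competitor": "O",
                      "quantity": "f"}
ECOI_SCHEMA = {"host": "O", "centres": "f", "cells": "f", "moi": "f"}
OBSERVATION_SCHEMA = {"time": "f", "observable": "O", "log_density": "f"}

_KIND_CAST = {"f": float, "i": "int64", "b": bool, "O": str}


def _enforce(df: pd.DataFrame, schema: dict, where: str) -> pd.DataFrame:
    missing = set(schema) - set(df.columns)
    if missing:
        raise SchemaError(f"{where}: missing column(s) {sorted(missing)}")
    out = df.loc[:, list(schema)].copy()
    for col, kind in schema.items():
        try:
            out[col] = out[col].astype(_KIND_CAST[kind])
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{where}: column {col!r} is not of type {kind!r}: {exc}"
            ) from exc
    return out


def write_table(df: pd.DataFrame, path, schema: dict | None = None) -> None:
    """Write a CSV (comma, LF, full-precision floats)."""
    if schema is not None:
        df = _enforce(df, schema, f"write_table({path})")
    # 17 significant digits + round_trip parsing on read: bit-exact.
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.17g")


def read_table(path, schema: dict | None = None) -> pd.DataFrame:
    """Read a CSV, optionally enforcing a schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    if schema is not None:
        df = _enforce(df, schema, f"read_table({path})")
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to re-execute it exactly."""

    command: str
    config: dict
    seed: int | None = None
    outputs: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.package_version:
            from . import __version__
            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def record_output(self, path) -> None:
        path = Path(path)
        self.outputs[str(path)] = _sha256(path)

    def write(self, path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True,
                                         default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
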