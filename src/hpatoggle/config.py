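"""Run configuration: YAML loading, strict validation, serialization.

A config file is a mapping with optional sections::

    parameters: {a1: 244.8, T: 1.5, ...}   # overrides, canonical per-day units
    mode: simplified | full | reduced
    solver: {drive: step|smooth, steepness: 50, rtol: 1e-7, atol: 1e-9}
    protocol:
      segments: [{t_start: 0, t_end: 100, u: 1, D: 1}]
      events: [{time: 10, ligand: CRH_ex, amount: 5}]
    out: results/run1
    seed: 0

An empty file yields all defaults (the nominal parameter set).  Unknown
keys are rejected by name.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import ConfigError, ModelParameters, PARAM_FIELDS
from .protocol import Protocol

MODES = ("full", "simplified", "reduced")
_TOP_KEYS = {"parameters", "mode", "solver", "protocol", "out", "seed"}
_SOLVER_KEYS = {"drive", "steepness", "rtol", "atol"}


@dataclass
class RunConfig:
    parameters: ModelParameters = field(default_factory=ModelParameters)
    mode: str = "simplified"
    drive: str = "step"
    steepness: float = 50.0
    rtol: float = 1e-7
    atol: float = 1e-9
    protocol: Protocol | None = None
    out: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; valid: {MODES}")
        if self.drive not in ("step", "smooth"):
            raise ConfigError(f"unknown drive {self.drive!r}")

    def to_dict(self) -> dict:
        data: dict = {
            "parameters": self.parameters.to_dict(),
            "mode": self.mode,
            "solver": {"drive": self.drive, "steepness": self.steepness,
                       "rtol": self.rtol, "atol": self.atol},
            "seed": self.seed,
        }
        if self.protocol is not None:
            data["protocol"] = self.protocol.to_dict()
        if self.out is not None:
            data["out"] = self.out
        return data

    def parameter_hash(self) -> str:
        """Short digest of the parameter set, for run logging."""
        blob = json.dumps(self.parameters.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def config_from_dict(data: dict) -> RunConfig:
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}; "
                          f"valid keys are {sorted(_TOP_KEYS)}")
    raw_params = data.get("parameters") or {}
    unknown = set(raw_params) - set(PARAM_FIELDS)
    if unknown:
        raise ConfigError(f"unknown parameter key(s): {sorted(unknown)}")
    params = ModelParameters(**{k: float(v) for k, v in raw_params.items()})
    solver = data.get("solver") or {}
    unknown = set(solver) - _SOLVER_KEYS
    if unknown:
        raise ConfigError(f"unknown solver key(s): {sorted(unknown)}")
    protocol = None
    if "protocol" in data and data["protocol"] is not None:
        protocol = Protocol.from_dict(data["protocol"])
    return RunConfig(
        parameters=params,
        mode=data.get("mode", "simplified"),
        drive=solver.get("drive", "step"),
        steepness=float(solver.get("steepness", 50.0)),
        rtol=float(solver.get("rtol", 1e-7)),
        atol=float(solver.get("atol", 1e-9)),
        protocol=protocol,
        out=data.get("out"),
        seed=int(data.get("seed", 0)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigError(f"cannot parse {path}: {err}") from err
    return config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
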