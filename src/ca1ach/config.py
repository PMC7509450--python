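"""YAML configuration: schema-validated loading and round-tripping.

The config mirrors the parameter dataclasses one-to-one under the ``model:``
key (namespaces ``morphology``, ``channels``, ``er``, ``cytosol``, ``ip3r``,
``soce``, ``m1``, ``solver``) plus optional ``protocols:`` arguments.
Unknown keys are rejected with the offending key path.  Concentrations are
mM throughout; the CLI additionally accepts suffixed strings ("100uM").
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

from .params import ModelParams, _dataclass_from_dict


@dataclass
class ProtocolDefaults:
    dose_lo: float = 1e-6        # mM (1 nM)
    dose_hi: float = 0.1         # mM (100 uM)
    doses_per_decade: int = 4
    phasic_pulse_ms: float = 50.0
    tonic_duration_ms: float = 60e3
    drive_target_hz: float = 10.0
    drive_tol_hz: float = 0.2


@dataclass
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    protocols: ProtocolDefaults = field(default_factory=ProtocolDefaults)

    def to_dict(self) -> dict[str, Any]:
        return {"model": self.model.to_dict(), "protocols": asdict(self.protocols)}


class ConfigError(ValueError):
    pass


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - {"model", "protocols"}
    if unknown:
        raise ConfigError(f"unknown config key: {sorted(unknown)[0]}")
    try:
        model = ModelParams.from_dict(data.get("model", {}))
        proto = _dataclass_from_dict(ProtocolDefaults, data.get("protocols", {}),
                                     path="protocols.")
    except KeyError as err:
        raise ConfigError(str(err.args[0])) from err
    return RunConfig(model=model, protocols=proto)


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def save_params(params: ModelParams, path: str) -> None:
    """Write the flat, units-annotated parameter file."""
    flat = flatten_params(params)
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=True)


def flatten_params(params: ModelParams) -> dict[str, Any]:
    out: dict[str, Any] = {}

    def walk(prefix: str, obj: Any) -> None:
        if isinstance(obj, dict):
            for k, v in obj.items():
                walk(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            out[prefix] = obj

    walk("", params.to_dict())
    return out


def load_params(path: str) -> ModelParams:
    with open(path) as fh:
        flat = yaml.safe_load(fh)
    nested: dict[str, Any] = {}
    for key, value in flat.items():
        node = nested
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return ModelParams.from_dict(nested)
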