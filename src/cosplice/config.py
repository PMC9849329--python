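"""Structured configuration for the simulators (YAML/JSON).

A config file is a mapping with a ``model`` key selecting the simulator
(``delay``, ``multistep``, ``exon_definition``, ``bursting``, ``release``)
and per-model blocks mirroring the dataclass fields.  Parsing is strict:
unknown or missing fields raise :class:`ConfigError` naming the offending
field, and parse -> serialize -> parse is idempotent.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .bursting import BurstingParams
from .commitment import CommitmentParams, CommitmentTopology
from .exondef import ExonDefinitionParams, GeneArchitecture, InhibitionProfile

__all__ = [
    "ConfigError",
    "load_config",
    "dump_config",
    "build_model",
    "model_to_config",
]


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ConfigError(f"unsupported config format: {path.suffix!r}")


def dump_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config, sort_keys=True))
    elif path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        raise ConfigError(f"unsupported config format: {path.suffix!r}")


def _build(cls, block: dict, section: str):
    if not isinstance(block, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise ConfigError(
            f"unknown field(s) {sorted(unknown)} in section {section!r}; "
            f"allowed: {sorted(fields)}"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {section!r}: {exc}") from exc


_SCHEMAS = {
    "delay": {"params": CommitmentParams, "topology": CommitmentTopology},
    "multistep": {"params": CommitmentParams, "topology": CommitmentTopology},
    "exon_definition": {
        "params": ExonDefinitionParams,
        "arch": GeneArchitecture,
        "profile": InhibitionProfile,
    },
    "bursting": {"params": BurstingParams},
}


def build_model(config: dict) -> dict:
    """Instantiate the dataclass bundle described by a config mapping.

    Returns ``{"model": name, <section>: instance, ...}``; scalar extras
    (e.g. ``vpol_grid``, ``seed``, ``t_end``) are passed through untouched.
    """
    if "model" not in config:
        raise ConfigError("missing required key 'model'")
    kind = config["model"]
    if kind == "release":
        out = dict(config)
        if "conditions" not in config:
            raise ConfigError("release config requires a 'conditions' mapping")
        return out
    if kind not in _SCHEMAS:
        raise ConfigError(
            f"unknown model {kind!r}; expected one of {sorted(_SCHEMAS) + ['release']}"
        )
    out = {"model": kind}
    for section, cls in _SCHEMAS[kind].items():
        if section not in config:
            raise ConfigError(f"model {kind!r} requires section {section!r}")
        out[section] = _build(cls, config[section], section)
    for key, value in config.items():
        if key not in out:
            out[key] = value
    return out


def model_to_config(bundle: dict) -> dict:
    """Inverse of :func:`build_model`: dataclasses back to plain mappings."""
    out = {}
    for key, value in bundle.items():
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            d = dataclasses.asdict(value)
            out[key] = {
                k: list(v) if isinstance(v, tuple) else v for k, v in d.items()
            }
        else:
            out[key] = list(value) if isinstance(value, tuple) else value
    return out
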