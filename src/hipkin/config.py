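"""Run configuration: schema-checked loading of YAML/JSON config files.

A :class:`RunConfig` gathers everything a pipeline run needs — the phantom
recipe, the registration search settings, the accuracy-protocol parameters,
the master seed, and logging verbosity.  Loading is strict: unknown keys
are rejected by name, so typos fail loudly instead of silently falling back
to defaults.  A config round-trips losslessly through its file form.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .phantom import PhantomSpec
from .registration import RegistrationConfig, Stage


@dataclass
class ProtocolConfig:
    """Parameters of the synthetic accuracy protocol."""

    n_poses: int = 10
    n_repeats: int = 3
    noise_sigma: float = 0.01
    max_translation_mm: float = 10.0
    max_rotation_deg: float = 10.0
    init_offset_mm: float = 3.0
    init_offset_deg: float = 3.0


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)


# nested dataclass-valued fields and the element type of list-valued ones
_NESTED = {"phantom": PhantomSpec, "registration": RegistrationConfig,
           "protocol": ProtocolConfig}
_NESTED_LISTS = {"stages": Stage}


def _build(cls, doc: dict, path: str):
    if not isinstance(doc, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {unknown} under '{path or 'config'}' "
            f"(known: {sorted(known)})"
        )
    kwargs = {}
    for name, value in doc.items():
        sub = path + "." + name if path else name
        if name in _NESTED_LISTS:
            kwargs[name] = tuple(
                _build(_NESTED_LISTS[name], s, f"{sub}[{i}]")
                for i, s in enumerate(value)
            )
        elif name in _NESTED:
            kwargs[name] = _build(_NESTED[name], value, sub)
        else:
            if isinstance(value, list):
                value = tuple(tuple(v) if isinstance(v, list) else v
                              for v in value)
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except Exception as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
    except Exception as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    return _build(RunConfig, doc, "")


def _normalize(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _normalize(getattr(obj, f.name))
                for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_normalize(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _normalize(v) for k, v in obj.items()}
    return obj


def save_config(cfg: RunConfig, path) -> None:
    """Write a config back to YAML/JSON; load(save(x)) == normalize(x)."""
    path = Path(path)
    doc = _normalize(cfg)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
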