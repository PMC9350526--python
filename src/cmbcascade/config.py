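"""YAML run configuration: strict loading into the package's dataclasses."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .cascade import CascadeConfig
from .phantom import AugmentationPolicy, PhantomConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "build_section"]

_SECTIONS = {
    "phantom": PhantomConfig,
    "augmentation": AugmentationPolicy,
    "cascade": CascadeConfig,
    "training": TrainConfig,
}
_TOP_KEYS = set(_SECTIONS) | {"run_dir", "log_level"}


def _tupleize(cls, kwargs: dict) -> dict:
    out = {}
    hints = {f.name: f for f in dataclasses.fields(cls)}
    for k, v in kwargs.items():
        if isinstance(v, list) and k in hints:
            v = tuple(v)
        out[k] = v
    return out


def build_section(name: str, kwargs: dict):
    """Instantiate one config section, rejecting unknown keys."""
    cls = _SECTIONS[name]
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(kwargs) - valid
    if unknown:
        raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
    return cls(**_tupleize(cls, kwargs))


@dataclasses.dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = PhantomConfig()
    augmentation: AugmentationPolicy = AugmentationPolicy()
    cascade: CascadeConfig = CascadeConfig()
    training: TrainConfig = TrainConfig()
    run_dir: str = "runs"
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Parse a YAML file into a RunConfig; unknown keys anywhere are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    sections = {name: build_section(name, raw.get(name, {}) or {})
                for name in _SECTIONS}
    return RunConfig(run_dir=raw.get("run_dir", "runs"),
                     log_level=raw.get("log_level", "INFO"), **sections)
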