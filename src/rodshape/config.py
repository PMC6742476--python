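"""YAML run configuration: model + protocol + io sections and a seed.

Unknown keys are rejected up front (a typo in a rate name must not silently
fall back to a default), and a loaded config saves and re-loads identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .divider import ModelParams
from .population import Protocol

__all__ = ["IOConfig", "RunConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class IOConfig:
    out_dir: str = "."


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{name}' section: {sorted(unknown)}")
    coerced = {}
    for key, value in section.items():
        if isinstance(value, list):  # yaml has no tuples
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


@dataclass(frozen=True)
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    protocol: Protocol = field(default_factory=Protocol)
    io: IOConfig = field(default_factory=IOConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - {"model", "protocol", "io", "seed"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(
            model=_build(ModelParams, d.get("model", {}) or {}, "model"),
            protocol=_build(Protocol, d.get("protocol", {}) or {}, "protocol"),
            io=_build(IOConfig, d.get("io", {}) or {}, "io"),
            seed=int(d.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "model": dataclasses.asdict(self.model),
            "protocol": dataclasses.asdict(self.protocol),
            "io": dataclasses.asdict(self.io),
        }


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of the canonical config dump (for output headers)."""
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
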