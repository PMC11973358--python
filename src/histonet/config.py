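"""Run configuration: one flat YAML document with per-module sections.

Unknown sections or keys are rejected so a config file round-trips through
serialization unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .arch import ArchConfig
from .augment import AugmentConfig
from .experiment import TrainConfig
from .preprocess import PreprocessConfig
from .synthdata import SyntheticConfig

_SECTIONS = {
    "model": ArchConfig,
    "train": TrainConfig,
    "augment": AugmentConfig,
    "preprocess": PreprocessConfig,
    "synth": SyntheticConfig,
}


@dataclass
class RunConfig:
    data_dir: Optional[str] = None
    test_dir: Optional[str] = None
    output_dir: str = "runs"
    seed: int = 0
    folds: int = 5
    model: ArchConfig = field(default_factory=ArchConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                out[f.name] = {
                    k: (list(x) if isinstance(x, tuple) else x)
                    for k, x in v.__dict__.items()
                }
            else:
                out[f.name] = v
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def _coerce_section(cls, payload: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(
            f"unknown keys in section [{cls.__name__}]: {sorted(unknown)}"
        )
    fields = {f.name: f for f in dataclasses.fields(cls)}
    coerced = {}
    for k, v in payload.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
        _ = fields[k]
    return cls(**coerced)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_fields
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"section '{key}' must be a mapping")
            kwargs[key] = _coerce_section(_SECTIONS[key], value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(cfg.to_yaml())
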