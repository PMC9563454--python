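"""Structured run configuration: YAML in, validated dataclasses out.

Unknown keys are rejected rather than ignored so that a typo in a config
file cannot silently fall back to a default.  The config snapshot written
into every run manifest is sufficient to reproduce any reported number.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import PipelineConfig
from .posture_model import ModelSpec, TrainConfig

__all__ = ["SimulateConfig", "RunConfig", "load_config", "config_to_dict", "config_hash"]


@dataclass(frozen=True)
class SimulateConfig:
    """Cohort-synthesis parameters (defaults = the short-term protocol)."""

    n_subjects: int = 15
    minutes_per_posture: float = 5.0
    fs: float = 500.0
    seed: int = 0
    overnight: bool = False
    overnight_duration_min: float = 366.0


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration: simulation + preprocessing + model."""

    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)


def _build(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        sub = {"simulate": SimulateConfig, "pipeline": PipelineConfig,
               "model": ModelSpec, "train": TrainConfig}.get(key)
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value, f"{path}.{key}")
        elif key in ("layer_sizes", "mmd_scales") and isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML, applying optional top-level overrides."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        for dotted, value in overrides.items():
            node = data
            *parents, leaf = dotted.split(".")
            for p in parents:
                node = node.setdefault(p, {})
            node[leaf] = value
    return _build(RunConfig, data, "config")


def config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, tuple):
            return [clean(v) for v in x]
        return x

    return clean(d)


def config_hash(cfg) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode("utf-8")
    return hashlib.sha256(blob).hexdigest()[:16]
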