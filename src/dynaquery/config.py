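"""Run configuration: a single YAML-serializable object holding every
configurable field of the framework, with the published defaults.

Round-trips losslessly (``from_dict(to_dict(c)) == c``); unknown keys are
rejected so typos in configuration files fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

from .active_learning import ALRunConfig, QueryPolicyConfig, SchedulerConfig
from .model_training import OptimizerConfig
from .preprocessing import AugmentationParams
from .synthetic import SyntheticConfig


@dataclass
class RunConfig:
    """Top-level configuration for one experiment."""

    run: ALRunConfig = field(default_factory=ALRunConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    seeds: list[int] = field(default_factory=lambda: [0])
    manifest_path: str | None = None
    output_dir: str = "runs"


def _build(cls: type, obj: Any) -> Any:
    if is_dataclass(cls) and isinstance(obj, dict):
        valid = {f.name: f for f in fields(cls)}
        unknown = set(obj) - set(valid)
        if unknown:
            raise ValueError(f"unknown configuration keys for {cls.__name__}: {sorted(unknown)}")
        kwargs = {}
        for name, value in obj.items():
            target = _FIELD_TYPES.get((cls.__name__, name))
            kwargs[name] = _build(target, value) if target is not None else value
        return cls(**kwargs)
    return obj


# nested dataclass fields that need explicit reconstruction from plain dicts
_FIELD_TYPES: dict[tuple[str, str], type] = {
    ("RunConfig", "run"): ALRunConfig,
    ("RunConfig", "synthetic"): SyntheticConfig,
    ("ALRunConfig", "scheduler"): SchedulerConfig,
    ("ALRunConfig", "policy"): QueryPolicyConfig,
    ("ALRunConfig", "optimizer"): OptimizerConfig,
    ("ALRunConfig", "augmentation"): AugmentationParams,
}


def to_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def from_dict(obj: dict) -> RunConfig:
    return _build(RunConfig, obj)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    return from_dict(yaml.safe_load(Path(path).read_text()))
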