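"""Nested run configuration with lossless YAML round-trip.

A :class:`RunConfig` bundles the scalogram, model and training configurations
plus the global seed.  Unknown YAML keys are rejected rather than ignored so
typos cannot silently change an experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import ModelConfig
from .tfr import ScalogramConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_run_config", "save_run_config"]


@dataclass
class RunConfig:
    scalogram: ScalogramConfig = field(default_factory=ScalogramConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        def plain(obj):
            d = dataclasses.asdict(obj)
            return {k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in d.items()}

        return {
            "scalogram": plain(self.scalogram),
            "model": plain(self.model),
            "training": plain(self.training),
            "seed": self.seed,
        }


def _build(cls, data: dict, section: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown key(s) in {section!r} config: {sorted(unknown)}")
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_run_config(path) -> RunConfig:
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    unknown = set(data) - {"scalogram", "model", "training", "seed"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    cfg = RunConfig(
        scalogram=_build(ScalogramConfig, data.get("scalogram", {}), "scalogram"),
        model=_build(ModelConfig, data.get("model", {}), "model"),
        training=_build(TrainConfig, data.get("training", {}), "training"),
        seed=int(data.get("seed", 0)),
    )
    cfg.model.validate()
    cfg.training.validate()
    return cfg


def save_run_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(config.to_dict(), f, sort_keys=False)
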