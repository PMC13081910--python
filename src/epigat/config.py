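"""Single-document YAML run configuration.

Sections: model, loss, train, ctsr, data, split, seed.  Unknown keys are
rejected outright — silently ignored configuration is the classic way to run
the wrong experiment.  Every run logs the resolved config plus a content
hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ctsr_training import TrainConfig
from .mga_model import ModelConfig
from .objectives import LossConfig


@dataclass
class DataConfig:
    interface_cutoff: float = 10.0
    adjacency_cutoff: float = 10.0
    M: int = 64
    L: int = 1600


@dataclass
class SplitConfig:
    train_fraction: float = 0.8
    distance_threshold: float = 0.5
    cv_folds: int = 5


@dataclass
class CTSRStageEpochs:
    epochs_per_stage: list = field(default_factory=lambda: [50, 50, 50, 50, 50])


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    ctsr: CTSRStageEpochs = field(default_factory=CTSRStageEpochs)
    data: DataConfig = field(default_factory=DataConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    seed: int = 0

    def resolved(self) -> dict:
        def conv(x):
            if dataclasses.is_dataclass(x):
                return {f.name: conv(getattr(x, f.name)) for f in dataclasses.fields(x)}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x
        return conv(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()).hexdigest()[:16]


def _build(cls, doc: dict, path: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - field_names
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in section {path!r}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in doc:
            v = doc[f.name]
            kwargs[f.name] = tuple(v) if isinstance(f.default, tuple) and isinstance(v, list) else v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ValueError("config root must be a mapping")
    sections = {f.name: f for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - set(sections)
    if unknown:
        raise ValueError(f"unknown config section(s) {sorted(unknown)}")
    kwargs = {}
    for name, f in sections.items():
        if name not in doc:
            continue
        if name == "seed":
            kwargs["seed"] = int(doc["seed"])
        else:
            kwargs[name] = _build(f.default_factory, doc[name] or {}, name)
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path):
    Path(path).write_text(yaml.safe_dump(cfg.resolved(), sort_keys=False))
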