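"""Run configuration: YAML-serializable defaults for every stage."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classifier import DEFAULT_HP, AugmentationConfig, HyperParams, TripletLayout
from .detection import DetectionConfig
from .gman import GMANConfig


@dataclass
class ClassifierScale:
    """Scale overrides for reduced-size runs (full-protocol values by default)."""

    max_epochs: int = 50
    batch_size: int = 64
    triplet_train: int = 100_000
    triplet_val: int = 5_000
    triplet_batch: int = 256


@dataclass
class RunConfig:
    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    hyperparams: dict = field(default_factory=lambda: {k: dataclasses.replace(v)
                                                       for k, v in DEFAULT_HP.items()})
    triplet_layout: TripletLayout = field(default_factory=TripletLayout)
    gman: GMANConfig = field(default_factory=GMANConfig)
    scale: ClassifierScale = field(default_factory=ClassifierScale)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        if "seed" in d:
            cfg.seed = int(d["seed"])
        for name, typ in [("detection", DetectionConfig),
                          ("augmentation", AugmentationConfig),
                          ("triplet_layout", TripletLayout),
                          ("gman", GMANConfig),
                          ("scale", ClassifierScale)]:
            if name in d:
                base = dataclasses.asdict(getattr(cfg, name))
                base.update(d[name])
                # tuples survive YAML round-trips as lists
                for k, v in base.items():
                    if isinstance(v, list):
                        base[k] = tuple(v)
                setattr(cfg, name, typ(**base))
        for net, hp in d.get("hyperparams", {}).items():
            cfg.hyperparams[net] = HyperParams(**hp)
        return cfg


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(cfg.to_dict())), fh, sort_keys=False)
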