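"""Experiment configuration: one plain-text (YAML) file that round-trips
losslessly through :func:`load_config` / :func:`save_config`."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .encoding import FrameMode, InputConfig
from .network import ModelSpec
from .training import AugmentConfig, LossConfig, TrainConfig

__all__ = ["ExperimentConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class ExperimentConfig:
    input_config: InputConfig = InputConfig()
    model: ModelSpec = ModelSpec()
    loss: LossConfig = LossConfig()
    train: TrainConfig = TrainConfig()
    augment: AugmentConfig = AugmentConfig()
    use_augmentation: bool = True
    seed: int = 0


def save_config(cfg: ExperimentConfig, path: str | Path) -> Path:
    doc = asdict(cfg)
    doc["input_config"]["frame_mode"] = FrameMode(cfg.input_config.frame_mode).value
    doc["augment"]["clip_percentiles"] = list(cfg.augment.clip_percentiles)
    path = Path(path)
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def load_config(path: str | Path) -> ExperimentConfig:
    doc = yaml.safe_load(Path(path).read_text())
    aug = dict(doc["augment"])
    aug["clip_percentiles"] = tuple(aug["clip_percentiles"])
    return ExperimentConfig(
        input_config=InputConfig(
            frame_mode=FrameMode(doc["input_config"]["frame_mode"]),
            use_annulus=doc["input_config"]["use_annulus"],
            use_commissures=doc["input_config"]["use_commissures"],
            use_resampling=doc["input_config"]["use_resampling"],
        ),
        model=ModelSpec(**doc["model"]),
        loss=LossConfig(**doc["loss"]),
        train=TrainConfig(**doc["train"]),
        augment=AugmentConfig(**aug),
        use_augmentation=doc["use_augmentation"],
        seed=doc["seed"],
    )
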