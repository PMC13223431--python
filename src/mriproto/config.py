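"""YAML run configuration: one file describing data, model, training and
augmentation, round-tripping losslessly through ``to_dict``/``from_dict``."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .backbone_tokenizer import BackboneConfig
from .data_io import AugmentConfig
from .model import ModelConfig
from .pcm import LossConfig
from .pipeline import TrainConfig
from .synthetic_data import SyntheticSpec
from .vit_encoder import EncoderConfig

__all__ = ["RunConfig", "load_config", "save_config"]


def _tuplify(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and v is not None else v for k, v in d.items()}


@dataclass
class RunConfig:
    manifest: str | None = None
    output_dir: str = "runs/out"
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentConfig = field(default_factory=lambda: AugmentConfig(crop_shape=(16, 32, 32)))
    synthetic: SyntheticSpec | None = None

    def to_dict(self) -> dict:
        d = {
            "manifest": self.manifest,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "model": asdict(self.model),
            "train": asdict(self.train),
            "augment": asdict(self.augment),
            "synthetic": asdict(self.synthetic) if self.synthetic else None,
        }
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        model_d = dict(d.get("model", {}))
        backbone = BackboneConfig(
            **_tuplify(model_d.pop("backbone", {}), ("stage_channels", "stage_blocks", "stage_strides"))
        )
        encoder = EncoderConfig(**model_d.pop("encoder", {}))
        model = ModelConfig(backbone=backbone, encoder=encoder, **model_d)
        train_d = dict(d.get("train", {}))
        loss = LossConfig(**train_d.pop("loss", {}))
        train = TrainConfig(loss=loss, **train_d)
        augment = AugmentConfig(
            **_tuplify(d.get("augment", {}), ("crop_shape", "scale_range"))
        )
        synth = d.get("synthetic")
        synthetic = (
            SyntheticSpec(**_tuplify(synth, ("shape", "body_scale_range"))) if synth else None
        )
        return RunConfig(
            manifest=d.get("manifest"),
            output_dir=d.get("output_dir", "runs/out"),
            seed=d.get("seed", 0),
            model=model,
            train=train,
            augment=augment,
            synthetic=synthetic,
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path} is not a mapping")
    return RunConfig.from_dict(d)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
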