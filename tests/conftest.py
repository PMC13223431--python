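import numpy as np
import pytest

from mriproto import ModelConfig, SequenceClassifier
from mriproto.backbone_tokenizer import BackboneConfig
from mriproto.data_io import AugmentConfig, Volume
from mriproto.vit_encoder import EncoderConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def micro_model_config(n_classes: int = 2, seed: int = 0) -> ModelConfig:
    """Smallest config that still exercises every component: 8x16x16 volumes,
    (1,2,2) backbone grid -> 4 tokens, 2-layer/2-head width-16 encoder."""
    return ModelConfig(
        n_classes=n_classes,
        backbone=BackboneConfig(
            stem_channels=4,
            stage_channels=(4, 8),
            stage_blocks=(1, 1),
            stage_strides=(2, 2),
            seed=seed,
        ),
        encoder=EncoderConfig(n_pre_layers=2, n_heads=2, width=16, mlp_ratio=2.0),
        seed=seed,
    )


@pytest.fixture
def micro_model():
    model = SequenceClassifier(micro_model_config())
    model.build_for_shape((8, 16, 16))
    return model


@pytest.fixture
def micro_aug():
    return AugmentConfig(crop_shape=(8, 16, 16), scale_prob=0.0, flip_prob=0.5, seed=0)


def linear_toy_volumes(n_per_class: int = 10, seed: int = 0) -> list[Volume]:
    """Two trivially separable classes: bright top half vs bright bottom half."""
    rng = np.random.default_rng(seed)
    vols = []
    for c in range(2):
        for i in range(n_per_class):
            arr = 0.1 * rng.random((8, 16, 16))
            if c == 0:
                arr[:, :8, :] += 1.0
            else:
                arr[:, 8:, :] += 1.0
            vols.append(Volume(intensities=arr, label=c, patient_id=f"p{i % 4}"))
    return vols
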