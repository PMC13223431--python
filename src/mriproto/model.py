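"""Full classifier assembly: frozen CNN backbone, tokenizer, transformer
encoder with token selection, and the two classification heads (FC head used
during pretraining and for the ablation baselines; prototype pool otherwise).

Three ablation configurations are supported:

- ``base``     — all N+1 encoder layers on the full token sequence, FC head;
- ``fsm``      — N layers, attention-fused token selection, final layer on
                 [CLS; selected tokens], FC head;
- ``fsm_pcm``  — as ``fsm`` but classified by the prototype pool.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, concat, no_grad
from .backbone_tokenizer import BackboneConfig, ResNet3D, Tokenizer, TokenState, tokenize_batch
from .data_io import minmax_normalize
from .fsm import fuse_attention, select_token_indices
from .nn import LayerNorm, Linear, Module
from .pcm import PrototypePool
from .vit_encoder import AttentionStack, Encoder, EncoderConfig, EncoderLayer

ABLATION_MODES = ("base", "fsm", "fsm_pcm")

__all__ = ["ModelConfig", "SequenceClassifier", "ForwardResult", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    n_classes: int = 4
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    seed: int = 0


@dataclass
class ForwardResult:
    cls: Tensor  # (B, d) output representation
    fc_logits: Tensor | None  # (B, C) when the FC head is attached
    stacks: list[AttentionStack]  # recorded pre-selection attention, per sample
    token_indices: np.ndarray | None  # (B, K) selected positions (fsm modes)


class SequenceClassifier(Module):
    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = ResNet3D(cfg.backbone)
        # token count is fixed by the backbone stride stack and crop shape,
        # so it is supplied at build time via `build_for_shape`
        self.tokenizer: Tokenizer | None = None
        self.encoder = Encoder(cfg.encoder, rng)
        self.last_layer = EncoderLayer(cfg.encoder, rng)
        self.final_norm = LayerNorm(cfg.encoder.width)
        self.fc = Linear(cfg.encoder.width, cfg.n_classes, rng)
        self._rng = rng
        self.selection_count = 0  # instrumentation: times token selection ran

    # -- construction --------------------------------------------------------

    def build_for_shape(self, volume_shape: tuple[int, int, int]) -> None:
        """Instantiate the tokenizer once the input crop shape is known."""
        probe = np.zeros((1,) + tuple(volume_shape))
        grid = self.backbone.forward_batch(probe).shape[2:]
        n_tokens = int(np.prod(grid))
        self.grid_shape = tuple(grid)
        self.tokenizer = Tokenizer(
            self.cfg.backbone.out_channels, n_tokens, self.cfg.encoder.width, self._rng
        )

    # -- forward -------------------------------------------------------------

    def forward_batch(
        self, volumes: np.ndarray, mode: str = "fsm_pcm", with_fc: bool = True
    ) -> ForwardResult:
        """volumes: (B, D, H, W), already normalized/cropped."""
        if mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {mode!r}")
        if self.tokenizer is None:
            raise RuntimeError("call build_for_shape before forward")
        feats = self.backbone.forward_batch(volumes)
        state = tokenize_batch(feats, self.tokenizer)

        per_layer: list[np.ndarray] = []
        x = state.x
        for layer in self.encoder.layers:
            x, attn = layer(x)
            per_layer.append(attn.data.copy())
        stacked = np.stack(per_layer, axis=1)  # (B, N, K, T, T)
        b = stacked.shape[0]
        stacks = [AttentionStack(matrices=stacked[i]) for i in range(b)]

        token_indices = None
        if mode == "base":
            out, _ = self.last_layer(x)
            cls = out[:, 0, :]
        else:
            token_indices = np.stack(
                [select_token_indices(fuse_attention(s)) for s in stacks], axis=0
            )  # (B, K)
            self.selection_count += b
            gathered = x[np.arange(b)[:, None], token_indices, :]  # (B, K, d)
            cls_in = x[:, 0:1, :]
            seq = concat([cls_in, gathered], axis=1)  # (B, K+1, d)
            out, _ = self.last_layer(seq)
            cls = out[:, 0, :]

        cls = self.final_norm(cls)
        logits = self.fc(cls) if with_fc else None
        return ForwardResult(cls=cls, fc_logits=logits, stacks=stacks, token_indices=token_indices)

    def forward_volume(self, intensities: np.ndarray, mode: str = "fsm_pcm") -> ForwardResult:
        """Single pre-cropped volume, evaluation mode (no graph)."""
        with no_grad():
            return self.forward_batch(minmax_normalize(intensities)[None], mode=mode)

    def trainable_parameters(self):
        return self.parameters()  # backbone weights are not Parameters

    # -- serialization -------------------------------------------------------

    def full_state(self) -> dict[str, np.ndarray]:
        state = {f"model.{k}": v for k, v in self.state_dict().items()}
        state.update({f"backbone.{k}": v for k, v in self.backbone.state_dict().items()})
        return state

    def load_full_state(self, state: dict[str, np.ndarray]) -> None:
        self.load_state_dict(
            {k[len("model."):]: v for k, v in state.items() if k.startswith("model.")}
        )
        self.backbone.load_state_dict(
            {k[len("backbone."):]: v for k, v in state.items() if k.startswith("backbone.")}
        )


def save_checkpoint(
    path,
    model: SequenceClassifier,
    pool: PrototypePool | None = None,
    label_vocabulary: list[str] | None = None,
    extra: dict | None = None,
) -> None:
    """Single-file checkpoint: parameters, optional prototype pool, metadata."""
    arrays = model.full_state()
    meta = {
        "n_classes": model.cfg.n_classes,
        "encoder": asdict(model.cfg.encoder),
        "backbone": asdict(model.cfg.backbone),
        "seed": model.cfg.seed,
        "volume_shape": None,
        "label_vocabulary": label_vocabulary,
        "has_pool": pool is not None,
        "extra": extra or {},
    }
    if model.tokenizer is not None:
        meta["n_tokens"] = model.tokenizer.n_tokens
        meta["grid_shape"] = list(getattr(model, "grid_shape", ()))
    if pool is not None:
        arrays["pool.vectors"] = pool.vectors
        arrays["pool.class_ids"] = pool.class_ids
        meta["pool_G"] = pool.G
        meta["pool_C"] = pool.C
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, volume_shape: tuple[int, int, int]):
    """Returns (model, pool-or-None, metadata dict)."""
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("__meta__").tobytes()).decode())
    cfg = ModelConfig(
        n_classes=meta["n_classes"],
        backbone=BackboneConfig(**{**meta["backbone"],
                                   "stage_channels": tuple(meta["backbone"]["stage_channels"]),
                                   "stage_blocks": tuple(meta["backbone"]["stage_blocks"]),
                                   "stage_strides": tuple(meta["backbone"]["stage_strides"])}),
        encoder=EncoderConfig(**meta["encoder"]),
        seed=meta["seed"],
    )
    model = SequenceClassifier(cfg)
    model.build_for_shape(volume_shape)
    pool = None
    if meta.get("has_pool"):
        pool = PrototypePool(
            vectors=arrays.pop("pool.vectors"),
            class_ids=arrays.pop("pool.class_ids"),
            G=meta["pool_G"],
            C=meta["pool_C"],
        )
    model.load_full_state(arrays)
    return model, pool, meta
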