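"""Frozen 3D convolutional backbone and token embedding.

A 3D residual network (ResNet18-style basic blocks) extracts a coarse feature
grid from each volume. Its weights are randomly initialized (He scaling) and
frozen: the backbone acts as a fixed feature extractor, so it is implemented
as pure-numpy forward computation with no gradient path. An optional
checkpoint load replaces the random weights.

Each spatial position of the final feature grid becomes one token; tokens are
linearly projected to the encoder width, learned positional embeddings are
added, and a learned CLS embedding is prepended. The projection, positional
and CLS parameters are trainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autodiff import Parameter, Tensor, concat
from .data_io import Volume
from .nn import Linear, Module

__all__ = [
    "BackboneConfig",
    "FeatureMap",
    "TokenState",
    "ResNet3D",
    "Tokenizer",
    "extract_basic_features",
    "tokenize",
]


@dataclass
class BackboneConfig:
    """Architecture of the frozen feature extractor.

    The default is a reduced three-stage network sized for desk-scale volumes
    (16 x 32 x 32 -> 64-channel 2 x 4 x 4 grid). ``resnet18`` returns the full
    four-stage 3D ResNet18 layout for full-resolution volumes.
    """

    in_channels: int = 1
    stem_channels: int = 16
    stem_kernel: int = 3
    stem_stride: int = 2
    stem_pool: bool = False
    stage_channels: tuple[int, ...] = (16, 32, 64)
    stage_blocks: tuple[int, ...] = (1, 1, 1)
    stage_strides: tuple[int, ...] = (2, 2, 1)
    frozen: bool = True
    seed: int = 0

    @staticmethod
    def resnet18() -> "BackboneConfig":
        return BackboneConfig(
            stem_channels=64,
            stem_kernel=7,
            stem_stride=2,
            stem_pool=True,
            stage_channels=(64, 128, 256, 512),
            stage_blocks=(2, 2, 2, 2),
            stage_strides=(1, 2, 2, 2),
        )

    @property
    def out_channels(self) -> int:
        return self.stage_channels[-1]

    @property
    def total_stride(self) -> int:
        s = self.stem_stride * (2 if self.stem_pool else 1)
        for st in self.stage_strides:
            s *= st
        return s


@dataclass
class FeatureMap:
    """Backbone output: a (channels, depth', height', width') feature grid."""

    features: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 4:
            raise ValueError("feature map must be 4D (C, D', H', W')")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature map contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.features.shape[1:]

    @property
    def n_tokens(self) -> int:
        d, h, w = self.grid_shape
        return d * h * w


@dataclass
class TokenState:
    """Token sequence at one encoder layer: CLS followed by M feature tokens.

    ``x`` has shape (batch, M+1, width); position 0 is the CLS token.
    """

    x: Tensor
    layer_index: int = 0

    @property
    def n_tokens(self) -> int:
        return self.x.shape[1] - 1

    @property
    def width(self) -> int:
        return self.x.shape[2]

    def cls(self) -> Tensor:
        return self.x[:, 0, :]

    def tokens(self) -> Tensor:
        return self.x[:, 1:, :]


def _conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    """'Same'-padded strided 3D convolution as an im2col GEMM.

    x: (B,C,D,H,W), w: (O,C,k,k,k); computed in float32 (the backbone is a
    frozen feature extractor, so reduced precision is inconsequential and
    deterministic for fixed inputs).
    """
    k = w.shape[-1]
    p = k // 2
    x = np.pad(x.astype(np.float32, copy=False), ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]  # (B,C,D',H',W',k,k,k)
    bsz, c, dd, hh, ww = win.shape[:5]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        bsz * dd * hh * ww, c * k**3
    )
    w2 = w.reshape(w.shape[0], -1).T.astype(np.float32)
    out = cols @ w2 + b.astype(np.float32)
    return out.reshape(bsz, dd, hh, ww, -1).transpose(0, 4, 1, 2, 3)


def _maxpool3d(x: np.ndarray, k: int = 3, stride: int = 2) -> np.ndarray:
    p = k // 2
    x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)), constant_values=-np.inf)
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::stride, ::stride, ::stride]
    return win.max(axis=(5, 6, 7))


class ResNet3D:
    """Forward-only residual 3D CNN with frozen weights."""

    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.weights: dict[str, np.ndarray] = {}

        def he_conv(name: str, c_out: int, c_in: int, k: int):
            fan_in = c_in * k**3
            self.weights[f"{name}.w"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k, k)
            )
            self.weights[f"{name}.b"] = np.zeros(c_out)

        he_conv("stem", cfg.stem_channels, cfg.in_channels, cfg.stem_kernel)
        c_in = cfg.stem_channels
        for s, (c_out, n_blocks) in enumerate(zip(cfg.stage_channels, cfg.stage_blocks)):
            for blk in range(n_blocks):
                base = f"stage{s}.block{blk}"
                he_conv(f"{base}.conv1", c_out, c_in, 3)
                he_conv(f"{base}.conv2", c_out, c_out, 3)
                stride = cfg.stage_strides[s] if blk == 0 else 1
                if stride != 1 or c_in != c_out:
                    he_conv(f"{base}.skip", c_out, c_in, 1)
                c_in = c_out

    def forward_batch(self, volumes: np.ndarray) -> np.ndarray:
        """volumes: (B, D, H, W) -> (B, C_out, D', H', W')."""
        cfg = self.cfg
        x = volumes[:, None].astype(np.float64)
        self._check_size(x.shape[2:])
        w = self.weights
        x = np.maximum(_conv3d(x, w["stem.w"], w["stem.b"], cfg.stem_stride), 0.0)
        if cfg.stem_pool:
            x = _maxpool3d(x)
        for s, n_blocks in enumerate(cfg.stage_blocks):
            for blk in range(n_blocks):
                base = f"stage{s}.block{blk}"
                stride = cfg.stage_strides[s] if blk == 0 else 1
                h = np.maximum(_conv3d(x, w[f"{base}.conv1.w"], w[f"{base}.conv1.b"], stride), 0.0)
                h = _conv3d(h, w[f"{base}.conv2.w"], w[f"{base}.conv2.b"], 1)
                if f"{base}.skip.w" in w:
                    sk = _conv3d(x, w[f"{base}.skip.w"], w[f"{base}.skip.b"], stride)
                else:
                    sk = x
                x = np.maximum(h + sk, 0.0)
        return x

    def _check_size(self, shape: tuple[int, int, int]) -> None:
        stride = self.cfg.total_stride
        if any(s < stride for s in shape):
            raise ValueError(
                f"volume shape {shape} too small for total stride {stride}"
            )

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.weights.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.weights):
            raise KeyError("backbone state dict mismatch")
        for k in self.weights:
            self.weights[k] = np.asarray(state[k], dtype=np.float64).copy()


def extract_basic_features(v: Volume, backbone: ResNet3D) -> FeatureMap:
    """Run one volume through the frozen backbone."""
    out = backbone.forward_batch(v.intensities[None])
    return FeatureMap(features=out[0])


class Tokenizer(Module):
    """Linear token projection with learned positional and CLS embeddings."""

    def __init__(self, in_channels: int, n_tokens: int, width: int, rng: np.random.Generator):
        self.proj = Linear(in_channels, width, rng)
        self.pos = Parameter(rng.normal(0.0, 0.02, size=(n_tokens + 1, width)))
        self.cls = Parameter(rng.normal(0.0, 0.02, size=(width,)))
        self.n_tokens = n_tokens
        self.width = width


def tokenize(f: FeatureMap, tok: Tokenizer) -> TokenState:
    """Turn a feature grid into the layer-0 token sequence [CLS; M tokens]."""
    return tokenize_batch(f.features[None], tok)


def tokenize_batch(features: np.ndarray, tok: Tokenizer) -> TokenState:
    """features: (B, C, D', H', W') -> TokenState with x (B, M+1, width)."""
    b, c, *grid = features.shape
    m = int(np.prod(grid))
    if m != tok.n_tokens:
        raise ValueError(f"grid yields {m} tokens, tokenizer expects {tok.n_tokens}")
    flat = features.reshape(b, c, m).transpose(0, 2, 1)  # (B, M, C)
    content = tok.proj(Tensor(flat))  # (B, M, width)
    cls = tok.cls.reshape(1, 1, tok.width) + Tensor(np.zeros((b, 1, tok.width)))
    x = concat([cls, content], axis=1) + tok.pos.reshape(1, m + 1, tok.width)
    return TokenState(x=x, layer_index=0)
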