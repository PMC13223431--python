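"""Pre-norm transformer encoder that records per-head attention maps.

Each layer applies multi-head self-attention inside a residual branch
(z' = z + MSA(LN(z))) followed by an MLP residual branch
(z'' = z' + MLP(LN(z'))). The row-stochastic attention matrices of every head
are recorded per layer so the feature-selection stage can fuse them across
depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .backbone_tokenizer import TokenState
from .nn import LayerNorm, Linear, Module

__all__ = [
    "EncoderConfig",
    "AttentionStack",
    "EncoderLayer",
    "Encoder",
    "encoder_layer",
    "encode",
]


@dataclass
class EncoderConfig:
    n_pre_layers: int = 2  # layers before token selection (the model has one more)
    n_heads: int = 4
    width: int = 64
    mlp_ratio: float = 2.0
    dropout: float = 0.0

    def __post_init__(self):
        if self.n_pre_layers < 1 or self.n_heads < 1:
            raise ValueError("need at least one layer and one head")
        if self.width % self.n_heads != 0:
            raise ValueError("width must be divisible by n_heads")


@dataclass
class AttentionStack:
    """Recorded attention: ``matrices[layer][head]`` is (M+1)x(M+1).

    Convention: rows index queries, columns index keys, so row 0 holds the
    attention of the CLS query over every position.
    """

    matrices: np.ndarray  # (n_layers, n_heads, M+1, M+1)

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=np.float64)
        if self.matrices.ndim != 4 or self.matrices.shape[-1] != self.matrices.shape[-2]:
            raise ValueError("attention stack must be (layers, heads, T, T)")

    @property
    def n_layers(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_heads(self) -> int:
        return self.matrices.shape[1]

    def validate_row_stochastic(self, tol: float = 1e-5) -> None:
        if self.matrices.min() < -tol:
            raise ValueError("negative attention weight")
        sums = self.matrices.sum(axis=-1)
        if np.abs(sums - 1.0).max() > tol:
            raise ValueError("attention rows do not sum to 1")


class MultiHeadSelfAttention(Module):
    def __init__(self, width: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.head_dim = width // n_heads
        self.q = Linear(width, width, rng)
        self.k = Linear(width, width, rng)
        self.v = Linear(width, width, rng)
        self.out = Linear(width, width, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        b, t, d = x.shape
        k_heads, dh = self.n_heads, self.head_dim

        def split(h: Tensor) -> Tensor:
            return h.reshape(b, t, k_heads, dh).transpose(0, 2, 1, 3)

        q = split(self.q(x))
        k = split(self.k(x))
        v = split(self.v(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = logits.softmax(axis=-1)  # (B, K, T, T)
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.out(mixed), attn


class MLP(Module):
    def __init__(self, width: int, mlp_ratio: float, rng: np.random.Generator):
        hidden = int(round(width * mlp_ratio))
        self.fc1 = Linear(width, hidden, rng)
        self.fc2 = Linear(hidden, width, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class EncoderLayer(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.norm1 = LayerNorm(cfg.width)
        self.attn = MultiHeadSelfAttention(cfg.width, cfg.n_heads, rng)
        self.norm2 = LayerNorm(cfg.width)
        self.mlp = MLP(cfg.width, cfg.mlp_ratio, rng)
        self.width = cfg.width

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        attended, attn = self.attn(self.norm1(x))
        x = x + attended
        x = x + self.mlp(self.norm2(x))
        return x, attn


class Encoder(Module):
    """The first N layers of the transformer (the final layer lives with the
    feature-selection stage, which decides what token sequence it sees)."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.layers = [EncoderLayer(cfg, rng) for _ in range(cfg.n_pre_layers)]


def encoder_layer(state: TokenState, layer: EncoderLayer) -> tuple[TokenState, np.ndarray]:
    """Apply one encoder layer; returns the new state and the per-head
    attention matrices (batch, heads, M+1, M+1) as plain arrays."""
    if state.width != layer.width:
        raise ValueError(f"token width {state.width} != layer width {layer.width}")
    x, attn = layer(state.x)
    return TokenState(x=x, layer_index=state.layer_index + 1), attn.data.copy()


def encode(z0: TokenState, enc: Encoder) -> tuple[TokenState, list[AttentionStack]]:
    """Run all N pre-selection layers, recording attention.

    Returns the layer-N TokenState and one AttentionStack per batch element
    (shape (N, K, M+1, M+1) each).
    """
    state = z0
    per_layer: list[np.ndarray] = []
    for layer in enc.layers:
        state, attn = encoder_layer(state, layer)
        per_layer.append(attn)
    stacked = np.stack(per_layer, axis=1)  # (B, N, K, T, T)
    stacks = [AttentionStack(matrices=stacked[b]) for b in range(stacked.shape[0])]
    return state, stacks
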