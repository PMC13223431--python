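"""Feature Selection Module: attention fusion and token selection.

The attention a deep encoder layer assigns between CLS and a token no longer
reflects which *input* token the CLS embedding depends on, because every layer
re-mixes tokens. The module therefore fuses the recorded attention of the
first N layers by cumulative matrix multiplication per head,

    A_final^i = A_N^i @ A_{N-1}^i @ ... @ A_1^i,

so row 0 of the fused matrix gives the effective CLS-to-token weights. For
each of the K heads the single most-attended token (CLS position excluded) is
selected; the final encoder layer is then run on the short sequence
[CLS; selected tokens], forcing it to aggregate only the most discriminative,
localized features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .backbone_tokenizer import TokenState
from .vit_encoder import AttentionStack, EncoderLayer

__all__ = [
    "FusedAttention",
    "SelectedFeatures",
    "fuse_attention",
    "select_tokens",
    "select_token_indices",
    "final_layer",
]


@dataclass
class FusedAttention:
    """Per-head fused attention matrices and their CLS rows."""

    per_head: np.ndarray  # (K, M+1, M+1)

    def __post_init__(self):
        self.per_head = np.asarray(self.per_head, dtype=np.float64)
        if self.per_head.ndim != 3 or self.per_head.shape[-1] != self.per_head.shape[-2]:
            raise ValueError("fused attention must be (heads, T, T)")

    @property
    def cls_vector(self) -> np.ndarray:
        """(K, M+1): fused weight of the CLS query over every position."""
        return self.per_head[:, 0, :]


@dataclass
class SelectedFeatures:
    """K selected token vectors (one per head) and their 1-based positions."""

    token_vectors: Tensor  # (K, d)
    token_indices: np.ndarray  # (K,), values in [1, M]

    def __post_init__(self):
        self.token_indices = np.asarray(self.token_indices, dtype=int)
        if np.any(self.token_indices < 1):
            raise ValueError("selected indices must exclude the CLS position 0")


def fuse_attention(stack: AttentionStack) -> FusedAttention:
    """Cumulative per-head matrix product across layers (later layers on the
    left, so the CLS query row propagates through the whole depth)."""
    mats = stack.matrices
    if mats.shape[0] < 1:
        raise ValueError("attention stack is empty")
    fused = mats[0].copy()  # (K, T, T)
    for layer in range(1, mats.shape[0]):
        fused = mats[layer] @ fused
    return FusedAttention(per_head=fused)


def select_token_indices(fa: FusedAttention) -> np.ndarray:
    """Per-head argmax of the fused CLS-to-token weights.

    The CLS position itself is excluded; ties break to the smallest index.
    Returned indices are 1-based sequence positions in [1, M].
    """
    token_weights = fa.cls_vector[:, 1:]  # (K, M)
    return np.argmax(token_weights, axis=1) + 1


def select_tokens(fa: FusedAttention, state: TokenState) -> SelectedFeatures:
    """Gather the layer-N hidden vectors of the per-head most-attended tokens."""
    if fa.per_head.shape[-1] != state.n_tokens + 1:
        raise ValueError("fused attention size does not match token count")
    idx = select_token_indices(fa)
    if state.x.shape[0] != 1:
        raise ValueError("select_tokens operates on a single-sample state")
    vectors = state.x[0, idx, :]  # (K, d); gradient flows into the gathered rows
    return SelectedFeatures(token_vectors=vectors, token_indices=idx)


def final_layer(cls: Tensor, selected: SelectedFeatures, layer: EncoderLayer) -> Tensor:
    """Run the last encoder layer on [CLS; selected tokens]; return its CLS.

    ``cls`` has shape (d,) — the layer-N CLS embedding of one sample.
    """
    seq = concat(
        [cls.reshape(1, 1, -1), selected.token_vectors.reshape(1, -1, cls.shape[-1])],
        axis=1,
    )
    out, _ = layer(seq)
    return out[0, 0, :]


def fused_cls_heatmap(
    stacks: list[AttentionStack], grid_shape: tuple[int, int, int]
) -> np.ndarray:
    """Mean-over-heads fused CLS-to-token weights on the backbone grid.

    Returns one (D', H', W') map per sample, stacked on axis 0 — the
    qualitative attention visualization exported by the CLI.
    """
    maps = []
    for stack in stacks:
        fused = fuse_attention(stack)
        w = fused.cls_vector[:, 1:].mean(axis=0)  # (M,)
        maps.append(w.reshape(grid_shape))
    return np.stack(maps, axis=0)
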