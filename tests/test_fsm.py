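"""Attention-fusion and token-selection oracles.

The fusion oracle multiplies the layer matrices with explicit nested loops;
the selection oracle scans the fused CLS weights exhaustively. Both are
independent of the numpy implementations they check.
"""

import numpy as np
import pytest

from mriproto.autodiff import Tensor
from mriproto.backbone_tokenizer import TokenState
from mriproto.fsm import (
    FusedAttention,
    final_layer,
    fuse_attention,
    select_token_indices,
    select_tokens,
)
from mriproto.synthetic_data import generate_attention_fixture
from mriproto.vit_encoder import AttentionStack, EncoderConfig, EncoderLayer


def loop_matrix_product(stack: np.ndarray) -> np.ndarray:
    """Naive per-head triple-loop product A_N ... A_1."""
    n_layers, n_heads, t, _ = stack.shape
    out = np.zeros((n_heads, t, t))
    for h in range(n_heads):
        acc = np.eye(t)
        for layer in range(n_layers):
            prev = acc
            acc = np.zeros((t, t))
            for i in range(t):
                for j in range(t):
                    s = 0.0
                    for k in range(t):
                        s += stack[layer, h, i, k] * prev[k, j]
                    acc[i, j] = s
        out[h] = acc
    return out


def exhaustive_argmax(cls_vector: np.ndarray) -> np.ndarray:
    """Per-head scan over token positions 1..M, first maximum wins."""
    out = []
    for head in cls_vector:
        best_j, best_w = 1, -np.inf
        for j in range(1, len(head)):
            if head[j] > best_w:
                best_j, best_w = j, head[j]
        out.append(best_j)
    return np.array(out)


class TestFuseAttention:
    def test_single_layer_is_identity_operation(self):
        stack = generate_attention_fixture(1, 3, 5, seed=0)
        fused = fuse_attention(stack)
        assert np.array_equal(fused.per_head, stack.matrices[0])

    def test_identity_matrices_fuse_to_identity(self):
        eye = np.broadcast_to(np.eye(4), (3, 2, 4, 4)).copy()
        fused = fuse_attention(AttentionStack(matrices=eye))
        assert np.allclose(fused.per_head, np.eye(4))
        assert np.allclose(fused.cls_vector, np.eye(4)[0])

    def test_matches_loop_oracle(self):
        stack = generate_attention_fixture(3, 2, 5, seed=7)
        fused = fuse_attention(stack)
        assert np.allclose(fused.per_head, loop_matrix_product(stack.matrices), atol=1e-10)

    def test_row_stochastic_closure(self):
        for seed in range(10):
            stack = generate_attention_fixture(3, 2, 6, seed=seed)
            fused = fuse_attention(stack)
            assert np.allclose(fused.per_head.sum(axis=-1), 1.0, atol=1e-5)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            fuse_attention(AttentionStack(matrices=np.zeros((0, 1, 3, 3))))


class TestSelectTokens:
    def test_direct_argmax_excludes_cls(self):
        fa = FusedAttention(per_head=np.array([[[0.5, 0.1, 0.4], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]]))
        assert select_token_indices(fa).tolist() == [2]

    def test_uniform_ties_break_to_smallest_index(self):
        fa = FusedAttention(per_head=np.full((2, 4, 4), 0.25))
        assert select_token_indices(fa).tolist() == [1, 1]

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cls_rows = rng.random((4, 7))
            mats = np.broadcast_to(cls_rows[:, None, :], (4, 7, 7)).copy()
            fa = FusedAttention(per_head=mats)
            assert np.array_equal(select_token_indices(fa), exhaustive_argmax(cls_rows))

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(1)
        mats = rng.random((3, 6, 6))
        fa = FusedAttention(per_head=mats)
        scaled = FusedAttention(per_head=mats * 37.5)
        assert np.array_equal(select_token_indices(fa), select_token_indices(scaled))

    def test_gathers_layer_n_hidden_states(self):
        rng = np.random.default_rng(2)
        state = TokenState(x=Tensor(rng.normal(size=(1, 6, 4))), layer_index=2)
        mats = rng.random((2, 6, 6))
        sel = select_tokens(FusedAttention(per_head=mats), state)
        assert sel.token_vectors.shape == (2, 4)
        for h in range(2):
            j = sel.token_indices[h]
            assert 1 <= j <= 5
            assert np.array_equal(sel.token_vectors.data[h], state.x.data[0, j])


class TestFinalLayer:
    def _parts(self, k=2, d=8, seed=0):
        rng = np.random.default_rng(seed)
        cfg = EncoderConfig(n_pre_layers=1, n_heads=2, width=d)
        layer = EncoderLayer(cfg, rng)
        cls = Tensor(rng.normal(size=(d,)))
        from mriproto.fsm import SelectedFeatures

        sel = SelectedFeatures(
            token_vectors=Tensor(rng.normal(size=(k, d))),
            token_indices=np.arange(1, k + 1),
        )
        return cls, sel, layer

    def test_sequence_length_and_output_shape(self):
        cls, sel, layer = self._parts(k=3)
        out = final_layer(cls, sel, layer)
        assert out.shape == (8,)

    def test_residual_identity_returns_input_cls(self):
        cls, sel, layer = self._parts()
        layer.attn.out.weight.data[:] = 0.0
        layer.attn.out.bias.data[:] = 0.0
        layer.mlp.fc2.weight.data[:] = 0.0
        layer.mlp.fc2.bias.data[:] = 0.0
        out = final_layer(cls, sel, layer)
        assert np.allclose(out.data, cls.data, atol=1e-12)

    def test_matches_independent_block_computation(self):
        """Step-by-step numpy replay of one pre-norm attention + MLP block."""
        cls, sel, layer = self._parts(k=2, d=8, seed=3)
        out = final_layer(cls, sel, layer)

        def ln(x, gamma, beta, eps=1e-6):
            mu = x.mean(-1, keepdims=True)
            var = ((x - mu) ** 2).mean(-1, keepdims=True)
            return (x - mu) / np.sqrt(var + eps) * gamma + beta

        x = np.vstack([cls.data[None], sel.token_vectors.data])  # (3, 8)
        h = ln(x, layer.norm1.gamma.data, layer.norm1.beta.data)
        nh, dh = 2, 4
        q = (h @ layer.attn.q.weight.data + layer.attn.q.bias.data).reshape(3, nh, dh)
        k_ = (h @ layer.attn.k.weight.data + layer.attn.k.bias.data).reshape(3, nh, dh)
        v = (h @ layer.attn.v.weight.data + layer.attn.v.bias.data).reshape(3, nh, dh)
        mixed = np.zeros((3, nh, dh))
        for head in range(nh):
            logits = q[:, head] @ k_[:, head].T / np.sqrt(dh)
            e = np.exp(logits - logits.max(-1, keepdims=True))
            a = e / e.sum(-1, keepdims=True)
            mixed[:, head] = a @ v[:, head]
        attended = mixed.reshape(3, 8) @ layer.attn.out.weight.data + layer.attn.out.bias.data
        x = x + attended
        h2 = ln(x, layer.norm2.gamma.data, layer.norm2.beta.data)
        z = h2 @ layer.mlp.fc1.weight.data + layer.mlp.fc1.bias.data
        c = np.sqrt(2 / np.pi)
        z = 0.5 * z * (1 + np.tanh(c * (z + 0.044715 * z**3)))
        x = x + (z @ layer.mlp.fc2.weight.data + layer.mlp.fc2.bias.data)
        assert np.allclose(out.data, x[0], atol=1e-10)
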