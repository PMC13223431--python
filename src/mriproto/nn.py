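"""Small neural-network layer library on top of :mod:`mriproto.autodiff`.

Provides the pieces the encoder needs (Linear, LayerNorm, multi-head
self-attention, MLP), an AdamW optimizer and the cosine-with-warmup
learning-rate schedule used for training.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "AdamW",
    "cosine_warmup_lr",
]


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def visit(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    visit(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    visit(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    visit(v)

        visit(self)
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def visit(obj, name):
            if isinstance(obj, Parameter):
                out[name] = obj
            elif isinstance(obj, Module):
                for k, v in vars(obj).items():
                    visit(v, f"{name}.{k}" if name else k)
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    visit(v, f"{name}.{i}")
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    visit(v, f"{name}.{k}")

        visit(self, prefix)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = self.named_parameters()
        missing = set(named) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in named.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        std = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(width))
        self.beta = Parameter(np.zeros(width))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class AdamW:
    """Decoupled weight-decay Adam (Loshchilov & Hutter)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self._t
        bc2 = 1.0 - b2**self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_warmup_lr(epoch: int, total_epochs: int, warmup_epochs: int, peak_lr: float) -> float:
    """Linear warmup from ~0 to ``peak_lr`` then cosine decay to 0.

    ``epoch`` is zero-based; at ``epoch == warmup_epochs`` the rate is the peak.
    """
    if total_epochs <= 0:
        raise ValueError("total_epochs must be positive")
    if warmup_epochs > 0 and epoch < warmup_epochs:
        return peak_lr * (epoch + 1) / (warmup_epochs + 1)
    span = max(total_epochs - warmup_epochs, 1)
    progress = (epoch - warmup_epochs) / span
    return peak_lr * 0.5 * (1.0 + np.cos(np.pi * min(progress, 1.0)))
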