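"""Transformer building blocks on top of the autodiff engine.

Post-layer-norm encoder blocks in the BERT style: multi-head self-attention
and a GELU feed-forward sublayer, each wrapped in residual + layer norm.
Weight init is truncated normal (sigma = 0.02, clipped at two sigma), seeded
through an explicit numpy Generator so model construction is reproducible.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor, embedding, gelu, layer_norm, softmax

__all__ = [
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Dropout",
    "MultiHeadSelfAttention",
    "TransformerLayer",
    "TransformerEncoder",
    "MLP",
    "trunc_normal",
]


def trunc_normal(rng: np.random.Generator, shape, sigma: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, sigma, size=shape)
    return np.clip(x, -2 * sigma, 2 * sigma).astype(np.float32)


class Module:
    """Tiny module system: named parameters, train/eval flag, state dicts."""

    def __init__(self) -> None:
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def _child_modules(self) -> Iterator["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
                yield from value._child_modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item
                        yield from item._child_modules()

    def train(self) -> "Module":
        self.training = True
        for m in self._child_modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._child_modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict keys do not match parameters: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: "
                                 f"{p.data.shape} vs {state[name].shape}")
            p.data = state[name].astype(np.float32).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(trunc_normal(rng, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_tokens: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(trunc_normal(rng, (n_tokens, dim)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.eps) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout driven by an explicit Generator for reproducibility."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = np.float32(1.0 - self.p)
        mask = (self.rng.random(x.shape, dtype=np.float32) < keep)
        return x * (mask.astype(np.float32) / keep)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, attn_dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"hidden size {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)
        self.drop = Dropout(attn_dropout, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        """x: [B, T, d]; key_mask: [B, T] with 1 = attendable, 0 = padding."""
        B, T, d = x.shape

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

        q, k, v = heads(self.q(x)), heads(self.k(x)), heads(self.v(x))
        scores = (q @ k.swapaxes(-1, -2)) * np.float32(1.0 / math.sqrt(self.d_head))
        bias = ((1.0 - key_mask[:, None, None, :]) * -1e9).astype(np.float32)
        attn = softmax(scores + bias, axis=-1)
        attn = self.drop(attn)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, d)
        return self.out(ctx)


class TransformerLayer(Module):
    """Post-LN encoder block: LN(x + MHSA(x)), LN(x + FFN(x))."""

    def __init__(self, dim: int, n_heads: int, intermediate: int,
                 dropout: float, attn_dropout: float, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, attn_dropout, rng)
        self.ln1 = LayerNorm(dim)
        self.fc1 = Linear(dim, intermediate, rng)
        self.fc2 = Linear(intermediate, dim, rng)
        self.ln2 = LayerNorm(dim)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x, key_mask)))
        x = self.ln2(x + self.drop(self.fc2(gelu(self.fc1(x)))))
        return x


class TransformerEncoder(Module):
    def __init__(self, n_layers: int, dim: int, n_heads: int, intermediate: int,
                 dropout: float, attn_dropout: float, rng: np.random.Generator):
        super().__init__()
        self.layers = [
            TransformerLayer(dim, n_heads, intermediate, dropout, attn_dropout, rng)
            for _ in range(n_layers)
        ]

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        for layer in self.layers:
            x = layer(x, key_mask)
        return x


class MLP(Module):
    """One-hidden-layer perceptron (projector / predictor heads).

    The hidden layer is layer-normalized: self-distillation objectives
    collapse to constant outputs without normalization in these heads.
    """

    def __init__(self, n_in: int, hidden: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(n_in, hidden, rng)
        self.ln = LayerNorm(hidden)
        self.fc2 = Linear(hidden, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(gelu(self.ln(self.fc1(x))))
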