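"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains Transformer encoders on a single CPU, so the engine is a
small tape-based design: every operation builds a :class:`Tensor` that holds
its forward value and a closure accumulating gradients into its parents.
All floating point work is float32. Only the operations the models need are
implemented; each non-trivial backward rule is covered by finite-difference
tests.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "embedding",
    "softmax",
    "layer_norm",
    "gelu",
    "bce_with_logits",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference / target nets)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


class Tensor:
    """A float32 array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        # Callers guarantee `grad` is either freshly allocated or a view that
        # no other accumulation target aliases, so first assignment is free.
        if self.grad is None:
            if grad.dtype != np.float32:
                grad = grad.astype(np.float32)
            self.grad = grad
        elif self.grad.flags.writeable:
            self.grad += grad
        else:
            self.grad = self.grad + grad

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- backprop -------------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this (typically scalar) node."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph to bound memory
                if node._parents:
                    node.grad = None
        # leaves keep their grads; clear tape references
        for node in topo:
            node._backward = None
            node._parents = ()

    # -- arithmetic -----------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                gb = _unbroadcast(g, b.data.shape)
                if gb is g and a.requires_grad and a is not b:
                    gb = g.copy()  # avoid two targets aliasing one buffer
                b._accumulate(gb)

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        a = self

        def bwd(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other) -> "Tensor":
        return self._coerce(other) / self

    def __pow__(self, p: float) -> "Tensor":
        a = self
        out_data = a.data ** np.float32(p)

        def bwd(g):
            a._accumulate(g * np.float32(p) * a.data ** np.float32(p - 1))

        return Tensor._make(out_data, (a,), bwd)

    def __matmul__(self, other) -> "Tensor":
        other = self._coerce(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bwd)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self) -> "Tensor":
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self) -> "Tensor":
        a = self

        def bwd(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def tanh(self) -> "Tensor":
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accumulate(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (a,), bwd)

    def sigmoid(self) -> "Tensor":
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

        return Tensor._make(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * np.float32(1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            a._accumulate(g.reshape(a.data.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes) -> "Tensor":
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            a._accumulate(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    def swapaxes(self, ax1: int, ax2: int) -> "Tensor":
        a = self

        def bwd(g):
            a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), bwd)

    def __getitem__(self, key) -> "Tensor":
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, key, g)
            a._accumulate(full)

        return Tensor._make(a.data[key], (a,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, bwd)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup `weight[ids]` with scatter-add backward."""
    ids = np.asarray(ids)
    w = weight

    def bwd(g):
        full = np.zeros_like(w.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, w.data.shape[-1]))
        w._accumulate(full)

    return Tensor._make(w.data[ids], (w,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    a = x
    z = a.data - a.data.max(axis=axis, keepdims=True)
    # clip far-negative (masked) scores: avoids denormal-heavy exp while
    # keeping masked weights at ~1e-22, numerically zero for attention
    np.maximum(z, -50.0, out=z)
    e = np.exp(z, out=z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accumulate(out_data * (g - dot))

    return Tensor._make(out_data, (a,), bwd)


def layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance (no affine)."""
    a = x
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    n = a.data.shape[-1]

    def bwd(g):
        gm = g.mean(axis=-1, keepdims=True)
        gxhat = (g * xhat).mean(axis=-1, keepdims=True)
        a._accumulate(inv * (g - gm - xhat * gxhat))

    return Tensor._make(xhat, (a,), bwd)


_SQRT_2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit, exact (erf) form."""
    a = x
    cdf = 0.5 * (1.0 + _erf(a.data / _SQRT_2))
    out_data = (a.data * cdf).astype(np.float32)

    def bwd(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data * a.data)
        a._accumulate(g * (cdf + a.data * pdf))

    return Tensor._make(out_data, (a,), bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable in the logit."""
    a = logits
    t = _as_array(targets)
    z = a.data
    # log(1 + exp(-|z|)) + max(z, 0) - z*t
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = loss.size
    out_data = np.float32(loss.mean())

    def bwd(g):
        p = 1.0 / (1.0 + np.exp(-z))
        a._accumulate((g * (p - t) / n).astype(np.float32))

    return Tensor._make(out_data, (a,), bwd)
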