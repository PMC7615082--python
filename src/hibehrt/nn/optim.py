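"""Optimizers: Adam (fine-tuning / supervised) and SGD with momentum
(self-supervised pre-training), both over lists of parameter tensors."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "SGD"]


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(np.float32)


class SGD:
    """Momentum SGD with optional weight decay and per-group LR scaling.

    `lr_scales` lets one parameter group (e.g. a self-distillation
    predictor) train faster than the rest under a single schedule.
    """

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 momentum: float = 0.9, weight_decay: float = 0.0,
                 lr_scales: list[float] | None = None):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.lr_scales = (list(lr_scales) if lr_scales is not None
                          else [1.0] * len(self.params))
        if len(self.lr_scales) != len(self.params):
            raise ValueError("lr_scales length must match params")
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p, b, s in zip(self.params, self.buf, self.lr_scales):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            b *= self.momentum
            b += g
            p.data -= (self.lr * s * b).astype(np.float32)
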