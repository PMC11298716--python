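"""Adam optimiser with L2 weight decay and a cosine-annealed learning rate."""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = ["Adam", "cosine_lr"]


def cosine_lr(t: int, total: int, base_lr: float, floor: float = 1e-7) -> float:
    """Cosine annealing from ``base_lr`` at t=0 to ``floor`` at t=total."""
    if total <= 0:
        raise ValueError("total iterations must be positive")
    frac = min(max(t, 0), total) / total
    return floor + 0.5 * (base_lr - floor) * (1.0 + math.cos(math.pi * frac))


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
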