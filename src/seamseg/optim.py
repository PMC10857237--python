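"""Optimizers."""

from __future__ import annotations

import numpy as np

from .nn import Parameter


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay.

    Update rule (per parameter p with gradient g):
        v <- momentum * v + (g + weight_decay * p)
        p <- p - lr * v
    """

    def __init__(self, params: list[Parameter], lr: float = 0.001,
                 momentum: float = 0.9, weight_decay: float = 0.0001):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
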