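"""Nesterov-momentum SGD with polynomial learning-rate decay."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["NesterovSGD", "poly_lr"]


def poly_lr(base_lr: float, iteration: int, max_iterations: int,
            power: float = 0.9) -> float:
    """base_lr * (1 - it/max_it)**power, clipped at a small positive floor."""
    frac = 1.0 - iteration / max_iterations
    return base_lr * max(frac, 1e-4) ** power


class NesterovSGD:
    """SGD with Nesterov momentum and decoupled-into-gradient weight decay.

    Update (per parameter p with gradient g):
        d = g + weight_decay * p
        v = momentum * v + d
        p -= lr * (d + momentum * v)
    """

    def __init__(self, params: list[Param], lr: float = 0.01,
                 momentum: float = 0.99, weight_decay: float = 3e-5):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        for p in self.params:
            p.momentum = np.zeros_like(p.value)

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        mu, wd = self.momentum, self.weight_decay
        for p in self.params:
            d = p.grad + wd * p.value
            p.momentum = mu * p.momentum + d
            p.value -= np.float32(lr) * (d + mu * p.momentum)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
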