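"""Adam optimizer and reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Param


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class ReduceLROnPlateau:
    """Multiply the optimizer's learning rate by ``factor`` after
    ``patience`` epochs without improvement of the monitored loss."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 20, eps: float = 1e-9):
        if not (0.0 < factor < 1.0):
            raise ValueError("factor must lie in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.eps = eps
        self.best = np.inf
        self.num_bad = 0

    def step(self, metric: float) -> bool:
        """Record an epoch's validation metric; returns True when the
        learning rate was just reduced."""
        if metric < self.best - self.eps:
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad >= self.patience:
            self.optimizer.lr *= self.factor
            self.num_bad = 0
            return True
        return False
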