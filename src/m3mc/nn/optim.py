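"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "ReduceLROnPlateau", "StepDecay"]


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        if not self.params:
            raise ValueError("no parameters to optimize")
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the optimizer's learning rate when the monitored
    loss has not improved for ``patience`` consecutive epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 25,
                 min_delta: float = 1e-8):
        if not 0 < factor < 1:
            raise ValueError("factor must be in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> bool:
        """Record an epoch loss; returns True if the rate was reduced."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs > self.patience:
            self.optimizer.lr *= self.factor
            self.bad_epochs = 0
            return True
        return False


class StepDecay:
    """Fixed-step alternative: multiply the rate by ``factor`` every
    ``every`` epochs regardless of the loss."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, every: int = 25):
        self.optimizer = optimizer
        self.factor = factor
        self.every = every
        self.epoch = 0

    def step(self, loss: float | None = None) -> bool:
        self.epoch += 1
        if self.epoch % self.every == 0:
            self.optimizer.lr *= self.factor
            return True
        return False
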