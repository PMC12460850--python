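"""First-order optimizers and the plateau learning-rate scheduler.

All four update rules operate on the autograd parameter list in place.
Hyperparameter defaults follow the training configuration used for the
spectral networks: lr 1e-4, Adam betas (0.9, 0.999), RMSprop decay 0.99.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["make_optimizer", "SGD", "Adam", "RMSprop", "Adadelta",
           "ReduceLROnPlateau"]

_EPS = 1e-7


class _Optimizer:
    def __init__(self, params: list[Tensor], lr: float):
        self.params = params
        self.lr = float(lr)

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is not None:
                self._update(i, p)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def _update(self, i: int, p: Tensor) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(_Optimizer):
    """theta <- theta - lr * g."""

    def _update(self, i, p):
        p.data -= self.lr * p.grad


class RMSprop(_Optimizer):
    """Moving average of squared gradients; decay rate 0.99."""

    def __init__(self, params, lr, decay: float = 0.99):
        super().__init__(params, lr)
        self.decay = decay
        self.v = [np.zeros_like(p.data) for p in params]

    def _update(self, i, p):
        self.v[i] = self.decay * self.v[i] + (1 - self.decay) * p.grad**2
        p.data -= self.lr * p.grad / (np.sqrt(self.v[i]) + _EPS)


class Adam(_Optimizer):
    """Bias-corrected first/second moment updates, betas (0.9, 0.999)."""

    def __init__(self, params, lr, betas: tuple[float, float] = (0.9, 0.999)):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        super().step()

    def _update(self, i, p):
        g = p.grad
        self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
        self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
        mhat = self.m[i] / (1 - self.b1**self.t)
        vhat = self.v[i] / (1 - self.b2**self.t)
        p.data -= self.lr * mhat / (np.sqrt(vhat) + _EPS)


class Adadelta(_Optimizer):
    """Decaying averages of squared gradients and squared updates (rho 0.95)."""

    def __init__(self, params, lr, rho: float = 0.95):
        super().__init__(params, lr)
        self.rho = rho
        self.eg = [np.zeros_like(p.data) for p in params]
        self.ed = [np.zeros_like(p.data) for p in params]

    def _update(self, i, p):
        g = p.grad
        self.eg[i] = self.rho * self.eg[i] + (1 - self.rho) * g**2
        delta = np.sqrt(self.ed[i] + _EPS) / np.sqrt(self.eg[i] + _EPS) * g
        self.ed[i] = self.rho * self.ed[i] + (1 - self.rho) * delta**2
        p.data -= self.lr * delta


_KINDS = {"Adam": Adam, "RMSprop": RMSprop, "SGD": SGD, "Adadelta": Adadelta}


def make_optimizer(name: str, params: list[Tensor], lr: float = 1e-4,
                   **kwargs) -> _Optimizer:
    """Build one of {Adam, RMSprop, SGD, Adadelta} with the study defaults."""
    try:
        cls = _KINDS[name]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; expected one of {sorted(_KINDS)}")
    return cls(params, lr, **kwargs)


class ReduceLROnPlateau:
    """Halve the learning rate after `patience` epochs without improvement.

    Improvement means a validation loss strictly below the best seen.
    The stagnation counter resets on every reduction; lr never drops
    below `min_lr` and is never increased.
    """

    def __init__(self, optimizer: _Optimizer, factor: float = 0.5,
                 patience: int = 5, min_lr: float = 1e-6):
        if not 0 < factor < 1:
            raise ValueError("factor must lie in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.stale = 0
        self.n_reductions = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, val_loss: float) -> None:
        if val_loss < self.best:
            self.best = float(val_loss)
            self.stale = 0
            return
        self.stale += 1
        if self.stale >= self.patience:
            self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
            self.n_reductions += 1
            self.stale = 0
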