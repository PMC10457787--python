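"""Adam optimizer and reduce-on-plateau learning-rate scheduling."""

from __future__ import annotations

import numpy as np

from .modules import Parameter

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    """First-order adaptive-moment optimizer with decoupled-from-graph L2
    weight decay added to the raw gradient (classic Adam + weight decay)."""

    def __init__(self, params: list[Parameter], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data - self.lr * update).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate when the monitored loss fails
    to improve by a relative ``threshold`` for ``patience`` epochs.

    With a loss held constant, the first reduction fires on the
    (patience + 1)-th recorded epoch: epoch 1 sets the best value and
    epochs 2..patience+1 count as stalled.
    """

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 threshold: float = 1e-4, min_lr: float = 0.0):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.min_lr = min_lr
        self.best = np.inf
        self.num_bad = 0

    @property
    def lr(self) -> float:
        return self.optimizer.lr

    def step(self, metric: float) -> None:
        if metric < self.best * (1.0 - self.threshold):
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad >= self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor,
                                        self.min_lr)
                self.num_bad = 0
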