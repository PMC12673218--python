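"""Optimisers: SGD with momentum and staircase exponential decay, and Adam."""

from __future__ import annotations

import numpy as np


class SGDMomentum:
    """SGD with classical momentum and optional staircase exponential LR decay.

    ``lr(epoch) = lr0 * decay ** floor(epoch / decay_every)`` when staircase,
    else ``lr0 * decay ** (epoch / decay_every)``.
    """

    def __init__(self, net, lr: float = 1e-4, momentum: float = 0.5,
                 decay: float = 0.94, staircase: bool = True, decay_every: int = 10):
        self.net = net
        self.lr0 = lr
        self.momentum = momentum
        self.decay = decay
        self.staircase = staircase
        self.decay_every = decay_every
        self._velocity: list[np.ndarray] | None = None
        self.lr = lr

    def set_epoch(self, epoch: int) -> None:
        e = epoch / self.decay_every
        if self.staircase:
            e = np.floor(e)
        self.lr = self.lr0 * self.decay ** e

    def step(self) -> None:
        pairs = self.net.trainable()
        if self._velocity is None:
            self._velocity = [np.zeros_like(p) for p, _ in pairs]
        for v, (p, g) in zip(self._velocity, pairs):
            v *= self.momentum
            v -= self.lr * g
            p += v


class Adam:
    def __init__(self, net, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None
        self._t = 0

    def set_epoch(self, epoch: int) -> None:  # Adam uses a constant step size
        pass

    def step(self) -> None:
        pairs = self.net.trainable()
        if self._m is None:
            self._m = [np.zeros_like(p) for p, _ in pairs]
            self._v = [np.zeros_like(p) for p, _ in pairs]
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1 ** self._t
        corr2 = 1 - b2 ** self._t
        for m, v, (p, g) in zip(self._m, self._v, pairs):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
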