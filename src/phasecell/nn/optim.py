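"""Parameter-update rules (SGD with momentum, Adam)."""

from __future__ import annotations

import numpy as np

from .core import Param


class Optimizer:
    def __init__(self, params: list[Param]):
        self.params = params

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:  # pragma: no cover
        raise NotImplementedError


class SGD(Optimizer):
    """SGD with classical momentum and decoupled-into-gradient weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        super().__init__(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._vel):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v


class Adam(Optimizer):
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        c1 = 1 - b1 ** self._t
        c2 = 1 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
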