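"""AdaDelta optimizer (Zeiler 2012), the optimizer used for all training runs.

`rho` and `learning_rate` are the study-level knobs; `eps` floors both
accumulators and controls how fast updates warm up from zero.  Parameters
with ``trainable = False`` (a frozen backbone) are skipped entirely, so their
values and optimizer state never change.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter

__all__ = ["AdaDelta"]


class AdaDelta:
    def __init__(self, params: list[Parameter], learning_rate: float = 0.005,
                 rho: float = 0.975, eps: float = 1e-6):
        self.params = list(params)
        self.lr, self.rho, self.eps = learning_rate, rho, eps
        self._eg = [np.zeros_like(p.data) for p in self.params]
        self._ed = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None or not getattr(p, "trainable", True):
                continue
            g = p.grad
            self._eg[i] = self.rho * self._eg[i] + (1 - self.rho) * g * g
            dx = np.sqrt(self._ed[i] + self.eps) / np.sqrt(self._eg[i] + self.eps) * g
            self._ed[i] = self.rho * self._ed[i] + (1 - self.rho) * dx * dx
            p.data -= self.lr * dx
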