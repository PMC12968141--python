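"""Adam optimizer over autodiff tensors (Kingma & Ba moment estimates)."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam"]


class Adam:
    """First-order optimizer with bias-corrected moment estimates.

    Defaults (lr 1e-3, betas 0.9/0.999, eps 1e-8) are the standard ones and
    the ones used throughout the package's experiments.
    """

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data = p.data - self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
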