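"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "cosine_schedule"]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_schedule(lr0: float, lr_min: float, total_steps: int):
    """Return step -> lr implementing cosine decay from lr0 to lr_min."""

    def lr_at(step: int) -> float:
        if total_steps <= 1:
            return lr0
        frac = min(step, total_steps - 1) / (total_steps - 1)
        return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + np.cos(np.pi * frac))

    return lr_at
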