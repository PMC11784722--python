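"""Optimizers and learning-rate schedules."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "linear_lr"]


class Adam:
    """Adam with optional decoupled weight decay (off by default)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                p.data *= (1 - self.lr * self.weight_decay)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def linear_lr(lr0: float, final_factor: float, step: int, total_steps: int) -> float:
    """Linear decay from ``lr0`` to ``lr0 * final_factor`` over the run."""
    frac = min(step / max(total_steps - 1, 1), 1.0)
    return lr0 * (1.0 - frac * (1.0 - final_factor))
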