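"""Optimizers and learning-rate schedules for the training phases."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["AdamW", "one_cycle_lr", "constant_lr"]


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-4):
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
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def one_cycle_lr(step: int, total_steps: int, max_lr: float = 1e-3,
                 warmup_frac: float = 0.3, div_factor: float = 25.0,
                 final_div: float = 1e4) -> float:
    """Single-cycle schedule: linear warm-up then cosine anneal."""
    warm = max(1, int(total_steps * warmup_frac))
    if step < warm:
        lo = max_lr / div_factor
        return lo + (max_lr - lo) * step / warm
    frac = (step - warm) / max(1, total_steps - warm)
    lo = max_lr / final_div
    return lo + (max_lr - lo) * 0.5 * (1 + math.cos(math.pi * min(frac, 1.0)))


def constant_lr(step: int, total_steps: int, lr: float = 1e-4) -> float:
    return lr
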