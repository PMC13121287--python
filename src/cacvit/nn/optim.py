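"""Optimizers and learning-rate schedules for the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Adam", "AdamW", "cosine_schedule"]


class Adam:
    """Adam with optional L2-coupled weight decay (set decoupled=False)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decoupled: bool = False):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            update = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and self.decoupled:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class AdamW(Adam):
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.04):
        super().__init__(params, lr=lr, betas=betas, eps=eps,
                         weight_decay=weight_decay, decoupled=True)


def cosine_schedule(base: float, final: float, total_steps: int,
                    warmup_steps: int = 0, warmup_start: float = 0.0) -> np.ndarray:
    """Per-step values: linear warmup then cosine decay from base to final."""
    if total_steps <= 0:
        return np.array([])
    warmup_steps = min(warmup_steps, total_steps)
    warm = np.linspace(warmup_start, base, warmup_steps, endpoint=False)
    n = total_steps - warmup_steps
    if n > 0:
        t = np.arange(n) / max(n - 1, 1)
        decay = final + 0.5 * (base - final) * (1 + np.cos(np.pi * t))
    else:
        decay = np.array([])
    return np.concatenate([warm, decay])
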