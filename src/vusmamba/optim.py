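"""AdamW with a warmup-cosine learning-rate schedule.

Defaults follow the training protocol used throughout the package:
lr 1e-3, weight decay 0.1 (decoupled), betas (0.9, 0.999).
"""

from __future__ import annotations

import math
from typing import List

import numpy as np

from .autodiff import Tensor


def warmup_cosine_lr(step: int, total_steps: int, base_lr: float,
                     warmup_fraction: float = 0.1, min_lr: float = 0.0) -> float:
    """Linear warmup to ``base_lr`` then cosine decay to ``min_lr``."""
    if total_steps <= 0:
        return base_lr
    warmup = max(int(round(warmup_fraction * total_steps)), 0)
    if warmup and step < warmup:
        return base_lr * (step + 1) / warmup
    denom = max(total_steps - warmup, 1)
    progress = min((step - warmup) / denom, 1.0)
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + math.cos(math.pi * progress))


class AdamW:
    def __init__(self, params: List[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.1):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
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
            if lr != 0.0:
                p.data -= lr * self.weight_decay * p.data  # decoupled decay
                p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
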