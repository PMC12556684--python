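"""AdamW with decoupled weight decay, gradient clipping, poly LR schedule."""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW", "clip_grad_norm", "poly_lr"]


def poly_lr(epoch: int, cfg) -> float:
    """``base_lr * (1 - epoch/epochs) ** lr_exponent``; strictly decreasing."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} out of range [0, {cfg.epochs})")
    return float(cfg.base_lr * (1.0 - epoch / cfg.epochs) ** cfg.lr_exponent)


def clip_grad_norm(grads: list[np.ndarray], max_norm: float) -> float:
    total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale
    return total


class AdamW:
    def __init__(self, params: list[np.ndarray], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 3e-5):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g64 = g.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g64
            v *= self.b2
            v += (1 - self.b2) * g64**2
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p -= (self.lr * (update + self.weight_decay * p.astype(np.float64))).astype(p.dtype)
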