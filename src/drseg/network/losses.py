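"""Compound Dice + cross-entropy loss with analytic logit gradients."""

from __future__ import annotations

import numpy as np

from .unet import softmax

__all__ = ["dice_ce_loss", "dice_ce_components", "dice_ce_grad_logits"]

EPS = 1e-5


def _as_class_array(target) -> np.ndarray:
    data = getattr(target, "data", target)
    return np.asarray(data)


def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    if target.max() >= n_classes or target.min() < 0:
        raise ValueError("target class indices out of range")
    oh = np.zeros((n_classes,) + target.shape, dtype=np.float32)
    for c in range(n_classes):
        oh[c] = target == c
    return oh


def dice_ce_components(
    probs: np.ndarray, target, eps: float = EPS
) -> tuple[float, float]:
    """(soft-Dice loss, cross-entropy loss) for per-class probabilities.

    ``probs`` is ``(C, ...)`` or ``(N, C, ...)`` and must sum to 1 per voxel;
    ``target`` holds class indices on the matching grid.  Dice is
    batch-summed per class (background included) with ``eps`` smoothing in
    numerator and denominator; cross-entropy is the voxel mean.
    """
    probs = np.asarray(probs, dtype=np.float64)
    t = _as_class_array(target)
    if probs.ndim != t.ndim + 1:
        raise ValueError(f"probs shape {probs.shape} incompatible with target {t.shape}")
    if probs.shape[1:] == t.shape:  # (C, ...) vs (...)
        caxis = 0
        n_classes = probs.shape[0]
        pm = probs.reshape(n_classes, -1)
    elif probs.shape[0] == t.shape[0] and probs.shape[2:] == t.shape[1:]:
        caxis = 1  # batched: (N, C, ...) vs (N, ...)
        n_classes = probs.shape[1]
        pm = np.moveaxis(probs, 1, 0).reshape(n_classes, -1)
    else:
        raise ValueError(f"probs shape {probs.shape} incompatible with target {t.shape}")
    if pm.shape[1] != t.size:
        raise ValueError("probability grid does not match target grid")
    if not np.allclose(probs.sum(axis=caxis), 1.0, atol=1e-4):
        raise ValueError("probabilities must sum to 1 per voxel")

    oh = _one_hot(t.reshape(-1), n_classes)  # (C, V)
    inter = (pm * oh).sum(axis=1)
    denom = pm.sum(axis=1) + oh.sum(axis=1)
    dice_per_class = (2 * inter + eps) / (denom + eps)
    dice_loss = float(1.0 - dice_per_class.mean())

    p_true = pm[t.reshape(-1), np.arange(t.size)]
    ce = float(-np.log(np.clip(p_true, 1e-12, None)).mean())
    return dice_loss, ce


def dice_ce_loss(probs: np.ndarray, target, eps: float = EPS) -> float:
    """Sum of the soft-Dice and cross-entropy losses (always >= 0)."""
    d, c = dice_ce_components(probs, target, eps)
    return d + c


def dice_ce_grad_logits(
    logits: np.ndarray, target: np.ndarray, eps: float = EPS
) -> tuple[float, float, float, np.ndarray]:
    """Loss and gradient w.r.t. logits for a batched (N, C, ...) prediction.

    Returns ``(total, dice_term, ce_term, dloss/dlogits)``.
    """
    probs = softmax(logits.astype(np.float64), axis=1)
    n, C = logits.shape[:2]
    V = int(np.prod(logits.shape)) // C
    pm = np.moveaxis(probs, 1, 0).reshape(C, -1)
    t = np.asarray(target).reshape(-1)
    oh = _one_hot(t, C)

    inter = (pm * oh).sum(axis=1)
    denom = pm.sum(axis=1) + oh.sum(axis=1)
    num = 2 * inter + eps
    den = denom + eps
    dice_loss = float(1.0 - (num / den).mean())
    ce = float(-np.log(np.clip(pm[t, np.arange(V)], 1e-12, None)).mean())

    # d(dice_loss)/dp_{c,v} = -(1/C) * (2*oh - num/den) / den
    gdice = -(2 * oh - (num / den)[:, None]) / den[:, None] / C
    # chain through softmax: gz = p * (gp - sum_c gp_c p_c)
    dot = (gdice * pm).sum(axis=0, keepdims=True)
    gz_dice = pm * (gdice - dot)
    gz_ce = (pm - oh) / V
    gz = (gz_dice + gz_ce).reshape((C,) + (n,) + logits.shape[2:])
    gz = np.moveaxis(gz, 0, 1)
    return dice_loss + ce, dice_loss, ce, gz.astype(np.float32)
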