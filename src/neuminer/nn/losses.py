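"""Segmentation losses with hand-written gradients.

Each head of the network is trained with soft dice plus cross-entropy over
a 2-channel softmax. The FNM weight map multiplies the per-voxel
cross-entropy only: dice is a set-overlap statistic, not a per-voxel loss,
so it is left unweighted by default (a weighted-dice variant exists behind
a flag). Deep supervision sums the per-head losses with fixed head weights;
the auxiliary head is compared against a max-pooled label so single-voxel
fibers survive the downsampling.
"""

from __future__ import annotations

import numpy as np

from ..fnm import extract_false_negatives, build_weight_map, DEFAULT_WFN

__all__ = ["softmax", "dice_loss", "cross_entropy_map", "head_loss",
           "deep_supervision_loss", "maxpool_label"]

_EPS = 1e-5
_CLIP = 1e-12


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def dice_loss(p: np.ndarray, f: np.ndarray, eps: float = _EPS,
              weights: np.ndarray | None = None) -> float:
    """Soft dice loss 1 - (2*sum(p*f)+eps) / (sum(p)+sum(f)+eps)."""
    p = np.asarray(p, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    if p.shape != f.shape:
        raise ValueError("prediction and label shapes differ")
    w = np.ones_like(p) if weights is None else np.asarray(weights, np.float64)
    inter = (w * p * f).sum()
    denom = (w * p).sum() + (w * f).sum()
    return float(1.0 - (2.0 * inter + eps) / (denom + eps))


def _dice_grad(p, f, eps=_EPS, weights=None):
    p = np.asarray(p, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    w = np.ones_like(p) if weights is None else np.asarray(weights, np.float64)
    inter = (w * p * f).sum()
    denom = (w * p).sum() + (w * f).sum() + eps
    num = 2.0 * inter + eps
    return -(2.0 * w * f * denom - num * w) / denom**2


def cross_entropy_map(probs: np.ndarray, label: np.ndarray) -> np.ndarray:
    """Per-voxel 2-class cross-entropy -log p_true, shape (B, 1, Z, Y, X)."""
    p1 = probs[:, 1]
    p_true = np.where(label > 0, p1, 1.0 - p1)
    return -np.log(np.clip(p_true, _CLIP, None))[:, None]


def head_loss(logits: np.ndarray, label: np.ndarray,
              wfn: float = DEFAULT_WFN, use_fnm: bool = True,
              weighted_dice: bool = False):
    """Dice + (FNM-weighted) cross-entropy for one head.

    Parameters
    ----------
    logits : (B, 2, Z, Y, X) raw head output.
    label : (B, Z, Y, X) binary foreground.

    Returns ``(total, dlogits, stats)`` where stats carries the dice and
    cross-entropy components and the number of mined false negatives.
    """
    if logits.ndim != 5 or logits.shape[1] != 2:
        raise ValueError("logits must be (B, 2, Z, Y, X)")
    label = np.asarray(label)
    if label.shape != logits.shape[:1] + logits.shape[2:]:
        raise ValueError("label shape must match logits spatial shape")
    probs = softmax(logits.astype(np.float64), axis=1)
    p1 = probs[:, 1]
    f = (label > 0).astype(np.float64)

    if use_fnm:
        fn = extract_false_negatives(f, p1)
        w = build_weight_map(fn, wfn).astype(np.float64)
    else:
        fn = np.zeros_like(f, dtype=bool)
        w = np.ones_like(f)

    ce_map = cross_entropy_map(probs, f)  # (B,1,Z,Y,X)
    n = ce_map.size
    ce = float(np.mean(w[:, None] * ce_map))
    dice_w = w if weighted_dice else None
    dice = dice_loss(p1, f, weights=dice_w)
    total = dice + ce

    # gradients w.r.t. logits ------------------------------------------
    onehot = np.stack([1.0 - f, f], axis=1)
    g_ce = (w[:, None] * (probs - onehot)) / n
    g_p1 = _dice_grad(p1, f, weights=dice_w)
    jac = p1 * (1.0 - p1)  # 2-class softmax jacobian wrt (z1 - z0)
    g_dice = np.stack([-g_p1 * jac, g_p1 * jac], axis=1)
    dlogits = (g_ce + g_dice).astype(logits.dtype, copy=False)
    stats = {"dice": dice, "ce": ce, "n_fn": int(fn.sum())}
    return total, dlogits, stats


def maxpool_label(label: np.ndarray, factor: int) -> np.ndarray:
    """Downsample a binary (B, Z, Y, X) label by block maximum."""
    if factor == 1:
        return label
    b, d, h, w = label.shape
    lr = label.reshape(b, d // factor, factor, h // factor, factor,
                       w // factor, factor)
    return lr.max(axis=(2, 4, 6))


def deep_supervision_loss(outputs, label, head_weights=(1.0, 0.5),
                          wfn: float = DEFAULT_WFN, use_fnm: bool = True,
                          weighted_dice: bool = False):
    """Weighted sum of per-head dice + FNM-weighted cross-entropy.

    ``outputs`` is (final_logits, aux_logits); the auxiliary head is scored
    against a max-pooled copy of ``label`` at its own resolution, with its
    own on-the-fly FN mask.

    Returns ``(total, grads, stats)``: ``grads`` aligns with ``outputs``
    and already includes the head weights.
    """
    if len(outputs) != len(head_weights):
        raise ValueError("need one weight per head")
    total = 0.0
    grads, stats = [], []
    full = label.shape[-1]
    for logits, hw in zip(outputs, head_weights):
        factor = full // logits.shape[-1]
        lab = maxpool_label(label, factor)
        loss, g, st = head_loss(logits, lab, wfn=wfn, use_fnm=use_fnm,
                                weighted_dice=weighted_dice)
        total += hw * loss
        grads.append(np.float32(hw) * g)
        st["weight"] = hw
        stats.append(st)
    return float(total), grads, stats
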