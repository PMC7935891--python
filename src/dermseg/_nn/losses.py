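"""Loss functions returning (scalar loss, gradient w.r.t. logits).

Working in logit space keeps the sigmoid/softmax + loss combination
numerically stable; the layers' final activation is applied here.
"""

from __future__ import annotations

import numpy as np

from .layers import sigmoid, softmax

_EPS = 1e-7


def bce_with_logits(logits, targets):
    """Pixelwise binary cross-entropy. targets in {0,1}, same shape."""
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    # log(1 + exp(z)) computed stably
    loss = np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z))))
    p = sigmoid(z)
    grad = ((p - t) / z.size).astype(np.float32)
    return float(loss), grad


def dice_loss_with_logits(logits, targets, smooth=1.0):
    """Soft Dice loss, 1 - 2*sum(p*t)/(sum(p)+sum(t)), per batch."""
    p = sigmoid(logits.astype(np.float64))
    t = targets.astype(np.float64)
    inter = (p * t).sum()
    denom = p.sum() + t.sum() + smooth
    dice = (2.0 * inter + smooth) / denom
    # d dice / d p, then chain through sigmoid
    ddice_dp = 2.0 * t / denom - (2.0 * inter + smooth) / denom ** 2
    grad = (-ddice_dp * p * (1.0 - p)).astype(np.float32)
    return float(1.0 - dice), grad


def cce_with_logits(logits, labels):
    """Categorical cross-entropy. labels: int array (n,)."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), labels] + _EPS))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


def focal_loss_with_logits(logits, labels, gamma=2.0):
    """Multiclass focal loss, -(1-p_t)^gamma log p_t."""
    p = softmax(logits.astype(np.float64))
    n, k = p.shape
    idx = np.arange(n)
    pt = np.clip(p[idx, labels], _EPS, 1.0)
    loss = float(np.mean((1.0 - pt) ** gamma * (-np.log(pt))))
    # dL/dpt, then dpt/dz_j = pt*(delta_tj - p_j)
    dl_dpt = gamma * (1.0 - pt) ** (gamma - 1) * np.log(pt) - (1.0 - pt) ** gamma / pt
    grad = -p * (dl_dpt * pt)[:, None]
    grad[idx, labels] += dl_dpt * pt
    return loss, (grad / n).astype(np.float32)


SEGMENTATION_LOSSES = {
    "bce": bce_with_logits,
    "binary_cross_entropy": bce_with_logits,
    "dice": dice_loss_with_logits,
    "dice_loss": dice_loss_with_logits,
}

CLASSIFICATION_LOSSES = {
    "cce": cce_with_logits,
    "categorical_cross_entropy": cce_with_logits,
    "focal": focal_loss_with_logits,
    "focal_loss": focal_loss_with_logits,
}
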