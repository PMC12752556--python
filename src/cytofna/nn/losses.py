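"""Loss functions returning (scalar loss, gradient w.r.t. logits)."""

from __future__ import annotations

import numpy as np

__all__ = ["sigmoid", "bce_dice_loss", "softmax", "softmax_cross_entropy"]


def sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_dice_loss(logits: np.ndarray, targets: np.ndarray, eps: float = 1.0):
    """Equal-weight sum of pixel binary cross-entropy and soft Dice loss.

    ``logits`` and ``targets`` share shape; targets are {0,1} floats.
    """
    p = sigmoid(logits)
    n = logits.size
    # numerically stable BCE in terms of logits
    bce = np.mean(np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits))))
    inter = float((p * targets).sum())
    denom = float(p.sum() + targets.sum())
    dice = 1.0 - (2.0 * inter + eps) / (denom + eps)
    # gradients
    dbce = (p - targets) / n
    ddice_dp = -(2.0 * targets * (denom + eps) - (2.0 * inter + eps)) / (denom + eps) ** 2
    ddice = ddice_dp * p * (1.0 - p)
    return float(bce + dice), (dbce + ddice).astype(np.float32)


def softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch; labels are integer class ids."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-12)))
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, (d / n).astype(np.float32)
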