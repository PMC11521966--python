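"""Loss functions returning (scalar loss, gradient w.r.t. logits)."""

from __future__ import annotations

import numpy as np


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over a batch of class logits.

    ``labels`` are integer class indices.  Returns the loss and its
    gradient with respect to the logits.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    dz = p.copy()
    dz[np.arange(n), labels] -= 1.0
    return loss, (dz / n).astype(np.float32)


def sigmoid(z):
    # clipped for float32 safety; saturation beyond |60| is exact to 1 ulp
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


def soft_dice_terms(p: np.ndarray, target: np.ndarray, smooth: float = 1.0):
    """Per-channel soft Dice loss terms and their dp gradient.

    ``p`` are probabilities in [0, 1], ``target`` binary, both NHWC
    (N, H, W, C).  Sums are aggregated over the batch and both spatial
    axes, so sparse channels (narrow event bands) keep a well-conditioned
    denominator even when individual samples carry no positive pixels.
    The Dice loss of a channel is
    ``1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s)``; with ``smooth == 0``
    an empty-vs-empty channel counts as a perfect match.
    """
    axes = (0, 1, 2)  # aggregate over batch and space, keep channels
    inter = (p * target).sum(axis=axes)
    sp = p.sum(axis=axes)
    st = target.sum(axis=axes)
    denom = sp + st + smooth
    num = 2.0 * inter + smooth
    safe = denom > 0
    dice = np.where(safe, 1.0 - num / np.where(safe, denom, 1.0), 0.0)
    # d dice / dp = -(2t*denom - num) / denom^2
    denom_sq = np.where(safe, denom, 1.0) ** 2
    dp = np.where(
        safe[None, None, None, :],
        -(2.0 * target * denom[None, None, None, :] - num[None, None, None, :])
        / denom_sq[None, None, None, :],
        0.0,
    )
    return dice, dp


def bce_loss(logits: np.ndarray, target: np.ndarray):
    """Numerically stable per-pixel binary cross-entropy and its gradient.

    Unlike overlap losses, its gradient on positive target pixels does not
    vanish when a channel's sigmoid saturates toward zero — which makes it
    the standard stabilizer for rare-class channels.
    """
    z = logits
    loss = np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))
    n = z.size
    dz = (sigmoid(z) - target) / n
    return float(loss.mean()), dz.astype(np.float32)


def dice_f1_loss(
    pred_logits: np.ndarray,
    target: np.ndarray,
    w_dice: float = 0.5,
    w_f1: float = 0.5,
    smooth: float = 1.0,
    from_logits: bool = True,
):
    """Combined soft Dice + soft F1 segmentation loss.

    For binary masks the soft F1 score ``2TP / (2TP + FP + FN)`` equals the
    soft Dice coefficient ``2|P∩T| / (|P| + |T|)`` algebraically, so the two
    terms coincide; both are kept with configurable weights so the
    combination is explicit.  Inputs are NHWC.  Returns the scalar loss
    averaged over samples and channels and, when ``from_logits``, its
    gradient w.r.t. the logits.
    """
    if pred_logits.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred_logits.shape} vs {target.shape}")
    p = sigmoid(pred_logits) if from_logits else np.asarray(pred_logits, dtype=float)
    dice, dp_dice = soft_dice_terms(p, target, smooth)
    # soft F1 term: identical functional form for binary targets
    f1, dp_f1 = dice, dp_dice
    per_channel = w_dice * dice + w_f1 * f1
    loss = float(per_channel.mean())
    n_terms = dice.size
    dp = (w_dice * dp_dice + w_f1 * dp_f1) / n_terms
    if from_logits:
        dz = dp * p * (1.0 - p)
        return loss, dz.astype(np.float32)
    return loss, dp
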