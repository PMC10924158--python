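"""Segmentation losses: binary cross-entropy, soft Dice, and their mix.

All losses take a binary truth slice s^t and a predicted probability
slice s^p of the same shape and return a scalar:

* BCE:   -(1/N) sum[ s^t log s^p + (1 - s^t) log(1 - s^p) ]
* Dice:  1 - 2 sum(s^t s^p) / (sum s^t + sum s^p)
* Combined: lambda * BCE + (1 - lambda) * Dice

The companion ``*_grad_z`` functions return the analytic gradient with
respect to the pre-sigmoid logits, which is what the training loop
back-propagates (folding the sigmoid into the loss keeps BCE gradients
exact even at saturated probabilities).
"""

from __future__ import annotations

import numpy as np

EPS = 1e-7
DICE_SMOOTH = 1.0


def _validate(truth: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape} vs pred {pred.shape}")
    return truth, pred


def bce_loss(truth: np.ndarray, pred: np.ndarray) -> float:
    """Mean binary cross-entropy; predictions clipped to [eps, 1-eps]."""
    t, p = _validate(truth, pred)
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def dice_loss(truth: np.ndarray, pred: np.ndarray) -> float:
    """Soft Dice loss in [0, 1]; 0 on an exactly-matching empty pair."""
    t, p = _validate(truth, pred)
    num = 2.0 * float((t * p).sum())
    den = float(t.sum() + p.sum())
    if den == 0.0:
        num += DICE_SMOOTH
        den += DICE_SMOOTH
    return float(1.0 - num / den)


def combined_loss(truth: np.ndarray, pred: np.ndarray, lam: float) -> float:
    """lambda-weighted mix: lam * BCE + (1 - lam) * Dice."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam * bce_loss(truth, pred) + (1.0 - lam) * dice_loss(truth, pred)


# --- gradients w.r.t. pre-sigmoid logits (p = sigmoid(z)) ---------------


def bce_grad_z(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    t, p = _validate(truth, pred)
    return (p - t) / t.size


def dice_grad_z(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    t, p = _validate(truth, pred)
    den = float(t.sum() + p.sum())
    if den == 0.0:
        return np.zeros_like(p)
    num = 2.0 * float((t * p).sum())
    dl_dp = -2.0 * t / den + num / den**2
    return dl_dp * p * (1.0 - p)


def combined_grad_z(truth: np.ndarray, pred: np.ndarray, lam: float) -> np.ndarray:
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return lam * bce_grad_z(truth, pred) + (1.0 - lam) * dice_grad_z(truth, pred)


def loss_and_grad(name: str, lam: float):
    """Resolve a loss name to (loss_fn(t, p), grad_z_fn(t, p)) callables."""
    if name == "bce":
        return bce_loss, bce_grad_z
    if name == "dice":
        return dice_loss, dice_grad_z
    if name == "combined":
        return (
            lambda t, p: combined_loss(t, p, lam),
            lambda t, p: combined_grad_z(t, p, lam),
        )
    raise ValueError(f"unknown loss {name!r}; expected bce, dice, or combined")
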