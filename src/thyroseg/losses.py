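"""Training objective: weighted cross-entropy + soft dice.

The total loss is L_total = L_wce + L_dice.

* L_wce is the standard per-pixel weighted cross-entropy with a weighted
  mean reduction: sum over pixels of w[y] * (-log softmax(logits)[y]),
  divided by the sum of the applied weights w[y].
* L_dice sums, over the batch and all C classes (background included),
  1 - (2 * Σ y·p + ε) / (Σ y² + Σ p² + ε) with the inner sums over pixels,
  p the softmax probabilities and y the one-hot target, then averages over
  the batch.  ε (default 1) keeps absent classes well-defined: a class
  missing from both target and prediction contributes 1 - ε/ε = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError
from .nn import functional as F
from .nn.tensor import Tensor


@dataclass
class LossValue:
    wce: Tensor
    dice: Tensor
    total: Tensor


def _prepare(logits, target, class_weights):
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    if logits.ndim != 4:
        raise InputError(f"logits must be (N,C,H,W), got {logits.shape}")
    N, C, H, W = logits.shape
    target = np.asarray(target)
    if target.shape != (N, H, W):
        raise InputError(f"target must be {(N, H, W)}, got {target.shape}")
    if target.min() < 0 or target.max() >= C:
        raise InputError(
            f"target labels must lie in [0,{C}), found range "
            f"[{target.min()},{target.max()}]"
        )
    if class_weights is None:
        class_weights = np.ones(C, dtype=np.float32)
    w = np.asarray(class_weights, dtype=np.float32)
    if w.shape != (C,) or (w <= 0).any():
        raise InputError(f"class_weights must be {C} positive reals")
    onehot = np.zeros((N, C, H, W), dtype=np.float32)
    np.put_along_axis(onehot, target[:, None].astype(np.int64), 1.0, axis=1)
    return logits, target.astype(np.int64), w, onehot


def weighted_cross_entropy(logits, target, class_weights=None) -> Tensor:
    """Weighted multiclass cross-entropy with weighted-mean reduction."""
    logits, target, w, onehot = _prepare(logits, target, class_weights)
    ls = F.log_softmax(logits, axis=1)
    nll = -(ls * Tensor(onehot)).sum(axis=1)  # (N,H,W)
    wmap = w[target]  # (N,H,W) constants
    return (nll * Tensor(wmap)).sum() * (1.0 / float(wmap.sum()))


def dice_loss(
    logits, target, epsilon: float = 1.0, class_weights=None, from_logits: bool = True
) -> Tensor:
    """Soft dice loss over all classes, batch-averaged.

    With ``from_logits=False`` the first argument is taken as per-class
    probabilities directly (e.g. an exact one-hot prediction).
    """
    if epsilon <= 0:
        raise InputError(f"epsilon must be positive, got {epsilon}")
    logits, target, _, onehot = _prepare(logits, target, class_weights)
    N = logits.shape[0]
    p = F.softmax(logits, axis=1) if from_logits else logits
    oh = Tensor(onehot)
    inter = (p * oh).sum(axis=(2, 3))  # (N,C)
    psq = (p * p).sum(axis=(2, 3))
    ysq = Tensor(onehot.sum(axis=(2, 3)))  # y one-hot: y^2 == y
    term = 1.0 - (2.0 * inter + epsilon) / (psq + ysq + epsilon)
    return term.sum() * (1.0 / float(N))


def total_loss(logits, target, class_weights=None, epsilon: float = 1.0) -> LossValue:
    """Combined objective: L_total = L_wce + L_dice."""
    wce = weighted_cross_entropy(logits, target, class_weights)
    dice = dice_loss(logits, target, epsilon, class_weights)
    return LossValue(wce=wce, dice=dice, total=wce + dice)
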