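"""Dice loss and the deeply supervised composite loss.

The per-class soft Dice term is 2*sum(y*p) / (sum(y) + sum(p)) over the
pixels of one image; the loss is one minus the class-average.  A smoothing
constant eps is added to numerator and denominator of every class term so a
class absent from both the labels and the prediction contributes a perfect
score instead of 0/0.  The composite training loss is the weighted sum of
the Dice losses of the four auxiliary coarse maps and the final fused map,
with all five weights defaulting to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .network import PredictionSet
from .nn import Tensor, softmax

__all__ = ["LossWeights", "dice_loss", "deep_supervision_loss", "one_hot"]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the four auxiliary terms and the final term."""

    lambda_aux: tuple = (1.0, 1.0, 1.0, 1.0)
    lambda_final: float = 1.0

    def __post_init__(self):
        if len(self.lambda_aux) != 4:
            raise ConfigurationError(
                f"expected 4 auxiliary weights, got {len(self.lambda_aux)}")
        if any(l < 0 for l in self.lambda_aux) or self.lambda_final < 0:
            raise ConfigurationError("loss weights must be nonnegative")


def one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    """(…) integer label array -> (num_classes, …) or (N, num_classes, …) one-hot.

    A batched input is recognized by ndim == 3 (N, H, W).
    """
    labels = np.asarray(labels)
    eye = np.eye(num_classes, dtype=np.float32)
    oh = eye[labels.astype(int)]  # (..., C)
    if labels.ndim == 3:
        return np.ascontiguousarray(np.moveaxis(oh, -1, 1))
    return np.ascontiguousarray(np.moveaxis(oh, -1, 0))


def _class_axis(y: np.ndarray) -> int:
    # batched maps are (N, C, H, W); unbatched are (C, ...) with class first
    return 1 if y.ndim == 4 else 0


def dice_loss(y, p, eps: float = 1e-5):
    """Soft Dice loss between one-hot labels ``y`` and probabilities ``p``.

    Accepts numpy arrays (returns a float) or autodiff tensors (returns a
    scalar tensor).  Shapes must match; the class axis is axis 1 for 4D
    (batched) input and axis 0 otherwise.  For batched input the per-image
    losses are averaged.
    """
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y)
    p_arr = p.data if isinstance(p, Tensor) else np.asarray(p)
    if y_arr.shape != p_arr.shape:
        raise InvalidInputError(f"shape mismatch: y {y_arr.shape} vs p {p_arr.shape}")

    symbolic = isinstance(p, Tensor) and p.requires_grad
    yt = y if isinstance(y, Tensor) else Tensor(y_arr.astype(p_arr.dtype, copy=False))
    pt = p if isinstance(p, Tensor) else Tensor(p_arr)

    axis = _class_axis(y_arr)
    # reduce over every axis except batch (if present) and class
    reduce_axes = tuple(i for i in range(y_arr.ndim) if i > axis) \
        if axis == 1 else tuple(range(1, y_arr.ndim))
    inter = (yt * pt).sum(axis=reduce_axes)
    denom = yt.sum(axis=reduce_axes) + pt.sum(axis=reduce_axes)
    per_class = (2.0 * inter + eps) / (denom + eps)
    loss = 1.0 - per_class.mean()
    return loss if symbolic else float(loss.data)


def deep_supervision_loss(y, preds: PredictionSet, weights: LossWeights | None = None,
                          eps: float = 1e-5, from_logits: bool = True):
    """Weighted sum of Dice losses over the four auxiliary maps and the final map.

    ``y`` is the one-hot label tensor at full input resolution.  With
    ``from_logits`` (default) a per-pixel softmax converts each map's class
    scores to probabilities first.
    """
    weights = weights or LossWeights()
    maps = preds.maps()
    lambdas = list(weights.lambda_aux) + [weights.lambda_final]
    total = None
    for lam, m in zip(lambdas, maps):
        mt = m if isinstance(m, Tensor) else Tensor(np.asarray(m))
        if from_logits:
            mt = softmax(mt, axis=_class_axis(mt.data))
        term = dice_loss(y, mt, eps=eps)
        term = term if isinstance(term, Tensor) else Tensor(np.asarray(term))
        term = term * float(lam)
        total = term if total is None else total + term
    if isinstance(total, Tensor) and not total.requires_grad:
        return float(total.data)
    return total
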