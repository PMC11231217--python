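"""Training and monitoring losses for probabilistic segmentation maps.

All functions take a predicted probability map and a one-hot truth mask,
both shaped ``(batch, height, width, classes)``, and return a scalar.
Categorical cross-entropy is the training loss; Tversky, focal and
boundary losses are monitored metrics. Tversky, focal and boundary are
standard literature definitions (the asymmetric soft-Dice generalization,
the modulated cross-entropy, and the signed-distance boundary integral
respectively); the defaults are alpha=0.7/beta=0.3 for Tversky and
gamma=2/alpha=0.25 for focal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LossConfig",
    "categorical_crossentropy",
    "soft_dice",
    "tversky_loss",
    "focal_loss",
    "boundary_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Loss hyperparameters.

    ``tversky_alpha`` weights false positives and ``tversky_beta`` false
    negatives (alpha + beta = 1 in the canonical form; 0.5/0.5 recovers
    soft-Dice). ``focal_gamma`` is the focusing exponent, ``focal_alpha``
    the class balance factor. ``smooth`` guards logs and ratios.
    """

    tversky_alpha: float = 0.7
    tversky_beta: float = 0.3
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    smooth: float = 1e-6

    def __post_init__(self):
        if not (0.0 <= self.tversky_alpha <= 1.0 and 0.0 <= self.tversky_beta <= 1.0):
            raise ValueError("tversky_alpha and tversky_beta must lie in [0, 1]")
        if abs(self.tversky_alpha + self.tversky_beta - 1.0) > 1e-9:
            raise ValueError("canonical Tversky requires alpha + beta = 1")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if not 0.0 < self.focal_alpha <= 1.0:
            raise ValueError("focal_alpha must lie in (0, 1]")
        if self.smooth <= 0:
            raise ValueError("smooth must be positive")


def _check_pair(pred: np.ndarray, truth: np.ndarray):
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"pred shape {pred.shape} != truth shape {truth.shape}")
    return pred, truth


def categorical_crossentropy(pred: np.ndarray, truth: np.ndarray,
                             smooth: float = 1e-6) -> float:
    """Mean over pixels of -sum_c t_c log(p_c + smooth)."""
    pred, truth = _check_pair(pred, truth)
    per_pixel = -(truth * np.log(pred + smooth)).sum(axis=-1)
    return float(per_pixel.mean())


def soft_dice(pred: np.ndarray, truth: np.ndarray, smooth: float = 1e-6) -> float:
    """Soft Dice coefficient averaged over classes: 2|PT| / (|P| + |T|)."""
    pred, truth = _check_pair(pred, truth)
    axes = tuple(range(pred.ndim - 1))
    inter = (pred * truth).sum(axis=axes)
    denom = pred.sum(axis=axes) + truth.sum(axis=axes)
    return float(((2.0 * inter + smooth) / (denom + smooth)).mean())


def tversky_loss(pred: np.ndarray, truth: np.ndarray,
                 cfg: LossConfig = LossConfig()) -> float:
    """1 - TP/(TP + alpha*FP + beta*FN) with soft per-class counts.

    alpha = beta = 0.5 reduces exactly to 1 - soft-Dice.
    """
    pred, truth = _check_pair(pred, truth)
    axes = tuple(range(pred.ndim - 1))
    tp = (pred * truth).sum(axis=axes)
    fp = (pred * (1.0 - truth)).sum(axis=axes)
    fn = ((1.0 - pred) * truth).sum(axis=axes)
    index = (tp + cfg.smooth) / (tp + cfg.tversky_alpha * fp + cfg.tversky_beta * fn + cfg.smooth)
    return float(1.0 - index.mean())


def focal_loss(pred: np.ndarray, truth: np.ndarray,
               cfg: LossConfig = LossConfig()) -> float:
    """Mean of -alpha * (1 - p_t)^gamma * log(p_t) over pixels.

    gamma = 0, alpha = 1 recovers categorical cross-entropy.
    """
    pred, truth = _check_pair(pred, truth)
    pt = (pred * truth).sum(axis=-1)
    per_pixel = -cfg.focal_alpha * (1.0 - pt) ** cfg.focal_gamma * np.log(pt + cfg.smooth)
    return float(per_pixel.mean())


def signed_distance_map(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the boundary of a binary mask.

    Negative inside the object, positive outside, zero when the mask is
    empty or full (no boundary to measure against).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or mask.all():
        return np.zeros(mask.shape, dtype=np.float64)
    dist_out = ndimage.distance_transform_edt(~mask)
    dist_in = ndimage.distance_transform_edt(mask)
    return dist_out - dist_in


def boundary_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean over foreground classes of sum(pred_c * SDM(truth_c)) / n_pixels.

    The signed distance map is negative inside the true region, so
    probability mass placed inside the object lowers the loss and mass
    far outside raises it; the value is signed by construction. Class 0
    is treated as background and skipped; an all-empty foreground class
    contributes zero.
    """
    pred, truth = _check_pair(pred, truth)
    n_classes = pred.shape[-1]
    n_pixels = int(np.prod(pred.shape[:-1]))
    total = 0.0
    count = 0
    for c in range(1, n_classes):
        per_image = []
        for b in range(pred.shape[0]):
            sdm = signed_distance_map(truth[b, ..., c] > 0.5)
            per_image.append(float((pred[b, ..., c] * sdm).sum()))
        total += sum(per_image) / n_pixels
        count += 1
    return total / count if count else 0.0
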