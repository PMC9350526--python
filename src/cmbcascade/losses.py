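"""Segmentation losses: binary cross-entropy, Dice and sensitivity terms.

The total training objective is  L = L_BCE + L_Dice + lambda * L_Sen, where
L_Sen = 1 - sum(y_hat * y) / sum(y)  is a soft missed-diagnosis rate that
penalizes under-segmentation of true lesion pixels.  The coarse stage uses
lambda = 10 (detect everything), the fine stage lambda = 1 (balance
sensitivity against precision).

Each loss is computed per image and averaged over the batch.  Probabilities
are clipped to [1e-7, 1 - 1e-7] before the log.  When an image has no
foreground at all, the Dice and sensitivity ratios are smoothed with +1 on
numerator and denominator so the losses stay defined (and go to zero for a
correctly empty prediction); with any foreground present the plain formulas
are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = ["LossWeights", "bce_loss", "dice_loss", "sen_loss", "total_loss",
           "LAMBDA_COARSE", "LAMBDA_FINE"]

EPS_CLIP = 1e-7
SMOOTH = 1.0

LAMBDA_COARSE = 10.0
LAMBDA_FINE = 1.0


@dataclass(frozen=True)
class LossWeights:
    """Weight of the sensitivity term; defaults per stage."""

    lambda_sen: float = LAMBDA_FINE

    def __post_init__(self):
        if self.lambda_sen < 0:
            raise ValueError("lambda_sen must be nonnegative")

    @classmethod
    def for_stage(cls, stage: str) -> "LossWeights":
        return cls(LAMBDA_COARSE if stage == "coarse" else LAMBDA_FINE)


def _prep(y_hat, y):
    y_hat = y_hat if isinstance(y_hat, Tensor) else Tensor(np.asarray(y_hat, dtype=float))
    y_arr = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=y_hat.data.dtype)
    if y_hat.data.shape != y_arr.shape:
        raise ValueError(f"shape mismatch: {y_hat.data.shape} vs {y_arr.shape}")
    # flatten to (batch, pixels); 1-D/2-D inputs are treated as one image
    n = y_hat.data.shape[0] if y_hat.ndim >= 3 else 1
    y_hat = y_hat.reshape(n, -1)
    y_arr = y_arr.reshape(n, -1)
    return y_hat, y_arr


def bce_loss(y_hat, y) -> Tensor:
    """Mean binary cross-entropy, per image then averaged over the batch."""
    y_hat, y_arr = _prep(y_hat, y)
    p = y_hat.clip(EPS_CLIP, 1.0 - EPS_CLIP)
    per_image = -(Tensor(y_arr) * p.log()
                  + Tensor(1.0 - y_arr) * (1.0 - p).log()).mean(axis=1)
    return per_image.mean()


def _overlap_terms(y_hat, y):
    y_hat, y_arr = _prep(y_hat, y)
    inter = (y_hat * Tensor(y_arr)).sum(axis=1)
    psum = y_hat.sum(axis=1)
    ysum = y_arr.sum(axis=1)
    # engage +1 smoothing only on images with empty foreground
    smooth = np.where(ysum > 0, 0.0, SMOOTH)
    return inter, psum, ysum, smooth


def dice_loss(y_hat, y) -> Tensor:
    """1 - 2*sum(y_hat*y) / (sum(y_hat) + sum(y)), batch-averaged."""
    inter, psum, ysum, smooth = _overlap_terms(y_hat, y)
    dice = (2.0 * inter + Tensor(smooth)) / (psum + Tensor(ysum + smooth))
    return (1.0 - dice).mean()


def sen_loss(y_hat, y) -> Tensor:
    """Soft missed-diagnosis rate 1 - sum(y_hat*y) / sum(y), batch-averaged."""
    inter, psum, ysum, smooth = _overlap_terms(y_hat, y)
    sen = (inter + Tensor(smooth)) / Tensor(ysum + smooth)
    return (1.0 - sen).mean()


def total_loss(y_hat, y, weights: LossWeights = LossWeights()) -> Tensor:
    """L_BCE + L_Dice + lambda * L_Sen."""
    return (bce_loss(y_hat, y) + dice_loss(y_hat, y)
            + weights.lambda_sen * sen_loss(y_hat, y))
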