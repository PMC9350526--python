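"""Scikit-learn-style estimators over the cascade.

`CoarseSegmenter` fits the residual U-Net alone; `CascadeSegmenter` fits
both stages and predicts through the full coarse->ROI->fine pipeline.  Both
follow the sklearn estimator contract (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``fit`` returning self) so they
compose with sklearn model-selection utilities; X is a list of 2-D
normalized image arrays (or ImageSlice) and y a list of congruent binary
masks.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import cascade as casc
from . import metrics, training
from .phantom import BinaryMask, ImageSlice

__all__ = ["CoarseSegmenter", "CascadeSegmenter"]


def _pairs(X, y):
    if y is None or len(X) != len(y):
        raise ValueError("X and y must be equal-length lists of images and masks")
    out = []
    for im, mk in zip(X, y):
        im = im if isinstance(im, ImageSlice) else ImageSlice(np.asarray(im))
        mk = mk if isinstance(mk, BinaryMask) else BinaryMask(np.asarray(mk))
        if im.pixels.shape != mk.labels.shape:
            raise ValueError("image/mask shape mismatch")
        out.append((im, mk))
    return out


class CoarseSegmenter(BaseEstimator):
    """Single-stage residual U-Net segmenter."""

    def __init__(self, width_factor=8, epochs=20, batch_size=6,
                 learning_rate=2e-4, lambda_sen=None, patience=25,
                 threshold=0.5, augment=False, seed=0):
        self.width_factor = width_factor
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.lambda_sen = lambda_sen
        self.patience = patience
        self.threshold = threshold
        self.augment = augment
        self.seed = seed

    def _config(self, stage="coarse"):
        return training.TrainConfig(
            stage=stage, learning_rate=self.learning_rate,
            max_epochs=self.epochs, batch_size=self.batch_size,
            early_stopping_patience=self.patience, lambda_sen=self.lambda_sen,
            width_factor=self.width_factor, augment=self.augment, seed=self.seed)

    def fit(self, X, y):
        pairs = _pairs(X, y)
        self.model_, self.history_ = training.train_stage(pairs, self._config())
        return self

    def predict_proba(self, X):
        self._check_fitted()
        self.model_.eval()
        out = []
        for im in X:
            px = (im.pixels if isinstance(im, ImageSlice) else np.asarray(im))
            out.append(self.model_(px[None, None].astype(np.float32)).data[0, 0])
        return out

    def predict(self, X):
        return [casc.binarize(p, self.threshold) for p in self.predict_proba(X)]

    def score(self, X, y):
        """Mean per-image Dice of thresholded predictions."""
        self._check_fitted()
        preds = self.predict(X)
        truths = [m.labels if isinstance(m, BinaryMask) else np.asarray(m) for m in y]
        return float(metrics.evaluate_pairs(preds, truths)["dsc"].mean())

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")


class CascadeSegmenter(CoarseSegmenter):
    """Two-stage coarse-to-fine cascade segmenter."""

    def __init__(self, roi_size=32, width_factor=8, coarse_epochs=20,
                 fine_epochs=20, batch_size=6, learning_rate=2e-4,
                 patience=25, coarse_threshold=0.5, fine_threshold=0.5,
                 overlap_rule="max", dilation_rates=(6, 8, 12), augment=False,
                 seed=0):
        self.roi_size = roi_size
        self.width_factor = width_factor
        self.coarse_epochs = coarse_epochs
        self.fine_epochs = fine_epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.patience = patience
        self.coarse_threshold = coarse_threshold
        self.fine_threshold = fine_threshold
        self.overlap_rule = overlap_rule
        self.dilation_rates = dilation_rates
        self.augment = augment
        self.seed = seed

    def _cascade_config(self):
        return casc.CascadeConfig(
            roi_size=self.roi_size, coarse_threshold=self.coarse_threshold,
            fine_threshold=self.fine_threshold, overlap_rule=self.overlap_rule)

    def fit(self, X, y):
        pairs = _pairs(X, y)
        cfg = training.TrainConfig(
            stage="coarse", learning_rate=self.learning_rate,
            max_epochs=self.coarse_epochs, batch_size=self.batch_size,
            early_stopping_patience=self.patience, roi_size=self.roi_size,
            width_factor=self.width_factor, dilation_rates=tuple(self.dilation_rates),
            augment=self.augment, seed=self.seed)
        (self.coarse_model_, self.fine_model_,
         self.coarse_history_, self.fine_history_) = training.train_cascade(
            pairs, cfg, coarse_epochs=self.coarse_epochs,
            fine_epochs=self.fine_epochs)
        return self

    def _check_fitted(self):
        if not hasattr(self, "coarse_model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict_proba(self, X):
        self._check_fitted()
        self.coarse_model_.eval(); self.fine_model_.eval()
        cfg = self._cascade_config()
        return [casc.run_cascade(im, self.coarse_model_, self.fine_model_, cfg)[1]
                for im in X]

    def predict(self, X):
        self._check_fitted()
        self.coarse_model_.eval(); self.fine_model_.eval()
        cfg = self._cascade_config()
        return [casc.run_cascade(im, self.coarse_model_, self.fine_model_, cfg)[0].labels
                for im in X]
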