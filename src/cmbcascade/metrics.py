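"""Pixel- and lesion-level evaluation of binary segmentations.

Pixel level: sensitivity (SEN), precision (PRE), Dice (DSC), F2-score,
Jaccard (JSC) and Matthews correlation (MCC) derived from the four pixel
confusion counts.  Lesion level: a ground-truth component counts as detected
iff at least one predicted 8-connected component overlaps it; predicted
components touching no truth component are false positives, and FP_avg is
their mean count per image.  A precision-recall curve over all pixels of a
dataset yields the average precision (AP, area under the step curve).

Zero-denominator policy: if prediction and truth are both empty the
segmentation is perfect (all metrics 1, MCC 1); otherwise any ratio with a
zero denominator is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ConfusionCounts", "DetectionMatch", "confusion", "pixel_metrics",
    "lesion_detection_stats", "fp_avg", "pr_curve", "evaluate_pairs",
    "summarize", "METRIC_NAMES",
]

METRIC_NAMES = ("sen", "pre", "dsc", "f2", "jsc", "mcc")

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class DetectionMatch:
    matched_truth: int
    missed_truth: int
    false_positive_components: int

    @property
    def truth_components(self) -> int:
        return self.matched_truth + self.missed_truth


def _as_binary(mask) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mask must be binary {0,1}")
    return arr.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Exact pixel confusion counts between two congruent binary masks."""
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)), tn=int(np.sum(~p & ~t)),
        fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t)))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def pixel_metrics(c: ConfusionCounts) -> dict:
    """SEN, PRE, DSC, F2, JSC, MCC from pixel confusion counts."""
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        # both masks empty: a correct empty prediction scores perfectly
        return {m: 1.0 for m in METRIC_NAMES}
    sen = _ratio(c.tp, c.tp + c.fn)
    pre = _ratio(c.tp, c.tp + c.fp)
    dsc = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    f2 = _ratio(5.0 * pre * sen, 4.0 * pre + sen)
    jsc = _ratio(c.tp, c.tp + c.fn + c.fp)
    mcc_den = np.sqrt(float(c.tp + c.fp) * (c.tp + c.fn)
                      * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = (c.tp * c.tn - c.fp * c.fn) / mcc_den if mcc_den > 0 else 0.0
    return {"sen": sen, "pre": pre, "dsc": dsc, "f2": f2, "jsc": jsc,
            "mcc": float(mcc)}


def lesion_detection_stats(pred, truth, min_iou: float = 0.0) -> DetectionMatch:
    """Component-level matching between predicted and true lesions.

    With the default ``min_iou=0`` a single shared pixel suffices (the usual
    microbleed-detection convention); a positive value requires that IoU
    between the pair instead.
    """
    p = _as_binary(pred)
    t = _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    lp, n_pred = ndimage.label(p, structure=_STRUCT8)
    lt, n_truth = ndimage.label(t, structure=_STRUCT8)
    matched = np.zeros(n_truth + 1, dtype=bool)
    pred_hits = np.zeros(n_pred + 1, dtype=bool)
    for pi in range(1, n_pred + 1):
        region = lp == pi
        overlapping = np.unique(lt[region])
        for ti in overlapping:
            if ti == 0:
                continue
            if min_iou > 0:
                tr = lt == ti
                iou = np.sum(region & tr) / np.sum(region | tr)
                if iou < min_iou:
                    continue
            matched[ti] = True
            pred_hits[pi] = True
    n_matched = int(matched[1:].sum())
    n_fp = int(n_pred - pred_hits[1:].sum())
    return DetectionMatch(matched_truth=n_matched,
                         missed_truth=n_truth - n_matched,
                         false_positive_components=n_fp)


def fp_avg(preds, truths, min_iou: float = 0.0) -> float:
    """Mean number of false-positive lesion components per image."""
    counts = [lesion_detection_stats(p, t, min_iou).false_positive_components
              for p, t in zip(preds, truths)]
    if not counts:
        raise ValueError("no images")
    return float(np.mean(counts))


def pr_curve(probs, truths):
    """Pixel-wise precision-recall curve and average precision.

    Accepts a probability map and truth mask, or lists thereof; pixels are
    pooled.  Returns (precision, recall, ap) with recall ascending and AP the
    area under the step curve, sum over thresholds of (R_k - R_{k-1}) * P_k.
    """
    if isinstance(probs, np.ndarray) and probs.ndim == 2:
        probs, truths = [probs], [truths]
    scores = np.concatenate([np.asarray(p, dtype=float).ravel() for p in probs])
    labels = np.concatenate([_as_binary(t).ravel() for t in truths])
    if scores.shape != labels.shape:
        raise ValueError("probability/truth size mismatch")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positive truth pixels; P-R curve undefined")
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    # evaluate at each distinct threshold (last index of each score run)
    distinct = np.nonzero(np.diff(scores))[0]
    idx = np.r_[distinct, scores.size - 1]
    tp = np.cumsum(labels)[idx]
    fp = (idx + 1) - tp
    precision = tp / (tp + fp)
    recall = tp / n_pos
    # ascending recall; prepend the (R=0) anchor implicitly via diff
    dr = np.diff(np.r_[0.0, recall])
    ap = float(np.sum(dr * precision))
    return precision, recall, ap


def evaluate_pairs(preds, truths) -> pd.DataFrame:
    """Per-image table of the six pixel metrics plus FP component count."""
    rows = []
    for i, (p, t) in enumerate(zip(preds, truths)):
        row = pixel_metrics(confusion(p, t))
        det = lesion_detection_stats(p, t)
        row["fp_components"] = det.false_positive_components
        row["matched_truth"] = det.matched_truth
        row["missed_truth"] = det.missed_truth
        row["image"] = i
        rows.append(row)
    return pd.DataFrame(rows).set_index("image")


def summarize(per_image: pd.DataFrame) -> dict:
    """Mean and sample SD of each metric over images (the reporting unit)."""
    out = {}
    for m in METRIC_NAMES:
        out[f"{m}_mean"] = float(per_image[m].mean())
        out[f"{m}_sd"] = float(per_image[m].std(ddof=1)) if len(per_image) > 1 else 0.0
    if "fp_components" in per_image:
        out["fp_avg"] = float(per_image["fp_components"].mean())
    return out
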