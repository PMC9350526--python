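"""Coarse-to-fine cascade: probability map -> candidates -> ROIs -> final mask.

The coarse network's probability map is thresholded and 8-connected
components become lesion candidates.  A square ROI window is centred on each
candidate centroid (translated, never padded, to stay inside the image) and
fed to the fine network.  Per-ROI fine probabilities are fused back onto a
full-size canvas (elementwise max by default, mean optional) and thresholded
into the final mask, so every final foreground pixel lies inside some ROI
and background far from any candidate is guaranteed zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .autograd import no_grad
from .phantom import BinaryMask, ImageSlice

__all__ = ["LesionComponent", "RoiPatch", "CascadeConfig", "binarize",
           "extract_components", "crop_roi", "run_cascade"]

_STRUCT8 = np.ones((3, 3), dtype=bool)

SUPPORTED_ROI_SIZES = (16, 32, 64, 128)


@dataclass(frozen=True)
class LesionComponent:
    """One 8-connected foreground region of a binary mask."""

    pixel_rows: np.ndarray
    pixel_cols: np.ndarray
    centroid: tuple
    area: int

    @property
    def equivalent_diameter(self) -> float:
        return float(np.sqrt(4.0 * self.area / np.pi))


@dataclass(frozen=True)
class RoiPatch:
    """Square crop: top-left origin (row, col), half-open window."""

    origin: tuple
    size: int
    image_crop: np.ndarray
    source_component: LesionComponent | None = None

    @property
    def window(self):
        r, c = self.origin
        return (slice(r, r + self.size), slice(c, c + self.size))


@dataclass(frozen=True)
class CascadeConfig:
    roi_size: int = 32
    coarse_threshold: float = 0.5
    fine_threshold: float = 0.5
    min_component_area: int = 1
    overlap_rule: str = "max"

    def __post_init__(self):
        if not (0 < self.coarse_threshold < 1 and 0 < self.fine_threshold < 1):
            raise ValueError("thresholds must lie in (0,1)")
        if self.overlap_rule not in ("max", "mean"):
            raise ValueError("overlap_rule must be 'max' or 'mean'")
        if self.roi_size not in SUPPORTED_ROI_SIZES:
            raise ValueError(f"roi_size must be one of {SUPPORTED_ROI_SIZES}")


def binarize(prob: np.ndarray, threshold: float) -> np.ndarray:
    """Pixel = 1 iff probability >= threshold."""
    prob = np.asarray(prob)
    return (prob >= threshold).astype(np.uint8)


def extract_components(mask, min_component_area: int = 1):
    """8-connected components of a binary mask, small ones dropped."""
    arr = mask.labels if isinstance(mask, BinaryMask) else np.asarray(mask)
    labelled, n = ndimage.label(arr, structure=_STRUCT8)
    comps = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labelled == lab)
        if rows.size < min_component_area:
            continue
        comps.append(LesionComponent(
            pixel_rows=rows, pixel_cols=cols,
            centroid=(float(rows.mean()), float(cols.mean())),
            area=int(rows.size)))
    return comps


def crop_roi(image, component: LesionComponent, size: int) -> RoiPatch:
    """Size x size window centred at the rounded centroid, clamped inside."""
    px = image.pixels if isinstance(image, ImageSlice) else np.asarray(image)
    h, w = px.shape
    if size > h or size > w:
        raise ValueError(f"ROI size {size} exceeds image {h}x{w}")
    cy, cx = component.centroid
    r0 = int(np.floor(cy + 0.5)) - size // 2
    c0 = int(np.floor(cx + 0.5)) - size // 2
    r0 = min(max(r0, 0), h - size)
    c0 = min(max(c0, 0), w - size)
    return RoiPatch(origin=(r0, c0), size=size,
                    image_crop=px[r0:r0 + size, c0:c0 + size].copy(),
                    source_component=component)


def run_cascade(image, coarse_model, fine_model,
                config: CascadeConfig = CascadeConfig()):
    """Full two-stage inference on one normalized slice.

    ``coarse_model`` and ``fine_model`` are callables mapping a (1,1,H,W)
    array to a probability Tensor/array of the same shape.  Returns
    (final BinaryMask, fused ProbabilityMap, list of RoiPatch).
    """
    px = image.pixels if isinstance(image, ImageSlice) else np.asarray(image)
    h, w = px.shape

    coarse_prob = _predict(coarse_model, px)
    candidates = extract_components(binarize(coarse_prob, config.coarse_threshold),
                                    config.min_component_area)
    fused = np.zeros((h, w), dtype=np.float64)
    counts = np.zeros((h, w), dtype=np.int64)
    rois = []
    for comp in candidates:
        roi = crop_roi(px, comp, config.roi_size)
        rois.append(roi)
        fine_prob = _predict(fine_model, roi.image_crop)
        win = roi.window
        if config.overlap_rule == "max":
            fused[win] = np.maximum(fused[win], fine_prob)
        else:
            fused[win] += fine_prob
        counts[win] += 1
    if config.overlap_rule == "mean":
        fused = np.divide(fused, counts, out=np.zeros_like(fused),
                          where=counts > 0)
    final = binarize(fused, config.fine_threshold)
    final[counts == 0] = 0  # nothing outside every ROI window
    return BinaryMask(final), fused, rois


def _predict(model, image2d: np.ndarray) -> np.ndarray:
    with no_grad():
        out = model(image2d[None, None, :, :].astype(np.float32))
    data = out.data if hasattr(out, "data") else np.asarray(out)
    return np.asarray(data, dtype=np.float64)[0, 0]
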