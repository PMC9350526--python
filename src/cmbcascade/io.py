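"""Image and mask I/O: NIfTI (.nii/.nii.gz) and 8/16-bit PNG.

Conventions (documented once, used everywhere): (row, col) indexing,
0-based, half-open windows.  NIfTI data are taken as stored — no
reorientation.  Intensities are never silently rescaled on read: a 16-bit
PNG with values {0, 65535} loads as floats {0.0, 65535.0}.  Masks are
strict: NIfTI masks hold {0,1} (uint8), PNG masks {0,255}; any other value
is a validation error, and nonzero maps to label 1 on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .phantom import BinaryMask, ImageSlice

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]

logger = logging.getLogger("cmbcascade")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _read_array(path: Path) -> tuple[np.ndarray, float | None]:
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim == 3:
            logger.warning("%s is a 3-D volume (%d slices); using slice 0",
                           path.name, data.shape[2])
            data = data[:, :, 0]
        elif data.ndim != 2:
            raise IOError(f"{path}: unsupported dimensionality {data.ndim}")
        spacing = float(img.header.get_zooms()[0])
        return data, spacing
    if path.suffix.lower() == ".png":
        data = np.asarray(iio.imread(path))
        if data.ndim == 3:  # collapse grayscale-stored-as-RGB
            data = data[..., 0]
        return data.astype(np.float64), None
    raise IOError(f"{path}: unsupported format (expected .nii, .nii.gz or .png)")


def read_image(path, default_spacing_mm: float = 0.5) -> ImageSlice:
    """Load a 2-D grayscale slice; spacing from the NIfTI header when present."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"{path}: no such file")
    data, spacing = _read_array(path)
    return ImageSlice(data, spacing_mm=spacing or default_spacing_mm,
                      id=path.name.split(".")[0])


def write_image(path, image: ImageSlice) -> None:
    """Write float32 NIfTI (verbatim values) or 8-bit PNG ([0,1] -> 0..255)."""
    path = Path(path)
    if _is_nifti(path):
        affine = np.diag([image.spacing_mm, image.spacing_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.pixels.astype(np.float32), affine), str(path))
    elif path.suffix.lower() == ".png":
        px = image.pixels
        if px.min() < 0 or px.max() > 1:
            raise IOError("PNG image writer expects normalized [0,1] intensities")
        iio.imwrite(path, np.round(px * 255).astype(np.uint8))
    else:
        raise IOError(f"{path}: unsupported format")


def read_mask(path) -> BinaryMask:
    """Load a binary mask; nonzero -> 1; strict about admissible raw values."""
    path = Path(path)
    data, _ = _read_array(path)
    vals = np.unique(data)
    if not np.isin(vals, (0, 1, 255)).all():
        raise ValueError(
            f"{path}: mask contains values {vals[:8]} outside {{0, 1, 255}}")
    return BinaryMask((data > 0).astype(np.uint8))


def write_mask(path, mask: BinaryMask) -> None:
    """Write uint8 {0,1} NIfTI or {0,255} PNG."""
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.labels.astype(np.uint8), np.eye(4)), str(path))
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, (mask.labels * 255).astype(np.uint8))
    else:
        raise IOError(f"{path}: unsupported format")
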