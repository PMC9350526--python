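"""Synthetic SWI-like phantom slices with ground-truth microbleed masks.

Real cerebral microbleeds appear on susceptibility-weighted images as small
ovoid hypointense (dark) foci, under 10 mm in diameter, on a textured brain
background that also contains dark curvilinear mimics (veins) and other
hypointense confusers.  The phantom emulates exactly those features:

* background — smoothed Gaussian noise, rescaled to a mid-grey band;
* lesions   — anti-aliased filled ellipses, darker than their surroundings,
  parameterized by equivalent diameter (mm) and eccentricity; these are the
  only structures written into the ground-truth mask;
* mimics    — thin dark random-walk curves that darken the image but
  contribute nothing to the mask (vein-like false-positive bait);
* noise     — additive Gaussian pixel noise.

Everything is a pure function of (config, seed): the same seed reproduces
bit-identical images and masks.

The module also houses the intensity normalization and the augmentation
stack used in training (random intensity shift/scale, probabilistic
rotations and flips, additive noise) and a seeded 4:1 train/validation
split helper.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomConfig", "ImageSlice", "BinaryMask", "AugmentationPolicy",
    "generate_dataset", "min_max_normalize", "augment", "train_val_split",
    "write_dataset",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ImageSlice:
    """One 2-D grayscale slice; (row, col) indexing, 0-based."""

    pixels: np.ndarray
    spacing_mm: float = 0.5
    id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("ImageSlice expects a 2-D array")
        if not np.isfinite(arr).all():
            raise ValueError("image contains non-finite values")
        object.__setattr__(self, "pixels", arr)


@dataclass(frozen=True)
class BinaryMask:
    """Per-pixel {0,1} labels congruent to an ImageSlice."""

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if not np.isin(np.unique(arr), (0, 1)).all():
            raise ValueError("mask values must be in {0,1}")
        object.__setattr__(self, "labels", arr.astype(np.uint8))


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic generator.

    Lesion size is the equivalent diameter in mm (area-preserving under
    eccentricity), strictly below the 10 mm microbleed definition.  Contrast
    is a negative intensity offset relative to the local background on the
    normalized [0,1] scale.
    """

    image_height: int = 96
    image_width: int = 128
    pixel_spacing_mm: float = 0.5
    lesions_per_image_range: tuple = (1, 3)
    lesion_diameter_range_mm: tuple = (2.0, 7.0)
    lesion_eccentricity_range: tuple = (0.0, 0.6)
    lesion_contrast_range: tuple = (0.25, 0.5)
    n_mimics_range: tuple = (0, 2)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.lesion_diameter_range_mm
        if not (0 < lo <= hi < 10.0):
            raise ConfigurationError(
                "lesion diameters must lie in (0, 10) mm (microbleed definition)")
        for name in ("lesions_per_image_range", "lesion_eccentricity_range",
                     "lesion_contrast_range", "n_mimics_range"):
            a, b = getattr(self, name)
            if a > b:
                raise ConfigurationError(f"{name} is empty: {a} > {b}")
        e0, e1 = self.lesion_eccentricity_range
        if not (0 <= e0 <= e1 < 1):
            raise ConfigurationError("eccentricity must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if min(self.image_height, self.image_width) < 16:
            raise ConfigurationError("image must be at least 16x16")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Stochastic training-time transforms and their gate probabilities.

    Defaults: intensity shift ~ U(-0.2, 0.2) and scale ~ U(0.8, 1.2) always
    applied when the support is nonzero, rotation up to 180 degrees with
    probability 0.30, horizontal/vertical flips each with probability 0.30,
    additive Gaussian noise on.
    """

    intensity_shift_scale_sd: float = 0.2
    rotation_probability: float = 0.30
    max_rotation_deg: float = 180.0
    flip_probability: float = 0.30
    noise_on: bool = True
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for p in (self.rotation_probability, self.flip_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0,1]")

    @classmethod
    def none(cls, seed: int = 0) -> "AugmentationPolicy":
        """Identity policy (useful for deterministic pipelines)."""
        return cls(intensity_shift_scale_sd=0.0, rotation_probability=0.0,
                   flip_probability=0.0, noise_on=False, seed=seed)


# -- generation ---------------------------------------------------------------

def _background(rng, h, w):
    base = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=8.0)
    base = (base - base.mean()) / (base.std() + 1e-12)
    return np.clip(0.55 + 0.08 * base, 0.25, 0.85)


def _ellipse_coverage(h, w, cy, cx, a, b, theta, supersample=4):
    """Subpixel-averaged indicator of an ellipse with semi-axes a, b (pixels)."""
    s = supersample
    pad = int(np.ceil(max(a, b))) + 2
    r0, r1 = max(0, int(cy) - pad), min(h, int(cy) + pad + 1)
    c0, c1 = max(0, int(cx) - pad), min(w, int(cx) + pad + 1)
    yy = (np.arange(r0 * s, r1 * s) + 0.5) / s - 0.5
    xx = (np.arange(c0 * s, c1 * s) + 0.5) / s - 0.5
    y, x = np.meshgrid(yy - cy, xx - cx, indexing="ij")
    ct, st = np.cos(theta), np.sin(theta)
    u = (y * ct + x * st) / a
    v = (-y * st + x * ct) / b
    inside = (u * u + v * v) <= 1.0
    cov = inside.reshape(r1 - r0, s, c1 - c0, s).mean(axis=(1, 3))
    out = np.zeros((h, w))
    out[r0:r1, c0:c1] = cov
    return out


def _mimic_curve(rng, h, w):
    """Thin dark random-walk curve; returns a soft intensity-decrement map."""
    canvas = np.zeros((h, w))
    r = rng.uniform(5, h - 5)
    c = rng.uniform(5, w - 5)
    angle = rng.uniform(0, 2 * np.pi)
    length = rng.integers(20, 60)
    for _ in range(length):
        angle += rng.normal(0, 0.3)
        r = np.clip(r + np.sin(angle), 0, h - 1)
        c = np.clip(c + np.cos(angle), 0, w - 1)
        canvas[int(round(r)), int(round(c))] = 1.0
    return ndimage.gaussian_filter(canvas, sigma=0.6)


def _place_lesions(rng, cfg: PhantomConfig):
    """Draw lesion geometry with rejection sampling so components stay disjoint."""
    n = int(rng.integers(cfg.lesions_per_image_range[0],
                         cfg.lesions_per_image_range[1] + 1))
    h, w = cfg.image_height, cfg.image_width
    placed = []
    for _ in range(n):
        d_mm = rng.uniform(*cfg.lesion_diameter_range_mm)
        ecc = rng.uniform(*cfg.lesion_eccentricity_range)
        contrast = rng.uniform(*cfg.lesion_contrast_range)
        theta = rng.uniform(0, np.pi)
        # equivalent diameter preserved under eccentricity: a*b = (d/2)^2
        r_eq = d_mm / (2 * cfg.pixel_spacing_mm)
        axis_ratio = (1 - ecc**2) ** 0.25
        a, b = r_eq / axis_ratio, r_eq * axis_ratio
        margin = a + 2
        for _try in range(1000):
            cy = rng.uniform(margin, h - 1 - margin)
            cx = rng.uniform(margin, w - 1 - margin)
            if all(np.hypot(cy - p[0], cx - p[1]) > a + p[2] + 3 for p in placed):
                placed.append((cy, cx, a, b, theta, contrast))
                break
        else:
            raise ConfigurationError(
                "could not place lesions without overlap; image too small "
                "for the configured count/size")
    return placed


def _render(rng, cfg: PhantomConfig, index: int):
    h, w = cfg.image_height, cfg.image_width
    img = _background(rng, h, w)
    mask = np.zeros((h, w), dtype=np.uint8)
    lesions = _place_lesions(rng, cfg)
    for cy, cx, a, b, theta, contrast in lesions:
        cov = _ellipse_coverage(h, w, cy, cx, a, b, theta)
        img -= contrast * cov
        mask[cov >= 0.5] = 1
    n_mimics = int(rng.integers(cfg.n_mimics_range[0], cfg.n_mimics_range[1] + 1))
    for _ in range(n_mimics):
        img -= 0.8 * np.mean(cfg.lesion_contrast_range) * _mimic_curve(rng, h, w)
    if cfg.noise_sd > 0:
        img += rng.normal(0, cfg.noise_sd, (h, w))
    img = np.clip(img, 0.0, 1.0)
    sl = ImageSlice(img, spacing_mm=cfg.pixel_spacing_mm,
                    id=f"phantom-{cfg.seed}-{index:04d}")
    return sl, BinaryMask(mask), lesions


def generate_dataset(config: PhantomConfig, n_images: int):
    """Generate ``n_images`` seeded (ImageSlice, BinaryMask) pairs."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(config.seed)
    return [(s, m) for s, m, _ in (_render(rng, config, i) for i in range(n_images))]


def generate_dataset_with_geometry(config: PhantomConfig, n_images: int):
    """As generate_dataset, but also returns the placed lesion parameters."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    rng = np.random.default_rng(config.seed)
    return [_render(rng, config, i) for i in range(n_images)]


# -- normalization & augmentation ---------------------------------------------

def min_max_normalize(image: ImageSlice) -> ImageSlice:
    """Affine rescale of intensities to [0,1]; constant images map to zeros."""
    px = image.pixels
    lo, hi = px.min(), px.max()
    if hi == lo:
        return replace(image, pixels=np.zeros_like(px))
    return replace(image, pixels=(px - lo) / (hi - lo))


def augment(image: ImageSlice, mask: BinaryMask, policy: AugmentationPolicy,
            rng: np.random.Generator | None = None):
    """Apply the stochastic augmentation stack to one (image, mask) pair.

    Geometric transforms hit image and mask identically (bilinear vs
    nearest-neighbour resampling so labels stay binary); intensity shift,
    scale and noise touch the image only.
    """
    if image.pixels.shape != mask.labels.shape:
        raise ValueError("image and mask shapes differ")
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    img = image.pixels.copy()
    lab = mask.labels.copy()

    if policy.rotation_probability > 0 and rng.random() < policy.rotation_probability:
        angle = rng.uniform(-policy.max_rotation_deg, policy.max_rotation_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1, cval=0.0)
        lab = ndimage.rotate(lab, angle, reshape=False, order=0, cval=0)
    if policy.flip_probability > 0 and rng.random() < policy.flip_probability:
        img, lab = img[:, ::-1], lab[:, ::-1]
    if policy.flip_probability > 0 and rng.random() < policy.flip_probability:
        img, lab = img[::-1, :], lab[::-1, :]
    if policy.intensity_shift_scale_sd > 0:
        s = policy.intensity_shift_scale_sd
        scale = rng.uniform(1.0 - s, 1.0 + s)
        shift = rng.uniform(-s, s)
        img = img * scale + shift
    if policy.noise_on:
        img = img + rng.normal(0.0, policy.noise_sd, img.shape)
    return (replace(image, pixels=np.ascontiguousarray(img)),
            BinaryMask(np.ascontiguousarray(lab)))


def train_val_split(items, seed: int, val_fraction: float = 0.2):
    """Seeded shuffle split at image level (default 4:1 train:validation)."""
    idx = np.random.default_rng(seed).permutation(len(items))
    n_val = int(round(val_fraction * len(items)))
    val_idx = set(idx[:n_val].tolist())
    train = [items[i] for i in range(len(items)) if i not in val_idx]
    val = [items[i] for i in sorted(val_idx)]
    return train, val


# -- writers ------------------------------------------------------------------

def write_dataset(pairs, out_dir, fmt: str = "png", seed: int | None = None):
    """Write paired images/masks (PNG 8-bit image + 0/255 mask, or NIfTI
    float32 image + uint8 mask) with identical basenames and a manifest CSV."""
    from . import io as cio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, mask) in enumerate(pairs):
        base = img.id or f"phantom-{i:04d}"
        if fmt == "png":
            img_path = out / f"{base}.png"
            mask_path = out / f"{base}_mask.png"
        elif fmt == "nifti":
            img_path = out / f"{base}.nii.gz"
            mask_path = out / f"{base}_mask.nii.gz"
        else:
            raise ValueError(f"unknown format {fmt!r}")
        cio.write_image(img_path, img)
        cio.write_mask(mask_path, mask)
        n_lesions = int(ndimage.label(mask.labels, structure=np.ones((3, 3)))[1])
        rows.append({"id": base, "image_path": img_path.name,
                     "mask_path": mask_path.name, "n_lesions": n_lesions,
                     "seed": seed if seed is not None else ""})
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return out / "manifest.csv"
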