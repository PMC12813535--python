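"""Geometric data augmentation: rotation, scaling, random cropping.

Defaults carry the published training protocol: rotation angles drawn from
[10, 90] degrees, scaling ratios from [0.8, 1.2], crops of 256 x 256 pixels.
Image and label map always receive the identical geometric transform; images
are interpolated bilinearly, label maps with nearest-neighbour so labels stay
integral and no new label values appear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

__all__ = ["AugmentConfig", "rotate_pair", "scale_pair", "random_crop_pair",
           "augment_pair", "sample_parameters"]


@dataclass(frozen=True)
class AugmentConfig:
    rotation_deg_range: tuple[float, float] = (10.0, 90.0)
    scale_range: tuple[float, float] = (0.8, 1.2)
    crop_size: tuple[int, int] = (256, 256)
    background_color: tuple[float, float, float] = (0.97, 0.95, 0.96)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rotation_deg_range
        if not (0.0 <= lo <= hi < 360.0):
            raise ValueError("rotation range must lie within [0, 360)")
        slo, shi = self.scale_range
        if not (0.0 < slo <= shi):
            raise ValueError("scale bounds must be positive")
        if min(self.crop_size) < 1:
            raise ValueError("crop_size must be >= 1 in both dimensions")


def rotate_pair(
    image: np.ndarray,
    labels: np.ndarray,
    angle_deg: float,
    background_color=(0.97, 0.95, 0.96),
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate image (bilinear) and labels (nearest) counterclockwise about the
    image centre, keeping the canvas size; exposed corners are filled with the
    background colour (labels: 0)."""
    if not math.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    if angle_deg % 360.0 == 0.0:
        return image.copy(), labels.copy()
    out_img = np.empty_like(image)
    for ch in range(image.shape[2]):
        out_img[:, :, ch] = sktransform.rotate(
            image[:, :, ch], angle_deg, resize=False, order=1,
            cval=background_color[ch], preserve_range=True,
        )
    np.clip(out_img, 0.0, 1.0, out=out_img)
    out_lab = sktransform.rotate(
        labels.astype(np.float64), angle_deg, resize=False, order=0, cval=0.0,
        preserve_range=True,
    )
    return out_img, np.round(out_lab).astype(labels.dtype)


def scale_pair(
    image: np.ndarray, labels: np.ndarray, factor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale both rasters to round(size * factor); labels nearest-neighbour."""
    if not (math.isfinite(factor) and factor > 0):
        raise ValueError("scale factor must be positive and finite")
    if factor == 1.0:
        return image.copy(), labels.copy()
    h, w = labels.shape
    out_shape = (max(1, round(h * factor)), max(1, round(w * factor)))
    out_img = sktransform.resize(
        image, out_shape + (image.shape[2],), order=1, preserve_range=True,
        anti_aliasing=factor < 1.0,
    )
    np.clip(out_img, 0.0, 1.0, out=out_img)
    out_lab = sktransform.resize(
        labels.astype(np.float64), out_shape, order=0, preserve_range=True,
        anti_aliasing=False,
    )
    return out_img, np.round(out_lab).astype(labels.dtype)


def _pad_to(image: np.ndarray, labels: np.ndarray, min_h: int, min_w: int,
            background_color) -> tuple[np.ndarray, np.ndarray]:
    h, w = labels.shape
    if h >= min_h and w >= min_w:
        return image, labels
    ph, pw = max(min_h - h, 0), max(min_w - w, 0)
    img = np.empty((h + ph, w + pw, image.shape[2]), dtype=image.dtype)
    img[:] = background_color
    img[:h, :w] = image
    lab = np.zeros((h + ph, w + pw), dtype=labels.dtype)
    lab[:h, :w] = labels
    return img, lab


def random_crop_pair(
    image: np.ndarray,
    labels: np.ndarray,
    crop_size: tuple[int, int],
    rng: np.random.Generator,
    background_color=(0.97, 0.95, 0.96),
) -> tuple[np.ndarray, np.ndarray]:
    """Crop the identical random window from image and labels; inputs smaller
    than the crop are background-padded first."""
    ch, cw = crop_size
    image, labels = _pad_to(image, labels, ch, cw, background_color)
    h, w = labels.shape
    r0 = int(rng.integers(0, h - ch + 1))
    c0 = int(rng.integers(0, w - cw + 1))
    return image[r0:r0 + ch, c0:c0 + cw].copy(), labels[r0:r0 + ch, c0:c0 + cw].copy()


def sample_parameters(config: AugmentConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (rotation angle, scale factor) uniformly from the configured ranges."""
    angle = float(rng.uniform(*config.rotation_deg_range))
    factor = float(rng.uniform(*config.scale_range))
    return angle, factor


def augment_pair(
    image: np.ndarray,
    labels: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate -> scale -> crop with parameters drawn uniformly from the
    configured ranges; deterministic under a fixed generator state."""
    angle, factor = sample_parameters(config, rng)
    img, lab = rotate_pair(image, labels, angle, config.background_color)
    img, lab = scale_pair(img, lab, factor)
    return random_crop_pair(img, lab, config.crop_size, rng, config.background_color)
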