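"""Image augmentations used during counter training.

Per image: independent 50% vertical and horizontal flips; a crop of 10% of
the linear size at a uniformly random position, resized back to the input
size; a brightness offset drawn from ±0.1 of the dynamic range; and a
contrast factor in [0.8, 1.2] applied about the image mean.  Labels are
never changed (none of these operations can alter a leaf count).
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

__all__ = ["augment_image", "augment_batch", "BRIGHTNESS_RANGE", "CONTRAST_RANGE"]

BRIGHTNESS_RANGE = (-0.1, 0.1)  # additive, images in [0, 1]
CONTRAST_RANGE = (0.8, 1.2)  # multiplicative about the mean


def augment_image(
    image: np.ndarray,
    rng: np.random.Generator,
    *,
    flips: bool = True,
    crop_fraction: float = 0.10,
    brightness: bool = True,
    contrast: bool = True,
) -> np.ndarray:
    """Return an augmented copy of a (H, W, 3) float image in [0, 1]."""
    img = np.asarray(image, dtype=np.float32)
    h, w = img.shape[:2]
    if flips:
        if rng.random() < 0.5:
            img = img[::-1, :, :]
        if rng.random() < 0.5:
            img = img[:, ::-1, :]
    if crop_fraction:
        if not (0 < crop_fraction < 1):
            raise ValueError("crop_fraction must be in (0, 1)")
        ch = max(1, int(round(h * (1 - crop_fraction))))
        cw = max(1, int(round(w * (1 - crop_fraction))))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        img = img[top:top + ch, left:left + cw, :]
        img = resize(img, (h, w), order=1, anti_aliasing=False,
                     preserve_range=True).astype(np.float32)
    if brightness:
        img = img + rng.uniform(*BRIGHTNESS_RANGE)
    if contrast:
        f = rng.uniform(*CONTRAST_RANGE)
        m = img.mean()
        img = (img - m) * f + m
    return np.clip(img, 0.0, 1.0)


def augment_batch(batch: np.ndarray, rng: np.random.Generator, **kwargs) -> np.ndarray:
    return np.stack([augment_image(im, rng, **kwargs) for im in batch])
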