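"""Training-time augmentation for (image, label) volume pairs.

Random flips, gamma jitter, additive Gaussian noise and isotropic resizing,
sampled independently per iteration. Geometric operations are applied
identically to image and label; the label is resampled nearest-neighbor so
it stays strictly binary. Intensity operations touch the image only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "augment_sample"]


@dataclass
class AugmentConfig:
    flip_prob: float = 0.5          # per axis
    gamma_prob: float = 0.3
    gamma_range: tuple[float, float] = (0.7, 1.4)
    noise_prob: float = 0.3
    noise_sigma_max: float = 0.05
    resize_prob: float = 0.2
    resize_range: tuple[float, float] = (0.8, 1.2)

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(flip_prob=0, gamma_prob=0, noise_prob=0, resize_prob=0)


def _resize_pair(image, label, scale):
    """Zoom both volumes, then center-crop/pad back to the original shape."""
    zoomed_img = ndimage.zoom(image, scale, order=1)
    zoomed_lab = ndimage.zoom(label.astype(np.float32), scale, order=0)
    out_img = np.zeros_like(image)
    out_lab = np.zeros_like(label)
    for out, src in ((out_img, zoomed_img), (out_lab, zoomed_lab)):
        slices_out, slices_src = [], []
        for n_out, n_src in zip(out.shape, src.shape):
            if n_src >= n_out:
                start = (n_src - n_out) // 2
                slices_src.append(slice(start, start + n_out))
                slices_out.append(slice(0, n_out))
            else:
                start = (n_out - n_src) // 2
                slices_out.append(slice(start, start + n_src))
                slices_src.append(slice(0, n_src))
        out[tuple(slices_out)] = src[tuple(slices_src)]
    return out_img, (out_lab > 0.5).astype(label.dtype)


def augment_sample(image: np.ndarray, label: np.ndarray,
                   rng: np.random.Generator,
                   cfg: AugmentConfig | None = None):
    """Apply a random augmentation subset to an aligned (image, label) pair.

    With all probabilities zero the pair is returned unchanged (same
    arrays). Image values stay within [0, 1]; label values within {0, 1}.
    """
    if image.shape != label.shape:
        raise ValueError("image and label must be aligned")
    cfg = cfg or AugmentConfig()
    img, lab = image, label
    for axis in range(3):
        if rng.random() < cfg.flip_prob:
            img = np.flip(img, axis=axis)
            lab = np.flip(lab, axis=axis)
    if rng.random() < cfg.resize_prob:
        scale = rng.uniform(*cfg.resize_range)
        img, lab = _resize_pair(np.ascontiguousarray(img),
                                np.ascontiguousarray(lab), scale)
    if rng.random() < cfg.gamma_prob:
        gamma = rng.uniform(*cfg.gamma_range)
        img = np.clip(img, 0, 1) ** gamma
    if rng.random() < cfg.noise_prob:
        sigma = rng.uniform(0, cfg.noise_sigma_max)
        img = np.clip(img + rng.normal(0, sigma, size=img.shape), 0, 1)
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)
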