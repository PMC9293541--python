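"""Global-statistics normalization, resizing and paired geometric augmentation.

Normalization standardizes every pixel by one global mean/std pair pooled
over all pixels of all training images,

    y_i  ->  (y_i - ybar) / (sigma + eps),    eps = 1e-10,

rather than per-image statistics.  The stats are computed on the training
partition only and reused unchanged for validation, test and inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from skimage import transform as sktransform

from .synthetic import RenderedSample

__all__ = [
    "NormalizationStats",
    "AugmentConfig",
    "compute_global_stats",
    "normalize",
    "resize_to_model",
    "augment",
]

DEFAULT_EPSILON = 1e-10


@dataclass(frozen=True)
class NormalizationStats:
    """Global mean, population std and the stabilizer epsilon."""

    global_mean: float
    global_std: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.global_std < 0:
            raise ValueError("global_std must be nonnegative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def to_dict(self) -> dict:
        return {
            "global_mean": self.global_mean,
            "global_std": self.global_std,
            "epsilon": self.epsilon,
            # resize-then-normalize: stats were computed on resized images
            "order": "resize_then_normalize",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            global_mean=float(d["global_mean"]),
            global_std=float(d["global_std"]),
            epsilon=float(d["epsilon"]),
        )


@dataclass(frozen=True)
class AugmentConfig:
    """Random rotation / zoom / scale, one draw each per sample.

    Ranges are deliberately mild: rotation uniform in +-25 degrees and
    multiplicative zoom/scale factors uniform in [0.9, 1.1].
    """

    rotation_range: tuple[float, float] = (-25.0, 25.0)  # degrees
    zoom_range: tuple[float, float] = (0.9, 1.1)
    scale_range: tuple[float, float] = (0.9, 1.1)
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.zoom_range[0] <= 0 or self.scale_range[0] <= 0:
            raise ValueError("zoom and scale factors must be strictly positive")


def compute_global_stats(
    images: Iterable[np.ndarray], epsilon: float = DEFAULT_EPSILON
) -> NormalizationStats:
    """Pool every pixel of every image (all channels) into one mean/std pair.

    Uses the population standard deviation (no Bessel correction).
    """
    total = 0
    s1 = 0.0
    s2 = 0.0
    for img in images:
        arr = np.asarray(img, dtype=np.float64)
        total += arr.size
        s1 += arr.sum()
        s2 += np.square(arr).sum()
    if total == 0:
        raise ValueError("cannot compute global stats of an empty collection")
    mean = s1 / total
    var = max(s2 / total - mean**2, 0.0)
    return NormalizationStats(
        global_mean=float(mean), global_std=float(np.sqrt(var)), epsilon=epsilon
    )


def normalize(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Elementwise (x - global_mean) / (global_std + epsilon), channel-agnostic."""
    arr = np.asarray(image, dtype=np.float64)
    return (arr - stats.global_mean) / (stats.global_std + stats.epsilon)


def resize_to_model(
    image_or_mask: np.ndarray, side: int, is_mask: bool = False
) -> np.ndarray:
    """Resize to ``side`` x ``side``: bilinear for images, nearest for masks.

    Masks stay strictly binary and keep their dtype; images are returned as
    float64 in the original intensity range.
    """
    if side < 8:
        raise ValueError("target side must be at least 8 pixels")
    arr = np.asarray(image_or_mask)
    out_shape = (side, side) + arr.shape[2:]
    if is_mask:
        out = sktransform.resize(
            arr.astype(np.float64),
            out_shape,
            order=0,
            preserve_range=True,
            anti_aliasing=False,
        )
        return (out > 0.5).astype(arr.dtype)
    out = sktransform.resize(
        arr.astype(np.float64),
        out_shape,
        order=1,
        preserve_range=True,
        anti_aliasing=arr.shape[0] > side,
    )
    return out


def _draw_transform(
    config: AugmentConfig, seed: int, shape: tuple[int, int]
) -> sktransform.AffineTransform:
    rng = np.random.default_rng(seed)
    angle = np.deg2rad(rng.uniform(*config.rotation_range))
    zoom = rng.uniform(*config.zoom_range)
    scale = rng.uniform(*config.scale_range)
    factor = zoom * scale
    center = np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])  # (x, y)
    shift_to = sktransform.AffineTransform(translation=-center)
    core = sktransform.AffineTransform(rotation=angle, scale=(factor, factor))
    shift_back = sktransform.AffineTransform(translation=center)
    return shift_to + core + shift_back


def augment(sample: RenderedSample, config: AugmentConfig, seed: int) -> RenderedSample:
    """Apply one random rotation+zoom+scale identically to image and mask.

    The image is warped bilinearly with reflected borders; the mask uses
    nearest-neighbour with zero fill and is re-binarized, so it stays a
    strict 0/1 array transformed by the same geometric map.
    """
    if not config.enabled:
        return sample
    tform = _draw_transform(config, seed, sample.mask.shape)
    img = sktransform.warp(
        sample.image.astype(np.float64),
        tform.inverse,
        order=1,
        mode="reflect",
        preserve_range=True,
    )
    msk = sktransform.warp(
        sample.mask.astype(np.float64),
        tform.inverse,
        order=0,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    return RenderedSample(
        image=np.clip(np.rint(img), 0, 255).astype(np.uint8),
        mask=(msk > 0.5).astype(np.uint8),
        sample_id=sample.sample_id,
        seed=sample.seed,
    )
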