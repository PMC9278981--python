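"""Photometric stress-test operators and aggregate-histogram analytics.

Three transformations probe a detector's robustness to acquisition
variability:

* **shift** — add an offset B1 ~ Uniform[mean/4, mean/2] to every pixel,
  raising the image mean by 25–50% (before clipping);
* **stretch** — apply A2·(I + B2) with gain A2 ~ Uniform[1.5, 2.5] and
  offset B2 = 127.5/A2 − mean(I), which centers the histogram at the
  midpoint of [0, 255] and scales the variance by A2² ∈ [2.25, 6.25]
  (+125% to +525%);
* **negate** — the pixel-wise complement 255 − I, flipping the contrast
  polarity of cells versus background.

All arithmetic is done in floating point; the result is clipped to [0, 255]
and quantized last, and each stochastic draw is recorded for reproducibility.
Aggregate histograms are normalized means of per-image normalized 256-bin
histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransformDraw",
    "IntensityHistogram",
    "shift_intensity",
    "stretch_contrast",
    "negate",
    "image_histogram",
    "aggregate_histogram",
]


@dataclass(frozen=True)
class TransformDraw:
    """Record of one stochastic transform application."""

    kind: str  # SHIFT | STRETCH | NEGATE
    b1: float | None = None
    a2: float | None = None
    b2: float | None = None
    saturation_fraction: float = 0.0


@dataclass(frozen=True)
class IntensityHistogram:
    bins: np.ndarray  # 256 values
    normalized: bool

    def __post_init__(self):
        if self.bins.shape != (256,):
            raise ValueError("intensity histogram must have 256 bins")

    def reversed(self) -> "IntensityHistogram":
        return IntensityHistogram(self.bins[::-1].copy(), self.normalized)


def _finalize(float_img: np.ndarray):
    clipped = np.clip(float_img, 0.0, 255.0)
    saturated = float(np.mean((float_img < 0.0) | (float_img > 255.0)))
    return np.rint(clipped).astype(np.uint8), saturated


def shift_intensity(image: np.ndarray, rng: np.random.Generator):
    """Brighten: I' = I + B1 with B1 ~ Uniform[mean/4, mean/2]."""
    img = np.asarray(image, dtype=np.float64)
    mean = img.mean()
    if mean <= 0:
        warnings.warn("zero-mean image: shift bounds degenerate, returning input unchanged")
        return np.asarray(image).copy(), TransformDraw("SHIFT", b1=0.0)
    b1 = float(rng.uniform(mean / 4.0, mean / 2.0))
    out, sat = _finalize(img + b1)
    return out, TransformDraw("SHIFT", b1=b1, saturation_fraction=sat)


def stretch_contrast(image: np.ndarray, rng: np.random.Generator):
    """Increase contrast: I' = A2·(I + B2), A2 ~ Uniform[1.5, 2.5].

    B2 = 127.5/A2 − mean(I) centers the stretched histogram at 127.5 before
    clipping, so the variance scales by exactly A2².
    """
    img = np.asarray(image, dtype=np.float64)
    a2 = float(rng.uniform(1.5, 2.5))
    b2 = 127.5 / a2 - img.mean()
    out, sat = _finalize(a2 * (img + b2))
    return out, TransformDraw("STRETCH", a2=a2, b2=b2, saturation_fraction=sat)


def negate(image: np.ndarray) -> np.ndarray:
    """Pixel-wise complement 255 − I (an exact involution on uint8)."""
    img = np.asarray(image)
    return (255 - img.astype(np.int16)).astype(np.uint8)


def image_histogram(image: np.ndarray, normalize: bool = True) -> IntensityHistogram:
    counts = np.bincount(np.asarray(image, dtype=np.uint8).ravel(), minlength=256).astype(float)
    if normalize:
        counts /= counts.sum()
    return IntensityHistogram(counts, normalize)


def aggregate_histogram(images) -> IntensityHistogram:
    """Normalized mean of per-image normalized histograms."""
    images = list(images)
    if not images:
        raise ValueError("aggregate_histogram requires at least one image")
    acc = np.zeros(256)
    for img in images:
        acc += image_histogram(img).bins
    acc /= len(images)
    acc /= acc.sum()
    return IntensityHistogram(acc, True)
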