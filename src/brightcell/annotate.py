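"""Automatic bounding-box ground truth from FITC + DAPI fluorescence masks.

Manual box annotation is replaced by a three-stage procedure: (1) fluorescent
cell-body signatures in the FITC mask are localized with the circular Hough
transform — the FITC background is far cleaner than the bright-field image,
(2) every localization that does not touch the image boundary is screened in
the DAPI mask, and localizations backed by a nuclear signature are stamped
into an MCF-7 binary mask, (3) every blob in that mask yields one fixed-size
(default 36×36) box centered on the blob centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.measure import label, regionprops
from skimage.transform import hough_circle, hough_circle_peaks

__all__ = [
    "BoundingBox",
    "CircleHit",
    "AnnotationConfig",
    "hough_circles",
    "screen_dapi",
    "blobs_to_bboxes",
    "annotate_image",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open ([x_min, x_min+width) etc.)."""

    x_min: int
    y_min: int
    width: int
    height: int
    image_id: str = ""
    label: str = "MCF7"

    @property
    def x_max(self) -> int:  # exclusive
        return self.x_min + self.width

    @property
    def y_max(self) -> int:  # exclusive
        return self.y_min + self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_min + self.width / 2.0, self.y_min + self.height / 2.0)

    def area(self) -> int:
        return self.width * self.height


@dataclass(frozen=True)
class CircleHit:
    center: tuple[float, float]  # (x, y)
    radius: float
    accumulator_score: float


@dataclass(frozen=True)
class AnnotationConfig:
    radius_range_px: tuple[float, float] = (6.0, 22.0)
    box_size: int = 36
    dapi_threshold: float = 0.5  # mask values above this count as signature
    min_center_distance: float | None = None  # default: r_lo
    accumulator_threshold: float = 0.4  # fraction of max accumulator


def hough_circles(fitc_mask: np.ndarray, radius_range) -> list[CircleHit]:
    """Locate filled fluorescent disks; one hit per disk, sorted by score."""
    r_lo, r_hi = float(radius_range[0]), float(radius_range[1])
    if r_lo <= 0 or r_hi < r_lo:
        raise ValueError(f"invalid radius range [{r_lo}, {r_hi}]")
    mask = np.asarray(fitc_mask) > 0.5
    if not mask.any():
        return []
    edges = canny(mask.astype(float), sigma=1.0)
    radii = np.arange(max(1, int(np.floor(r_lo))), int(np.ceil(r_hi)) + 1)
    acc = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(
        acc,
        radii,
        min_xdistance=int(r_lo),
        min_ydistance=int(r_lo),
        threshold=acc.max() * 0.4,
        num_peaks=np.inf,
        total_num_peaks=np.inf,
    )
    hits = [
        CircleHit((float(x), float(y)), float(r), float(a))
        for a, x, y, r in zip(accums, cxs, cys, rads)
    ]
    # one hit per disk: suppress residual near-duplicates
    hits.sort(key=lambda h: -h.accumulator_score)
    kept: list[CircleHit] = []
    for h in hits:
        if all(
            (h.center[0] - k.center[0]) ** 2 + (h.center[1] - k.center[1]) ** 2 >= r_lo**2
            for k in kept
        ):
            kept.append(h)
    return kept


def screen_dapi(hits, dapi_mask: np.ndarray, image_size=None, threshold: float = 0.5):
    """Screen circle hits against the nuclear (DAPI) mask.

    A hit contributes a blob to the output MCF-7 mask iff its circle does not
    touch the image boundary and at least one DAPI-positive pixel lies
    strictly inside the circle.  Returns the binary MCF-7 mask.
    """
    dapi = np.asarray(dapi_mask)
    h, w = dapi.shape
    if image_size is not None and (w, h) != tuple(image_size):
        raise ValueError("dapi mask dimensions do not match image_size")
    out = np.zeros((h, w), dtype=bool)
    yy, xx = np.ogrid[:h, :w]
    for hit in hits:
        cx, cy = hit.center
        r = hit.radius
        if cx - r < 0 or cy - r < 0 or cx + r > w - 1 or cy + r > h - 1:
            continue  # touches the image boundary
        circle = (xx - cx) ** 2 + (yy - cy) ** 2 < r**2
        if np.any((dapi > threshold) & circle):
            out |= circle
    return out


def blobs_to_bboxes(mcf7_mask: np.ndarray, box_size: int = 36, image_id: str = ""):
    """One centered fixed-size box per connected blob.

    Blob centroids are rounded to the nearest pixel; a box that would extend
    past the image after rounding is dropped.
    """
    mask = np.asarray(mcf7_mask) > 0
    h, w = mask.shape
    half = box_size // 2
    boxes: list[BoundingBox] = []
    for prop in regionprops(label(mask)):
        cy, cx = prop.centroid
        x0 = int(round(cx)) - half
        y0 = int(round(cy)) - half
        if x0 < 0 or y0 < 0 or x0 + box_size > w or y0 + box_size > h:
            continue
        boxes.append(BoundingBox(x0, y0, box_size, box_size, image_id))
    return boxes


def annotate_image(
    bright_field: np.ndarray,
    fitc: np.ndarray,
    dapi: np.ndarray,
    config: AnnotationConfig = AnnotationConfig(),
    image_id: str = "",
):
    """Full auto-annotation: Hough on FITC → DAPI screening → centered boxes."""
    if fitc.shape != dapi.shape:
        raise ValueError("FITC and DAPI masks must share dimensions")
    hits = hough_circles(fitc, config.radius_range_px)
    h, w = dapi.shape
    mcf7_mask = screen_dapi(hits, dapi, (w, h), threshold=config.dapi_threshold)
    return blobs_to_bboxes(mcf7_mask, config.box_size, image_id)
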