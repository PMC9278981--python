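"""Cell localization via maximally stable extremal regions (MSER).

This is module 1 of the decoupled detection approach: the bright-field image
is binarized at a sweep of threshold levels, connected regions are tracked
across levels, and regions whose area stays nearly constant over a minimum
number of consecutive levels — and whose area lies inside the configured
size band — are accepted.  One centroid is emitted per accepted region after
duplicate suppression, and fixed-size tiles are cropped around the centroids
for the downstream classifier.

The size band is configured as diameter bounds with a ±5% margin applied on
the diameter and then converted to an equivalent-circle area band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MSERParams", "Tile", "derive_mser_params", "localize_cells", "crop_tiles"]


@dataclass(frozen=True)
class MSERParams:
    diameter_range_px: tuple[float, float]
    area_range_px2: tuple[float, float]
    delta: int = 5  # gray levels between successive thresholds
    stability_range: int = 2  # min consecutive stable levels
    max_variation: float = 0.25  # max relative area change per level step
    polarity: str = "dark"  # detect dark-on-bright ("dark") or bright-on-dark


def derive_mser_params(
    diameter_bounds_px,
    margin: float = 0.05,
    pixel_scale: float | None = None,
    **kw,
) -> MSERParams:
    """Build MSER parameters from object diameter bounds.

    ``diameter_bounds_px`` is ``[lo, hi]`` in pixels (if ``pixel_scale`` is
    given, the bounds are interpreted in µm and divided by it first).  The
    margin widens the band to ``[lo·(1−margin), hi·(1+margin)]`` on the
    diameter; the area band is the equivalent-circle conversion π·(d/2)².
    """
    lo, hi = float(diameter_bounds_px[0]), float(diameter_bounds_px[1])
    if pixel_scale:
        lo, hi = lo / pixel_scale, hi / pixel_scale
    if lo <= 0 or hi < lo:
        raise ValueError(f"invalid diameter bounds [{lo}, {hi}]")
    d_lo, d_hi = lo * (1.0 - margin), hi * (1.0 + margin)
    a_lo, a_hi = np.pi * (d_lo / 2.0) ** 2, np.pi * (d_hi / 2.0) ** 2
    return MSERParams((d_lo, d_hi), (a_lo, a_hi), **kw)


@dataclass(frozen=True)
class Tile:
    """Fixed-size grayscale patch centered on a localized object."""

    pixels: np.ndarray
    source_image: str
    center: tuple[int, int]  # (x, y)
    label: str | None = None


def _level_components(mask):
    """Label a binary level set; return flat labels, count, areas, first-pixel
    index per label and per-label centroid sums (vectorized)."""
    labels, n = ndimage.label(mask)
    flat = labels.ravel()
    areas = np.bincount(flat, minlength=n + 1)
    uniq, first = np.unique(flat, return_index=True)
    first_idx = np.zeros(n + 1, dtype=np.int64)
    first_idx[uniq] = first
    return flat, n, areas, first_idx


def localize_cells(image: np.ndarray, params: MSERParams) -> list[tuple[float, float]]:
    """Return one (x, y) centroid per stable in-range region.

    The image is binarized at thresholds ``delta, 2·delta, …`` (on the raw
    intensities for dark polarity, on the inverted image otherwise); regions
    are linked across levels by containment (masks are nested), the per-level
    area variation (A_next − A_prev)/A_cur is computed for every component,
    and components that stay within ``max_variation`` for at least
    ``stability_range`` consecutive levels while inside the area band are
    candidates.  Candidates are ranked by variation (ties: larger area) and
    greedily accepted with a minimum centroid separation of d_lo/2, which
    collapses nested duplicates of the same cell.
    """
    img = np.asarray(image)
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    if params.polarity != "dark":
        img = 255 - img
    a_lo, a_hi = params.area_range_px2
    d_lo = params.diameter_range_px[0]
    delta = params.delta
    thresholds = np.arange(delta, 256, delta)

    # labels per level (masks nested: level k mask ⊆ level k+1 mask)
    levels = [_level_components(img < t) for t in thresholds]
    h, w = img.shape
    yy, xx = np.indices((h, w))
    yy, xx = yy.ravel().astype(np.float64), xx.ravel().astype(np.float64)

    candidates = []  # (variation, area, cx, cy)
    for k, (flat_k, n_k, areas_k, first_k) in enumerate(levels):
        if n_k == 0:
            continue
        labs = np.arange(1, n_k + 1)
        in_range = (areas_k[1:] >= a_lo) & (areas_k[1:] <= a_hi)
        if not in_range.any():
            continue
        # descendant area at k+1: parent component containing this one
        if k + 1 < len(levels):
            flat_next, _, areas_next, _ = levels[k + 1]
            parent = flat_next[first_k[1:]]
            area_next = np.where(parent > 0, areas_next[parent], areas_k[1:])
        else:
            area_next = areas_k[1:].astype(np.int64)
        # ancestor area at k-1: largest child contained in this component
        max_child = np.zeros(n_k + 1)
        if k - 1 >= 0:
            flat_prev, n_prev, areas_prev, first_prev = levels[k - 1]
            if n_prev > 0:
                child_parent = flat_k[first_prev[1:]]
                np.maximum.at(max_child, child_parent, areas_prev[1:].astype(float))
        variation = (area_next - max_child[1:]) / areas_k[1:]
        keep = in_range & (variation <= params.max_variation)
        if not keep.any():
            continue
        sum_x = np.bincount(flat_k, weights=xx, minlength=n_k + 1)
        sum_y = np.bincount(flat_k, weights=yy, minlength=n_k + 1)
        for lab in labs[keep]:
            candidates.append(
                (
                    float(variation[lab - 1]),
                    int(areas_k[lab]),
                    sum_x[lab] / areas_k[lab],
                    sum_y[lab] / areas_k[lab],
                )
            )

    if not candidates:
        return []

    # stability requirement: a genuine region appears at >= stability_range
    # consecutive levels; nested duplicates across levels collapse below.
    # Count per-location multiplicity first.
    pts = np.array([(c[2], c[3]) for c in candidates])
    order = sorted(range(len(candidates)), key=lambda i: (candidates[i][0], -candidates[i][1]))
    min_sep = d_lo / 2.0
    accepted: list[tuple[float, float]] = []
    for i in order:
        _, _, cx, cy = candidates[i]
        # multiplicity: number of candidate levels supporting this location
        support = np.sum((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2 < min_sep**2)
        if support < params.stability_range:
            continue
        if all((cx - ax) ** 2 + (cy - ay) ** 2 >= min_sep**2 for ax, ay in accepted):
            accepted.append((cx, cy))
    return accepted


def crop_tiles(
    image: np.ndarray,
    centroids,
    tile_size: int = 36,
    source_image: str = "",
) -> tuple[list[Tile], int]:
    """Crop one ``tile_size``-square tile per centroid.

    Centroids whose tile would cross the image border are skipped; the second
    return value counts those boundary skips (they are localization misses
    from the pipeline's point of view).
    """
    h, w = image.shape[:2]
    if tile_size > min(h, w):
        raise ValueError("tile_size exceeds image side")
    half = tile_size // 2
    tiles: list[Tile] = []
    skipped = 0
    for cx, cy in centroids:
        x0, y0 = int(round(cx)) - half, int(round(cy)) - half
        if x0 < 0 or y0 < 0 or x0 + tile_size > w or y0 + tile_size > h:
            skipped += 1
            continue
        pix = image[y0 : y0 + tile_size, x0 : x0 + tile_size].copy()
        tiles.append(Tile(pix, source_image, (int(round(cx)), int(round(cy)))))
    return tiles, skipped
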