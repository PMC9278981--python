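"""Synthetic bright-field scenes with matched FITC/DAPI masks and exact truth.

Emulates mixed populations of large cancer-line cells (MCF-7-like) and small
leukocytes (WBC-like) imaged in transmitted light: cells appear darker than a
bright background, the large cells carry both a cytoplasmic FITC signature
and a nuclear DAPI signature, the small cells carry DAPI only, and debris
carries neither.  Class mean diameters differ by a factor of two by default
(20 µm vs 10 µm at 0.8 µm/pixel), which is the size contrast the downstream
classifier experiments probe.

Every scene is generated from an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["SceneSpec", "CellRecord", "generate_scene", "make_dataset"]

MCF7, WBC, DEBRIS = "MCF7", "WBC", "DEBRIS"


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Diameters are sampled per class from truncated normals (±3 sd) given in
    micrometres and converted to pixels via ``pixel_scale``.  ``cell_contrast``
    is the signed offset of the cell interior relative to the background; the
    default is negative (cells darker than background).  ``texture_params``
    maps class name to ``(amplitude, correlation_px)`` of the internal
    granularity; the defaults make the large cells coarser and higher-contrast
    than the small ones so that texture alone remains a learnable cue.
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_scale: float = 0.8  # µm per pixel
    n_mcf7: int = 6
    n_wbc: int = 20
    n_debris: int = 4
    mcf7_diameter_um: tuple[float, float] = (20.0, 3.0)  # mean, sd
    wbc_diameter_um: tuple[float, float] = (10.0, 1.5)
    background_level: float = 180.0
    cell_contrast: float = -55.0
    wbc_contrast: float = -45.0
    rim_contrast: float = -35.0  # extra darkening of the cell rim
    texture_params: dict = field(
        default_factory=lambda: {MCF7: (14.0, 2.5), WBC: (7.0, 1.2), DEBRIS: (5.0, 1.0)}
    )
    noise_sd: float = 3.0
    blur_sigma: float = 0.8
    interior_margin_px: float | None = None  # keep circles this far inside the border
    min_gap_px: float = 4.0
    seed: int = 0

    def with_(self, **kw) -> "SceneSpec":
        d = asdict(self)
        d.update(kw)
        return SceneSpec(**d)


@dataclass(frozen=True)
class CellRecord:
    """Ground truth for one rendered object (0-based pixel coordinates)."""

    center: tuple[float, float]  # (x, y)
    diameter_px: float
    cell_class: str
    touches_boundary: bool


def _sample_diameter(rng, mean, sd, n):
    d = rng.normal(mean, sd, size=n)
    return np.clip(d, mean - 3 * sd, mean + 3 * sd)


def _texture(rng, shape, amplitude, corr_px):
    noise = rng.normal(0.0, 1.0, size=shape)
    if corr_px > 0:
        noise = ndimage.gaussian_filter(noise, corr_px)
        noise /= max(noise.std(), 1e-9)
    return amplitude * noise


def _disk_mask(shape, cx, cy, r):
    h, w = shape
    y, x = np.ogrid[:h, :w]
    return (x - cx) ** 2 + (y - cy) ** 2 <= r**2


def _place(rng, spec, diam_px, placed, max_tries=200):
    """Rejection-sample a center keeping a min gap to already placed circles."""
    h, w = spec.image_size_px[1], spec.image_size_px[0]
    r = diam_px / 2.0
    if spec.interior_margin_px is not None:
        lo_x, hi_x = r + spec.interior_margin_px, w - 1 - r - spec.interior_margin_px
        lo_y, hi_y = r + spec.interior_margin_px, h - 1 - r - spec.interior_margin_px
        if hi_x <= lo_x or hi_y <= lo_y:
            raise ValueError("interior margin leaves no room for cell placement")
    else:
        lo_x, hi_x, lo_y, hi_y = 0.0, w - 1.0, 0.0, h - 1.0
    for _ in range(max_tries):
        cx = rng.uniform(lo_x, hi_x)
        cy = rng.uniform(lo_y, hi_y)
        ok = True
        for px, py, pr in placed:
            if (cx - px) ** 2 + (cy - py) ** 2 < (r + pr + spec.min_gap_px) ** 2:
                ok = False
                break
        if ok:
            return cx, cy
    raise RuntimeError(
        f"could not place a cell of diameter {diam_px:.1f}px after {max_tries} tries; "
        "the scene spec is overcrowded"
    )


def generate_scene(spec: SceneSpec):
    """Render one scene.

    Returns
    -------
    bright_field : uint8 (H, W)
    fitc : bool (H, W) — one blob per MCF-7-like cell
    dapi : bool (H, W) — one blob per nucleated cell (MCF-7 and WBC)
    truth : list[CellRecord]
    """
    if min(spec.n_mcf7, spec.n_wbc, spec.n_debris) < 0:
        raise ValueError("object counts must be non-negative")
    rng = np.random.default_rng(spec.seed)
    w, h = spec.image_size_px
    shape = (h, w)
    img = np.full(shape, float(spec.background_level))
    fitc = np.zeros(shape, dtype=bool)
    dapi = np.zeros(shape, dtype=bool)
    truth: list[CellRecord] = []
    placed: list[tuple[float, float, float]] = []

    classes = [MCF7] * spec.n_mcf7 + [WBC] * spec.n_wbc + [DEBRIS] * spec.n_debris
    diam_um = np.concatenate(
        [
            _sample_diameter(rng, *spec.mcf7_diameter_um, spec.n_mcf7),
            _sample_diameter(rng, *spec.wbc_diameter_um, spec.n_wbc),
            _sample_diameter(rng, 4.0, 1.0, spec.n_debris),
        ]
    )
    diam_px = diam_um / spec.pixel_scale

    for cls, d in zip(classes, diam_px):
        cx, cy = _place(rng, spec, d, placed)
        placed.append((cx, cy, d / 2.0))
        r = d / 2.0
        amp, corr = spec.texture_params[cls]
        if cls == DEBRIS:
            # irregular speck: union of a few small offset disks
            body = np.zeros(shape, dtype=bool)
            for _ in range(rng.integers(2, 5)):
                ox, oy = rng.normal(0, r / 2, 2)
                body |= _disk_mask(shape, cx + ox, cy + oy, r * rng.uniform(0.4, 0.8))
            img[body] += spec.cell_contrast * rng.uniform(0.6, 1.0)
        else:
            body = _disk_mask(shape, cx, cy, r)
            rim = body & ~_disk_mask(shape, cx, cy, r * 0.82)
            contrast = spec.cell_contrast if cls == MCF7 else spec.wbc_contrast
            img[body] += contrast
            img[rim] += spec.rim_contrast
            tex = _texture(rng, shape, amp, corr)
            img[body] += tex[body]
            if cls == MCF7:
                fitc |= _disk_mask(shape, cx, cy, r * 0.9)
            dapi |= _disk_mask(shape, cx, cy, r * 0.45)
        touches = (cx - r < 0) or (cy - r < 0) or (cx + r > w - 1) or (cy + r > h - 1)
        truth.append(CellRecord((cx, cy), d, cls, touches))

    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    img += rng.normal(0.0, spec.noise_sd, size=shape)
    bright_field = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return bright_field, fitc, dapi, truth


def truth_to_frame(truth, image_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_id": image_id,
            "x": [round(t.center[0], 2) for t in truth],
            "y": [round(t.center[1], 2) for t in truth],
            "diameter_px": [round(t.diameter_px, 2) for t in truth],
            "cell_class": [t.cell_class for t in truth],
            "touches_boundary": [t.touches_boundary for t in truth],
        }
    )


def make_dataset(spec: SceneSpec, n_images: int, out_dir, seed: int, overwrite: bool = False):
    """Write ``n_images`` scenes (bright-field + FITC + DAPI PNGs) plus truth CSV.

    Per-image seeds are spawned deterministically from ``seed`` so any single
    image can be regenerated in isolation.  Returns the manifest dict (also
    written to ``manifest.json``).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(seed).generate_state(n_images) % (2**31)
    frames = []
    entries = []
    for i, s in enumerate(seeds):
        image_id = f"img_{i:04d}"
        bf, fitc, dapi, truth = generate_scene(spec.with_(seed=int(s)))
        paths = {
            "bright_field": f"{image_id}_bf.png",
            "fitc": f"{image_id}_fitc.png",
            "dapi": f"{image_id}_dapi.png",
        }
        iio.imwrite(out / paths["bright_field"], bf)
        iio.imwrite(out / paths["fitc"], (fitc * 255).astype(np.uint8))
        iio.imwrite(out / paths["dapi"], (dapi * 255).astype(np.uint8))
        frames.append(truth_to_frame(truth, image_id))
        entries.append({"image_id": image_id, "seed": int(s), **paths})
    truth_df = pd.concat(frames, ignore_index=True) if frames else truth_to_frame([], "")
    truth_df.to_csv(out / "truth.csv", index=False)
    manifest = {
        "n_images": n_images,
        "master_seed": seed,
        "spec": asdict(spec),
        "images": entries,
        "truth_csv": "truth.csv",
        "total_mcf7_boxes": int((truth_df["cell_class"] == MCF7).sum()) if len(truth_df) else 0,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
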