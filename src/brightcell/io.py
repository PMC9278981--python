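"""CSV / image round-tripping for boxes, centroids, tiles and histograms.

All coordinates are 0-based pixels with half-open boxes; file formats are the
plain-text ones the CLI emits so results stay diff-able and versionable.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .annotate import BoundingBox
from .detector import Detection
from .mser import Tile
from .transforms import IntensityHistogram

__all__ = [
    "read_image",
    "write_centroids",
    "read_centroids",
    "write_boxes",
    "read_boxes",
    "write_detections",
    "read_detections",
    "write_tiles",
    "read_tiles",
    "write_histogram",
]


def read_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB(A) to grayscale
        img = np.round(img[..., :3].mean(axis=-1)).astype(np.uint8)
    return img


def write_centroids(path, centroids, image_id: str = "") -> None:
    pd.DataFrame(
        {"image_id": image_id, "x": [c[0] for c in centroids], "y": [c[1] for c in centroids]}
    ).to_csv(path, index=False)


def read_centroids(path):
    df = pd.read_csv(path)
    return list(zip(df["x"], df["y"]))


def write_boxes(path, boxes) -> None:
    pd.DataFrame(
        [
            {
                "image_id": b.image_id,
                "x_min": b.x_min,
                "y_min": b.y_min,
                "width": b.width,
                "height": b.height,
                "label": b.label,
            }
            for b in boxes
        ],
        columns=["image_id", "x_min", "y_min", "width", "height", "label"],
    ).to_csv(path, index=False)


def read_boxes(path):
    df = pd.read_csv(path)
    return [
        BoundingBox(int(r.x_min), int(r.y_min), int(r.width), int(r.height), str(r.image_id), str(r.label))
        for r in df.itertuples()
    ]


def write_detections(path, detections) -> None:
    pd.DataFrame(
        [
            {
                "image_id": d.box.image_id,
                "x_min": d.box.x_min,
                "y_min": d.box.y_min,
                "width": d.box.width,
                "height": d.box.height,
                "score": d.score,
            }
            for d in detections
        ],
        columns=["image_id", "x_min", "y_min", "width", "height", "score"],
    ).to_csv(path, index=False)


def read_detections(path):
    df = pd.read_csv(path)
    return [
        Detection(
            BoundingBox(int(r.x_min), int(r.y_min), int(r.width), int(r.height), str(r.image_id)),
            float(r.score),
        )
        for r in df.itertuples()
    ]


def write_tiles(out_dir, tiles) -> Path:
    """PNG per tile plus an index CSV (tile_id,image_id,x,y,label)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(tiles):
        tile_id = f"tile_{i:05d}"
        iio.imwrite(out / f"{tile_id}.png", np.asarray(t.pixels, dtype=np.uint8))
        rows.append(
            {
                "tile_id": tile_id,
                "image_id": t.source_image,
                "x": t.center[0],
                "y": t.center[1],
                "label": t.label or "",
            }
        )
    pd.DataFrame(rows, columns=["tile_id", "image_id", "x", "y", "label"]).to_csv(
        out / "index.csv", index=False
    )
    return out / "index.csv"


def read_tiles(tiles_dir):
    d = Path(tiles_dir)
    df = pd.read_csv(d / "index.csv", keep_default_na=False)
    tiles = []
    for r in df.itertuples():
        pix = read_image(d / f"{r.tile_id}.png")
        tiles.append(Tile(pix, str(r.image_id), (int(r.x), int(r.y)), str(r.label) or None))
    return tiles


def write_histogram(path, hist: IntensityHistogram) -> None:
    pd.DataFrame({"intensity": np.arange(256), "frequency": hist.bins}).to_csv(path, index=False)
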