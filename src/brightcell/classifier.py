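"""Tile labeling, CNN training/inference, and the tile-resizing operators.

This is module 2 of the decoupled approach.  Tiles produced by the MSER
localizer are labeled from fluorescence: a tile is the target class (MCF7)
iff both a FITC and a DAPI signature fall in the tile's central region;
everything else — small DAPI-only cells, debris, background junk — is
NON_MCF7.  A shallow CNN (2 or 3 conv layers, 5×5 kernels, 2×2 pooling,
one fully connected layer) is trained with Adam on the labeled tiles.

``resize_tiles`` implements the size-equalization operators used to probe
whether the classifier relies on cell size: enlarge-then-crop (e.g. double
the small-cell tiles) and shrink-then-crop (halve the large-cell tiles down
to a 15×15 input).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize

from .mser import Tile
from .nn import SmallCNN

__all__ = [
    "ClassifierConfig",
    "TrainReport",
    "label_tiles",
    "train_classifier",
    "classify_tiles",
    "resize_tiles",
    "LABELS",
]

LABELS = ("NON_MCF7", "MCF7")  # index = class id


@dataclass(frozen=True)
class ClassifierConfig:
    n_conv_layers: int = 3
    kernel_size: int = 5
    pool_size: int = 2
    input_side: int = 36
    n_classes: int = 2
    channels: tuple = (16, 32, 64)
    epochs: int = 35
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass(frozen=True)
class TrainReport:
    train_sensitivity: float
    train_precision: float
    train_accuracy: float
    epochs_run: int
    wall_time: float


def label_tiles(tiles, fitc: np.ndarray, dapi: np.ndarray, central_fraction: float = 1 / 3):
    """Assign MCF7 / NON_MCF7 labels from the fluorescence masks.

    The decision region is the central ``central_fraction`` of the tile
    around its center; the label is MCF7 iff both masks have at least one
    positive pixel there.  Pure function of the masks — no randomness.
    """
    if fitc.shape != dapi.shape:
        raise ValueError("FITC and DAPI masks must share dimensions")
    h, w = fitc.shape
    out = []
    for t in tiles:
        side = t.pixels.shape[0]
        half = max(1, int(round(side * central_fraction / 2)))
        cx, cy = t.center
        x0, x1 = max(0, cx - half), min(w, cx + half + 1)
        y0, y1 = max(0, cy - half), min(h, cy + half + 1)
        has_fitc = bool(np.any(fitc[y0:y1, x0:x1] > 0.5))
        has_dapi = bool(np.any(dapi[y0:y1, x0:x1] > 0.5))
        out.append(replace(t, label="MCF7" if has_fitc and has_dapi else "NON_MCF7"))
    return out


def _stack(tiles):
    return np.stack([np.asarray(t.pixels, dtype=np.float64) for t in tiles])


def train_classifier(tiles, config: ClassifierConfig = ClassifierConfig()):
    """Train the shallow CNN on labeled tiles; returns (model, TrainReport)."""
    import time

    tiles = list(tiles)
    labels = np.array([LABELS.index(t.label) for t in tiles])
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes to be present")
    sides = {t.pixels.shape for t in tiles}
    if sides != {(config.input_side, config.input_side)}:
        raise ValueError(f"all tiles must be {config.input_side}x{config.input_side}")
    model = SmallCNN(
        input_side=config.input_side,
        n_conv_layers=config.n_conv_layers,
        channels=config.channels,
        kernel_size=config.kernel_size,
        n_classes=config.n_classes,
        seed=config.seed,
    )
    x = _stack(tiles)
    t0 = time.perf_counter()
    model.fit(
        x,
        labels,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
    )
    wall = time.perf_counter() - t0
    pred = model.predict_scores(x).argmax(axis=1)
    pos = LABELS.index("MCF7")
    tp = int(np.sum((pred == pos) & (labels == pos)))
    fn = int(np.sum((pred != pos) & (labels == pos)))
    fp = int(np.sum((pred == pos) & (labels != pos)))
    report = TrainReport(
        train_sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        train_precision=tp / (tp + fp) if tp + fp else float("nan"),
        train_accuracy=float(np.mean(pred == labels)),
        epochs_run=config.epochs,
        wall_time=wall,
    )
    return model, report


def classify_tiles(model: SmallCNN, tiles):
    """Return one (label, score_vector) per tile; label is the argmax class."""
    tiles = list(tiles)
    if not tiles:
        return []
    sides = {t.pixels.shape for t in tiles}
    if sides != {(model.input_side, model.input_side)}:
        raise ValueError(f"tiles must be {model.input_side}x{model.input_side}")
    scores = model.predict_scores(_stack(tiles))
    return [(LABELS[int(s.argmax())], s) for s in scores]


def resize_tiles(tiles, factor: float, out_side: int, mode: str | None = None):
    """Rescale tile contents by ``factor`` and center-crop to ``out_side``.

    With factor > 1 this enlarges the imaged cell then crops back to the
    network input (the small-cell doubling experiment); with factor < 1 it
    shrinks the cell (the large-cell halving experiment, typically combined
    with a 15×15 input).  Bilinear interpolation; raises if the scaled tile
    is smaller than ``out_side``.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    out = []
    for t in tiles:
        side = t.pixels.shape[0]
        new_side = int(round(side * factor))
        if new_side < out_side:
            raise ValueError(
                f"scaled side {new_side} smaller than requested crop {out_side}"
            )
        if factor != 1.0:
            scaled = resize(
                np.asarray(t.pixels, dtype=np.float64),
                (new_side, new_side),
                order=1,
                anti_aliasing=factor < 1.0,
                preserve_range=True,
            )
        else:
            scaled = np.asarray(t.pixels, dtype=np.float64)
        off = (new_side - out_side) // 2
        crop = scaled[off : off + out_side, off : off + out_side]
        out.append(replace(t, pixels=crop))
    return out
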