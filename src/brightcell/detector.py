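"""Desk-scale box detector honoring the two-stage training contract.

The production-scale reference for this task is a region-proposal detector
with a deep residual backbone; at desk scale we keep its *training
contract* — a single square anchor size matched to the fixed 36×36
ground-truth boxes, positive anchors at IoU ∈ [0.6, 1] with some ground
truth, negative anchors at IoU ∈ [0, 0.5], anchors in the (0.5, 0.6) gap
excluded from the loss, 30 training epochs — and score anchors with a small
conv net over a dense anchor grid, followed by score thresholding and
non-maximum suppression.

Images are standardized globally (zero mean, unit variance over the whole
frame) before anchor windows are cropped.  Global standardization cancels
uniform brightness shifts and contrast stretches while preserving the
within-image contrast differences between cell classes, so the detector is
robust to those transforms but *not* to contrast-polarity reversal — the
robustness profile the photometric stress tests probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import BoundingBox
from .evaluation import iou
from .nn import SmallCNN

__all__ = [
    "DetectorConfig",
    "Detection",
    "DetectorTrainReport",
    "anchor_grid",
    "assign_anchors",
    "train_detector",
    "detect",
    "nms",
]


@dataclass(frozen=True)
class DetectorConfig:
    negative_overlap: tuple[float, float] = (0.0, 0.5)
    positive_overlap: tuple[float, float] = (0.6, 1.0)
    epochs: int = 30
    anchor_size_px: int = 36
    anchor_stride_px: int = 4
    backbone: str = "smallcnn-3"
    channels: tuple = (8, 16, 32)
    score_threshold: float = 0.5
    nms_iou: float = 0.3
    neg_pos_ratio: float = 2.0
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        for rng_ in (self.negative_overlap, self.positive_overlap):
            if not (0.0 <= rng_[0] <= rng_[1] <= 1.0):
                raise ValueError("overlap ranges must lie within [0, 1]")
        if self.negative_overlap[1] >= self.positive_overlap[0]:
            raise ValueError("negative upper bound must be below positive lower bound")


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    score: float


@dataclass(frozen=True)
class DetectorTrainReport:
    mean_iou: float  # mean IoU of matched training detections vs ground truth
    mean_score: float  # mean score of those detections
    n_positive_anchors: int
    n_negative_anchors: int
    epochs_run: int


def anchor_grid(image_shape, size: int, stride: int):
    """All fully-inside anchor boxes on a regular grid; returns (N, 2) of
    (x_min, y_min)."""
    h, w = image_shape[:2]
    xs = np.arange(0, w - size + 1, stride)
    ys = np.arange(0, h - size + 1, stride)
    gx, gy = np.meshgrid(xs, ys)
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def _max_iou_fixed(anchors_xy: np.ndarray, gt_boxes, size: int) -> np.ndarray:
    """Max IoU of each size×size anchor against the ground-truth boxes."""
    best = np.zeros(len(anchors_xy))
    for g in gt_boxes:
        ix = np.minimum(anchors_xy[:, 0] + size, g.x_max) - np.maximum(anchors_xy[:, 0], g.x_min)
        iy = np.minimum(anchors_xy[:, 1] + size, g.y_max) - np.maximum(anchors_xy[:, 1], g.y_min)
        inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
        union = size * size + g.area() - inter
        np.maximum(best, inter / union, out=best)
    return best


def assign_anchors(anchors_xy: np.ndarray, gt_boxes, config: DetectorConfig) -> np.ndarray:
    """Label each anchor: 1 positive, 0 negative, -1 ignored (overlap gap)."""
    best = _max_iou_fixed(anchors_xy, gt_boxes, config.anchor_size_px)
    out = np.full(len(anchors_xy), -1, dtype=np.int8)
    neg_lo, neg_hi = config.negative_overlap
    pos_lo, pos_hi = config.positive_overlap
    out[(best >= neg_lo) & (best <= neg_hi)] = 0
    out[(best >= pos_lo) & (best <= pos_hi)] = 1
    return out


def _standardize_image(image: np.ndarray) -> np.ndarray:
    x = np.asarray(image, dtype=np.float64)
    return (x - x.mean()) / max(x.std(), 1e-6)


def _crop_windows(image, anchors_xy, size):
    return np.stack(
        [image[y : y + size, x : x + size] for x, y in anchors_xy]
    ).astype(np.float64)


def train_detector(images, annotations, config: DetectorConfig = DetectorConfig(), diagnostics: bool = True):
    """Train the anchor-scoring net.

    ``images`` is a list of 8-bit grayscale arrays, ``annotations`` the
    matching list of ground-truth box lists.  Positive anchors from every
    image are pooled with a sampled multiple of negatives and fed to the
    conv net as standardized windows.  Returns (model, DetectorTrainReport);
    the report's mean IoU / mean score are computed by running detection on
    the training images and matching to ground truth.
    """
    if not any(len(a) for a in annotations):
        raise ValueError("training requires at least one annotated box")
    rng = np.random.default_rng(config.seed)
    size = config.anchor_size_px
    pos_windows, neg_windows = [], []
    for raw_img, boxes in zip(images, annotations):
        img = _standardize_image(raw_img)
        anchors = anchor_grid(img.shape, size, config.anchor_stride_px)
        lab = assign_anchors(anchors, boxes, config)
        pos_xy = anchors[lab == 1]
        neg_xy = anchors[lab == 0]
        n_each = int(np.ceil(max(len(pos_xy), 1) * config.neg_pos_ratio)) + 4
        if len(neg_xy):
            # hard negatives: windows whose *central* region carries the most
            # object mass — these are the non-target cells and debris the
            # detector must learn to reject (full-window mass would instead
            # select windows grazing a target cell)
            ii = np.abs(img - np.median(img))
            csum = np.pad(ii.cumsum(0).cumsum(1), ((1, 0), (1, 0)))
            core = size // 3
            off = (size - core) // 2
            x, y = neg_xy[:, 0] + off, neg_xy[:, 1] + off
            mass = (
                csum[y + core, x + core]
                - csum[y, x + core]
                - csum[y + core, x]
                + csum[y, x]
            )
            hard_idx = np.argsort(-mass)[: min(n_each, len(neg_xy))]
            rest = np.setdiff1d(np.arange(len(neg_xy)), hard_idx)
            n_rand = min(len(rest), n_each)
            rand_idx = (
                rest[rng.choice(len(rest), size=n_rand, replace=False)]
                if n_rand
                else rest[:0]
            )
            neg_xy = neg_xy[np.concatenate([hard_idx, rand_idx])]
        if len(pos_xy):
            pos_windows.append(_crop_windows(img, pos_xy, size))
        if len(neg_xy):
            neg_windows.append(_crop_windows(img, neg_xy, size))
    pos = np.concatenate(pos_windows) if pos_windows else np.zeros((0, size, size))
    neg = np.concatenate(neg_windows) if neg_windows else np.zeros((0, size, size))
    x = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    model = SmallCNN(
        input_side=size,
        n_conv_layers=3,
        channels=config.channels,
        n_classes=2,
        seed=config.seed,
        input_mode="raw",
    )
    model.fit(
        x, y, epochs=config.epochs, batch_size=config.batch_size,
        learning_rate=config.learning_rate,
    )
    # training diagnostics: detect on training images, match to ground truth
    ious, scores = [], []
    if diagnostics:
        for img, boxes in zip(images, annotations):
            for det in detect(model, img, config):
                best = max((iou(det.box, g) for g in boxes), default=0.0)
                if best > 0.5:
                    ious.append(best)
                    scores.append(det.score)
    report = DetectorTrainReport(
        mean_iou=float(np.mean(ious)) if ious else float("nan"),
        mean_score=float(np.mean(scores)) if scores else float("nan"),
        n_positive_anchors=int(len(pos)),
        n_negative_anchors=int(len(neg)),
        epochs_run=config.epochs,
    )
    return model, report


def nms(detections, iou_threshold: float):
    """Greedy non-maximum suppression on score-sorted detections."""
    dets = sorted(detections, key=lambda d: -d.score)
    kept: list[Detection] = []
    for d in dets:
        if all(iou(d.box, k.box) <= iou_threshold for k in kept):
            kept.append(d)
    return kept


def detect(
    model: SmallCNN,
    image: np.ndarray,
    config: DetectorConfig = DetectorConfig(),
    apply_nms: bool = True,
    image_id: str = "",
):
    """Score every anchor window; threshold, optionally NMS, sort by score."""
    size = config.anchor_size_px
    anchors = anchor_grid(image.shape, size, config.anchor_stride_px)
    if len(anchors) == 0:
        return []
    image = _standardize_image(image)
    raw: list[Detection] = []
    chunk = 512
    for i in range(0, len(anchors), chunk):
        sub = anchors[i : i + chunk]
        windows = _crop_windows(image, sub, size)
        probs = model.predict_scores(windows)[:, 1]
        for (x, y), p in zip(sub, probs):
            if p >= config.score_threshold:
                raw.append(
                    Detection(BoundingBox(int(x), int(y), size, size, image_id), float(p))
                )
    if apply_nms:
        raw = nms(raw, config.nms_iou)
    return sorted(raw, key=lambda d: -d.score)
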