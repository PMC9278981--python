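"""Detection/classification accounting: TP/FN/FP semantics and derived metrics.

Two evaluation modes exist.  *Detector mode* matches predicted boxes to
ground-truth boxes greedily by descending score at an IoU threshold
(strictly greater than 0.5 by default) and splits false positives into
redundant boxes on an already-matched cell versus boxes on non-target
objects.  *Decoupled mode* matches localized centroids to truth cell centers
and splits false negatives into localization misses (cell never localized)
versus classification misses (localized but labeled non-target) — the split
the decoupled architecture exists to expose.

Sensitivity, precision and F1 are reported as percentages; undefined
denominators yield NaN rather than a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .annotate import BoundingBox

__all__ = [
    "EvalReport",
    "iou",
    "match_detections",
    "decoupled_confusion",
    "compute_metrics",
    "f1_from_rates",
    "fn_attribution",
    "robustness_report",
]


@dataclass
class EvalReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    fn_localization: int | None = None
    fn_classification: int | None = None
    fp_redundant: int | None = None
    fp_nonmcf7: int | None = None
    sensitivity: float = field(default=math.nan)
    precision: float = field(default=math.nan)
    f1: float = field(default=math.nan)

    def __post_init__(self):
        self.refresh()

    def refresh(self) -> "EvalReport":
        if self.fn_localization is not None and self.fn_classification is not None:
            assert self.fn == self.fn_localization + self.fn_classification
        if self.fp_redundant is not None and self.fp_nonmcf7 is not None:
            assert self.fp == self.fp_redundant + self.fp_nonmcf7
        self.sensitivity, self.precision, self.f1 = compute_metrics(self.tp, self.fn, self.fp)
        return self

    def __add__(self, other: "EvalReport") -> "EvalReport":
        def opt(a, b):
            return None if a is None or b is None else a + b

        return EvalReport(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            fn_localization=opt(self.fn_localization, other.fn_localization),
            fn_classification=opt(self.fn_classification, other.fn_classification),
            fp_redundant=opt(self.fp_redundant, other.fp_redundant),
            fp_nonmcf7=opt(self.fp_nonmcf7, other.fp_nonmcf7),
        )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two half-open pixel boxes."""
    if a.width <= 0 or a.height <= 0 or b.width <= 0 or b.height <= 0:
        raise ValueError("degenerate (zero-area) box")
    ix = max(0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area() + b.area() - inter
    return inter / union


def compute_metrics(tp: int, fn: int, fp: int):
    """(sensitivity %, precision %, F1 %); NaN where the denominator is 0."""
    if min(tp, fn, fp) < 0:
        raise ValueError("counts must be non-negative")
    sens = 100.0 * tp / (tp + fn) if tp + fn > 0 else math.nan
    prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else math.nan
    f1 = f1_from_rates(sens, prec)
    return sens, prec, f1


def f1_from_rates(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision (both on the same scale)."""
    if math.isnan(sensitivity) or math.isnan(precision):
        return math.nan
    if sensitivity + precision == 0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def fn_attribution(fn_localization: int, fn_classification: int) -> float:
    """Fraction of all false negatives attributable to the localization stage."""
    total = fn_localization + fn_classification
    if total <= 0:
        raise ValueError("no false negatives to attribute")
    return fn_localization / total


def match_detections(detections, truth_boxes, iou_threshold: float = 0.5) -> EvalReport:
    """Greedy score-descending one-to-one matching of detections to truth.

    A detection whose best overlap exceeds the threshold with an *unmatched*
    truth box is a TP; if every over-threshold truth box is already matched
    it is a redundant FP; with no over-threshold truth at all it is a
    non-target FP.  IoU comparisons are strict (> threshold).  Ties on equal
    IoU break toward the earlier truth box in input order.
    """
    dets = sorted(detections, key=lambda d: -d.score)
    matched = [False] * len(truth_boxes)
    tp = fp_red = fp_non = 0
    for det in dets:
        best_iou, best_j = 0.0, -1
        overlaps_any = False
        for j, t in enumerate(truth_boxes):
            v = iou(det.box, t)
            if v > iou_threshold:
                overlaps_any = True
                if not matched[j] and v > best_iou:
                    best_iou, best_j = v, j
        if best_j >= 0:
            matched[best_j] = True
            tp += 1
        elif overlaps_any:
            fp_red += 1
        else:
            fp_non += 1
    fn = matched.count(False)
    return EvalReport(
        tp=tp, fp=fp_red + fp_non, fn=fn, fp_redundant=fp_red, fp_nonmcf7=fp_non
    )


def decoupled_confusion(
    centroids,
    predictions,
    truth_records,
    match_radius_px: float = 18.0,
    target_class: str = "MCF7",
) -> EvalReport:
    """Score the decoupled pipeline on one scene.

    ``centroids`` are localized (x, y) points, ``predictions`` the classifier
    labels for those points (same order; entries may be None for centroids
    whose tile was skipped at the boundary), ``truth_records`` the scene's
    CellRecord list.  Truth target cells with no centroid inside
    ``match_radius_px`` count as localization FNs; localized targets
    predicted non-target count as classification FNs; localized non-target
    objects predicted as target count as FPs.
    """
    centroids = list(centroids)
    predictions = list(predictions)
    if len(centroids) != len(predictions):
        raise ValueError("one prediction per centroid required")
    targets = [t for t in truth_records if t.cell_class == target_class]
    used = [False] * len(centroids)
    tp = fn_loc = fn_cls = 0
    for t in targets:
        tx, ty = t.center
        best_i, best_d = -1, math.inf
        for i, (cx, cy) in enumerate(centroids):
            d = math.hypot(cx - tx, cy - ty)
            if not used[i] and d <= match_radius_px and d < best_d:
                best_i, best_d = i, d
        if best_i < 0:
            fn_loc += 1
        else:
            used[best_i] = True
            if predictions[best_i] == target_class:
                tp += 1
            elif predictions[best_i] is None:
                # localized, but its tile was dropped (e.g. at the border):
                # the cell never reached the classifier
                fn_loc += 1
            else:
                fn_cls += 1
    fp = sum(
        1
        for i, pred in enumerate(predictions)
        if not used[i] and pred == target_class
    )
    return EvalReport(
        tp=tp, fp=fp, fn=fn_loc + fn_cls, fn_localization=fn_loc, fn_classification=fn_cls
    )


def robustness_report(evaluate_fn, variants) -> "pd.DataFrame":
    """Evaluate one model across dataset variants.

    ``variants`` is an iterable of ``(name, images, truth_boxes_per_image)``;
    ``evaluate_fn(images, truths)`` must return an EvalReport.  Returns a
    table with one row per variant (dataset, tp, fn, fp, sensitivity,
    precision, f1).
    """
    import pandas as pd

    rows = []
    for name, images, truths in variants:
        rep = evaluate_fn(images, truths)
        rows.append(
            {
                "dataset": name,
                "tp": rep.tp,
                "fn": rep.fn,
                "fp": rep.fp,
                "sensitivity": rep.sensitivity,
                "precision": rep.precision,
                "f1": rep.f1,
            }
        )
    return pd.DataFrame(rows)
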