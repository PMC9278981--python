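import math

import numpy as np
import pytest

from brightcell.annotate import BoundingBox
from brightcell.detector import Detection
from brightcell.evaluation import (
    compute_metrics,
    decoupled_confusion,
    f1_from_rates,
    fn_attribution,
    iou,
    match_detections,
)
from brightcell.scenes import CellRecord


def box(x, y, w=36, h=36):
    return BoundingBox(x, y, w, h)


class TestIoU:
    def test_identical_boxes(self):
        assert iou(box(10, 10), box(10, 10)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(box(0, 0), box(100, 100)) == 0.0

    def test_half_horizontal_offset_is_one_third(self):
        assert iou(box(0, 0), box(18, 0)) == pytest.approx(648 / 1944)

    def test_degenerate_box_raises(self):
        with pytest.raises(ValueError):
            iou(box(0, 0, 0, 10), box(0, 0))


class TestComputeMetrics:
    def test_integrated_detector_row(self):
        s, p, _ = compute_metrics(1945, 17, 4)
        assert round(s, 1) == 99.1
        assert round(p, 1) == 99.8

    def test_decoupled_row(self):
        s, p, _ = compute_metrics(1869, 71 + 22, 4)
        assert round(s, 1) == 95.3
        assert round(p, 1) == 99.8

    def test_f1_harmonic_mean_values(self):
        assert round(f1_from_rates(99.1, 99.8), 2) == 99.45
        assert f1_from_rates(80.0, 80.0) == pytest.approx(80.0)

    def test_undefined_denominators_are_nan(self):
        s, p, f = compute_metrics(0, 0, 5)
        assert math.isnan(s) and math.isnan(f)
        s, p, f = compute_metrics(0, 5, 0)
        assert math.isnan(p) and math.isnan(f)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0)


class TestFnAttribution:
    def test_localization_dominates(self):
        frac = fn_attribution(71, 22)
        assert frac == pytest.approx(71 / 93)
        assert frac > 0.75

    @pytest.mark.parametrize("loc,cls,expect", [(0, 5, 0.0), (5, 0, 1.0)])
    def test_extremes(self, loc, cls, expect):
        assert fn_attribution(loc, cls) == expect

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            fn_attribution(0, 0)


class TestMatchDetections:
    def test_single_match_above_threshold(self):
        rep = match_detections([Detection(box(4, 0), 0.9)], [box(0, 0)])
        assert (rep.tp, rep.fn, rep.fp) == (1, 0, 0)

    def test_redundant_detection_on_matched_truth(self):
        dets = [Detection(box(0, 0), 0.95), Detection(box(4, 0), 0.80)]
        rep = match_detections(dets, [box(0, 0)])
        assert rep.tp == 1 and rep.fp_redundant == 1 and rep.fp_nonmcf7 == 0

    def test_low_iou_counts_fn_and_nontarget_fp(self):
        rep = match_detections([Detection(box(24, 0), 0.9)], [box(0, 0)])  # IoU = 1/5
        assert (rep.tp, rep.fn, rep.fp_nonmcf7) == (0, 1, 1)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        truths = [box(0, 0), box(100, 100), box(60, 180)]
        dets = [
            Detection(box(2, 2), 0.97),
            Detection(box(104, 98), 0.81),
            Detection(box(200, 10), 0.65),
            Detection(box(58, 182), 0.59),
        ]
        base = match_detections(dets, truths)
        for _ in range(5):
            shuffled = list(rng.permutation(len(dets)))
            rep = match_detections([dets[i] for i in shuffled], truths)
            assert (rep.tp, rep.fn, rep.fp) == (base.tp, base.fn, base.fp)

    def _brute_force_tp(self, dets, truths, thr=0.5):
        """Maximum one-to-one matching cardinality (assignment oracle)."""
        if not dets or not truths:
            return 0
        from scipy.optimize import linear_sum_assignment

        w = np.array(
            [[1.0 if iou(d.box, t) > thr else 0.0 for t in truths] for d in dets]
        )
        ri, ci = linear_sum_assignment(w, maximize=True)
        return int(w[ri, ci].sum())

    def test_greedy_agrees_with_bruteforce_on_small_scenes(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n_t = rng.integers(0, 5)
            n_d = rng.integers(0, 6)
            truths = [box(int(x), int(y)) for x, y in rng.integers(0, 200, (n_t, 2))]
            dets = [
                Detection(box(int(x), int(y)), float(s))
                for (x, y), s in zip(
                    rng.integers(0, 200, (n_d, 2)), rng.uniform(0.5, 1, n_d)
                )
            ]
            rep = match_detections(dets, truths)
            assert rep.tp == self._brute_force_tp(dets, truths)
            assert rep.fn == len(truths) - rep.tp
            assert rep.fp == len(dets) - rep.tp


class TestDecoupledConfusion:
    def _cell(self, x, y, cls="MCF7"):
        return CellRecord((x, y), 25.0, cls, False)

    def test_fn_split_and_fp_accounting(self):
        # 3 truth MCF7: one not localized, one localized but misclassified,
        # one correct; plus a WBC localized and called MCF7 (FP)
        truth = [
            self._cell(50, 50),
            self._cell(150, 50),
            self._cell(100, 150),
            self._cell(200, 200, "WBC"),
        ]
        centroids = [(151, 50), (100, 149), (200, 201)]
        preds = ["NON_MCF7", "MCF7", "MCF7"]
        rep = decoupled_confusion(centroids, preds, truth, match_radius_px=18)
        assert rep.tp == 1
        assert rep.fn_localization == 1
        assert rep.fn_classification == 1
        assert rep.fp == 1
        assert rep.fn == 2

    def test_empty_scene_all_zero(self):
        rep = decoupled_confusion([], [], [])
        assert (rep.tp, rep.fn, rep.fp) == (0, 0, 0)

    def test_boundary_skipped_tile_counts_as_localization_miss(self):
        truth = [self._cell(10, 50)]
        rep = decoupled_confusion([(10, 50)], [None], truth)
        assert rep.fn_localization == 1 and rep.fn_classification == 0
        assert rep.tp == 0

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            decoupled_confusion([(0, 0)], [], [])
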