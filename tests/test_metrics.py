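"""Segmentation metrics, detection protocol and the weighted loss.

Worked examples are frozen from hand set-arithmetic; batch implementations
are cross-checked against scalar-loop references on random masks.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from esfpnet.metrics import (
    DetectionCounts,
    boundary_weights,
    dataset_summary,
    dice,
    evaluate_frame,
    filter_significant,
    iou,
    label_regions,
    mae,
    match_regions,
    precision,
    recall,
    weighted_seg_loss,
)
from esfpnet.nn import Tensor


def _mask(rows):
    return np.array(rows, dtype=np.uint8)


class TestPixelMetrics:
    def test_identity_scores_one(self):
        a = _mask([[1, 0], [1, 1]])
        assert dice(a, a) == 1.0 and iou(a, a) == 1.0

    def test_disjoint_scores_zero(self):
        a = _mask([[1, 0], [0, 0]])
        b = _mask([[0, 0], [0, 1]])
        assert dice(a, b) == 0.0 and iou(a, b) == 0.0

    def test_partial_overlap_set_arithmetic(self):
        # |A|=2, |B|=1, |A∩B|=1 -> Dice 2/3, IoU 1/2
        a = _mask([[1, 1], [0, 0]])
        b = _mask([[1, 0], [0, 0]])
        assert dice(a, b) == pytest.approx(2 / 3)
        assert iou(a, b) == pytest.approx(1 / 2)

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), np.uint8)
        assert dice(z, z) == 1.0 and iou(z, z) == 1.0
        assert dice(z, z, empty_value=0.0) == 0.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            dice(_mask([[2, 0]]), _mask([[1, 0]]))

    def test_mae_worked_cases(self):
        g = _mask([[1, 0], [0, 1]])
        assert mae(g, g) == 0.0
        assert mae(1 - g, g) == 1.0
        p = np.array([[0.5, 0.0], [1.0, 1.0]])
        assert mae(p, g) == pytest.approx((0.5 + 0 + 1.0 + 0) / 4)

    @given(st.integers(0, 2**32 - 1))
    def test_dice_iou_identity_and_ordering(self, seed):
        rng = np.random.default_rng(seed)
        a = (rng.random((12, 12)) > 0.6).astype(np.uint8)
        b = (rng.random((12, 12)) > 0.6).astype(np.uint8)
        d, j = dice(a, b), iou(a, b)
        assert 0.0 <= j <= d <= 1.0
        assert d == pytest.approx(2 * j / (1 + j))


class TestRegions:
    def test_empty_mask_has_no_regions(self):
        assert label_regions(np.zeros((4, 4), np.uint8)) == []

    def test_full_mask_is_one_region(self):
        regions = label_regions(np.ones((4, 4), np.uint8))
        assert len(regions) == 1 and regions[0].area == 16

    def test_diagonal_pixels_depend_on_connectivity(self):
        m = _mask([[1, 0], [0, 1]])
        assert len(label_regions(m, connectivity=2)) == 1  # 8-connected
        assert len(label_regions(m, connectivity=1)) == 2  # 4-connected

    def test_areas_sum_to_mask_total(self, rng):
        m = (rng.random((32, 32)) > 0.7).astype(np.uint8)
        assert sum(r.area for r in label_regions(m)) == m.sum()

    def test_significance_filter_boundary(self):
        m = np.zeros((60, 60), np.uint8)
        m[0:19, 0:21] = 1  # 399 px
        m[30:50, 30:50] = 1  # 400 px
        regions = label_regions(m)
        kept = filter_significant(regions)
        assert [r.area for r in kept] == [400]
        assert filter_significant(regions, min_area=0) == regions

    def test_sweep_retains_nested_subsets(self, rng):
        m = (rng.random((80, 80)) > 0.72).astype(np.uint8)
        regions = label_regions(m)
        kept = [
            {r.label for r in filter_significant(regions, t)} for t in (100, 400, 800)
        ]
        assert kept[2] <= kept[1] <= kept[0]


class TestMatching:
    def test_one_prediction_covers_one_of_two_gt(self):
        gt = np.zeros((20, 20), np.uint8)
        gt[0:3, 0:3] = 1
        gt[10:13, 10:13] = 1
        pred = np.zeros((20, 20), np.uint8)
        pred[1:4, 1:4] = 1
        c = match_regions(label_regions(pred), label_regions(gt), gt.shape)
        assert (c.tp, c.fn, c.fp) == (1, 1, 0)

    def test_prediction_on_normal_frame_is_false_positive(self):
        pred = np.zeros((10, 10), np.uint8)
        pred[2:5, 2:5] = 1
        c = match_regions(label_regions(pred), [], pred.shape)
        assert (c.tp, c.fn, c.fp) == (0, 0, 1)

    def test_empty_everything(self):
        c = match_regions([], [], (8, 8))
        assert (c.tp, c.fp, c.fn) == (0, 0, 0)

    def test_one_prediction_spanning_two_gt_counts_both(self):
        gt = np.zeros((10, 30), np.uint8)
        gt[4:6, 2:6] = 1
        gt[4:6, 20:24] = 1
        pred = np.zeros((10, 30), np.uint8)
        pred[4:6, 0:30] = 1
        c = match_regions(label_regions(pred), label_regions(gt), gt.shape)
        assert (c.tp, c.fn, c.fp) == (2, 0, 0)

    def test_gt_region_conservation_on_random_masks(self, rng):
        for _ in range(50):
            gt = (rng.random((24, 24)) > 0.75).astype(np.uint8)
            pred = (rng.random((24, 24)) > 0.75).astype(np.uint8)
            gtr = label_regions(gt)
            c = match_regions(label_regions(pred), gtr, gt.shape)
            assert c.tp + c.fn == len(gtr)


class TestDetectionRates:
    def test_paper_style_counts(self):
        assert recall(DetectionCounts(tp=110, fn=7)) == pytest.approx(0.940, abs=5e-4)
        assert recall(DetectionCounts(tp=111, fn=6)) == pytest.approx(0.949, abs=5e-4)

    def test_vacuous_counts_score_one(self):
        c = DetectionCounts()
        assert recall(c) == 1.0 and precision(c) == 1.0

    def test_precision_counts_false_positives(self):
        c = DetectionCounts(tp=3, fp=1, fn=0)
        assert precision(c) == pytest.approx(0.75)


class TestWeightedLoss:
    def test_perfect_prediction_limit(self):
        gt = np.zeros((1, 1, 16, 16), np.float32)
        gt[0, 0, 4:10, 4:10] = 1
        logits = Tensor(np.where(gt > 0, 30.0, -30.0).astype(np.float32))
        loss = weighted_seg_loss(logits, gt)
        assert loss.item() < 1e-3
        assert loss.wiou >= 0 and loss.wbce >= 0

    def test_uniform_background_reduces_to_plain_bce(self, rng):
        gt = np.zeros((1, 1, 8, 8), np.float32)  # weights collapse to 1
        x = rng.standard_normal((1, 1, 8, 8)).astype(np.float32)
        loss = weighted_seg_loss(Tensor(x), gt)
        plain = np.mean(np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x))))
        assert loss.wbce == pytest.approx(plain, rel=1e-5)

    def test_scalar_loop_oracle_on_toy_mask(self):
        """4x4 mask + fixed logits against an elementwise reference that
        re-derives the pooled weights, BCE and weighted IoU by hand."""
        gt = np.zeros((4, 4), np.float32)
        gt[1:3, 1:3] = 1
        logits = np.linspace(-2, 2, 16, dtype=np.float32).reshape(4, 4)
        k, pad = 31, 15
        w = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                acc = 0.0
                for di in range(-pad, pad + 1):
                    for dj in range(-pad, pad + 1):
                        if 0 <= i + di < 4 and 0 <= j + dj < 4:
                            acc += gt[i + di, j + dj]
                w[i, j] = 1 + 5 * abs(acc / (k * k) - gt[i, j])
        sig = 1 / (1 + np.exp(-logits))
        bce = -(gt * np.log(sig) + (1 - gt) * np.log(1 - sig))
        wbce = (w * bce).sum() / w.sum()
        inter = (w * sig * gt).sum()
        union = (w * (sig + gt)).sum()
        wiou = 1 - (inter + 1) / (union - inter + 1)
        loss = weighted_seg_loss(Tensor(logits[None, None]), gt[None, None])
        assert loss.item() == pytest.approx(wbce + wiou, rel=1e-4)

    def test_boundary_weights_emphasise_edges(self):
        gt = np.zeros((1, 1, 64, 64), np.float32)
        gt[0, 0, 16:48, 16:48] = 1
        w = boundary_weights(gt)[0, 0]
        assert w[31, 16] > w[31, 31]  # edge pixel outweighs interior
        assert w.min() >= 1.0 and w.max() <= 6.0

    def test_gradient_step_reduces_loss(self, rng):
        gt = np.zeros((1, 1, 8, 8), np.float32)
        gt[0, 0, 2:6, 2:6] = 1
        x = Tensor(rng.standard_normal((1, 1, 8, 8)).astype(np.float32), requires_grad=True)
        loss = weighted_seg_loss(x, gt)
        loss.total.backward()
        x2 = Tensor(x.data - 0.5 * x.grad)
        assert weighted_seg_loss(x2, gt).item() < loss.item()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="vs"):
            weighted_seg_loss(Tensor(np.zeros((1, 1, 4, 4))), np.zeros((1, 1, 8, 8)))


class TestAggregation:
    def test_single_frame_summary_equals_frame(self):
        row = {"dice": 0.8, "iou": 0.7, "mae": 0.1, "tp": 2, "fp": 1, "fn": 0}
        s = dataset_summary([row])
        assert s.mdice == 0.8 and s.miou == 0.7 and s.mae == 0.1
        assert s.recall == 1.0 and s.precision == pytest.approx(2 / 3)

    def test_two_frame_mean(self):
        rows = [
            {"dice": 0.0, "iou": 0.0, "mae": 0.5, "tp": 0, "fp": 0, "fn": 1},
            {"dice": 1.0, "iou": 1.0, "mae": 0.0, "tp": 1, "fp": 0, "fn": 0},
        ]
        s = dataset_summary(rows)
        assert s.mdice == 0.5
        assert s.recall == pytest.approx(0.5)

    def test_pooled_counts_match_per_frame_sums(self, rng):
        rows = []
        total = DetectionCounts()
        for _ in range(3):
            gt = (rng.random((20, 20)) > 0.8).astype(np.uint8)
            pred = (rng.random((20, 20)) > 0.8).astype(np.uint8)
            row = evaluate_frame(pred, gt, min_area=1)
            rows.append(row)
            total += DetectionCounts(row["tp"], row["fp"], row["fn"])
        s = dataset_summary(rows)
        assert (s.counts.tp, s.counts.fp, s.counts.fn) == (
            total.tp,
            total.fp,
            total.fn,
        )

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError, match="no frames"):
            dataset_summary([])
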