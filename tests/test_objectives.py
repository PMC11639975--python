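import itertools

import numpy as np
import pytest

from exactnet.imgio import Box3D
from exactnet.objectives import (
    FocalParams,
    average_precision,
    cross_entropy,
    dice_loss,
    dsc,
    dual_seg_loss,
    focal_loss,
    iou3d,
    smooth_l1,
)

from .conftest import random_boxes


def brute_force_max_matching(preds, truth, thr):
    """Oracle: exhaustive enumeration of one-to-one assignments; max TP."""
    best = 0
    idx = range(len(truth))
    for k in range(min(len(preds), len(truth)), 0, -1):
        for pred_sub in itertools.combinations(range(len(preds)), k):
            for perm in itertools.permutations(idx, k):
                if all(iou3d(preds[i], truth[j]) >= thr for i, j in zip(pred_sub, perm)):
                    return k
    return best


def brute_force_iou(a, b, grid=40):
    """Oracle: voxel-by-voxel counting."""
    ga = np.zeros((grid,) * 3, bool)
    gb = np.zeros((grid,) * 3, bool)
    ga[a.slices()] = True
    gb[b.slices()] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union if union else 0.0


class TestSegLosses:
    def test_perfect_prediction_is_zero(self):
        y = np.zeros((2, 4, 4, 4), np.float64)
        y[1, 1:3, 1:3, 1:3] = 1
        y[0] = 1 - y[1]
        assert dual_seg_loss(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_masks_dice_is_one(self):
        p = np.zeros((8,) * 3)
        y = np.zeros((8,) * 3)
        p[:2] = 1
        y[6:] = 1
        assert dice_loss(p, y) == pytest.approx(1.0, abs=1e-6)

    def test_half_overlap_dice(self):
        # |p| = |y| = n, overlap n/2 -> Dice loss 1 - 2(n/2)/(2n) = 0.5
        p = np.zeros((8, 8, 8))
        y = np.zeros((8, 8, 8))
        p[0:4, 0, 0] = 1
        y[2:6, 0, 0] = 1
        assert dice_loss(p, y) == pytest.approx(0.5, abs=1e-6)

    def test_dice_decreases_with_agreement(self):
        y = np.zeros((6, 6, 6))
        y[2:4, 2:4, 2:4] = 1
        worse = np.clip(y - 0.4, 0, 1)
        better = np.clip(y - 0.1, 0, 1)
        assert dice_loss(better, y) < dice_loss(worse, y)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            cross_entropy(np.zeros((2, 4)), np.zeros((2, 5)))


class TestSmoothL1:
    @staticmethod
    def boxes_with_mae(mae):
        a = [Box3D(lo=(0, 0, 0), hi=(4, 4, 4))]
        b = [Box3D(lo=tuple(int(mae) for _ in range(3)), hi=tuple(4 + int(mae) for _ in range(3)))]
        return a, b

    @pytest.mark.parametrize("mae, expected", [(0, 0.0), (1, 0.5), (3, 2.5)])
    def test_known_values(self, mae, expected):
        a, b = self.boxes_with_mae(mae)
        assert smooth_l1(a, b, delta=1.0) == pytest.approx(expected)

    def test_continuous_at_delta(self):
        # the two branches agree at MAE = delta
        delta = 1.0
        quad = 0.5 * delta * delta / delta
        lin = delta - 0.5 * delta
        assert quad == pytest.approx(lin)
        a, b = self.boxes_with_mae(1)
        below = smooth_l1([Box3D((0, 0, 0), (4, 4, 4))], [Box3D((0, 0, 0), (4, 4, 5))], delta=1.0)
        assert below < smooth_l1(a, b, delta=1.0)

    def test_monotone_in_mae(self):
        vals = [smooth_l1(*self.boxes_with_mae(m), delta=1.0) for m in (0, 1, 2, 3, 5)]
        assert vals == sorted(vals)

    def test_printed_variant_matches_at_delta_one(self):
        a, b = self.boxes_with_mae(1)
        assert smooth_l1(a, b, delta=1.0) == smooth_l1(a, b, delta=1.0, as_printed=True)

    def test_empty_pairing_raises(self):
        with pytest.raises(ValueError):
            smooth_l1([], [])


class TestFocalLoss:
    def test_perfect_positive_is_zero(self):
        assert focal_loss(1.0, 1.0) == pytest.approx(0.0, abs=1e-5)

    def test_derived_value(self):
        # -0.25 * (0.5)^2 * log 0.5
        expected = -0.25 * 0.25 * np.log(0.5)
        assert focal_loss(0.5, 1.0, FocalParams(alpha=0.25, gamma=2.0)) == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(0.04332, abs=5e-6)

    def test_gamma_zero_reduces_to_half_bce(self):
        fp = FocalParams(alpha=0.5, gamma=0.0)
        for p in np.linspace(0.01, 0.99, 25):
            for y in (0.0, 1.0):
                bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
                assert focal_loss(p, y, fp) == pytest.approx(0.5 * bce, rel=1e-4)


class TestDSC:
    def test_identical_nonempty(self):
        x = np.zeros((5, 5, 5), bool)
        x[1:3] = True
        assert dsc(x, x) == 1.0

    def test_disjoint(self):
        x = np.zeros((5, 5, 5), bool)
        y = np.zeros((5, 5, 5), bool)
        x[0] = True
        y[4] = True
        assert dsc(x, y) == 0.0

    def test_half_overlap(self):
        x = np.zeros(200, bool).reshape(2, 10, 10)
        y = x.copy()
        x.flat[0:100] = True
        y.flat[50:150] = True
        assert dsc(x, y) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3, 3), bool)
        assert dsc(z, z) == 1.0

    def test_iou_identity(self):
        # DSC == 2 IoU / (1 + IoU) for any mask pair
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.random((6, 6, 6)) < 0.4
            y = rng.random((6, 6, 6)) < 0.4
            union = (x | y).sum()
            if union == 0:
                continue
            iou = (x & y).sum() / union
            assert dsc(x, y) == pytest.approx(2 * iou / (1 + iou), abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(6)
        x = rng.random((5, 5, 5)) < 0.3
        y = rng.random((5, 5, 5)) < 0.3
        assert dsc(x, y) == dsc(y, x)

    def test_printed_form_is_half(self):
        x = np.ones((2, 2, 2), bool)
        assert dsc(x, x, printed_form=True) == pytest.approx(0.5)


class TestIoU3D:
    def test_identical(self):
        b = Box3D(lo=(0, 0, 0), hi=(3, 3, 3))
        assert iou3d(b, b) == 1.0

    def test_disjoint(self):
        assert iou3d(Box3D((0, 0, 0), (2, 2, 2)), Box3D((5, 5, 5), (7, 7, 7))) == 0.0

    def test_unit_cube_shift(self):
        # [0,2)^3 vs [1,3)^3: intersection 1, union 15
        a = Box3D((0, 0, 0), (2, 2, 2))
        b = Box3D((1, 1, 1), (3, 3, 3))
        assert iou3d(a, b) == pytest.approx(1 / 15)
        assert iou3d(a, b) == pytest.approx(brute_force_iou(a, b))

    def test_matches_voxel_counting_on_random_boxes(self):
        rng = np.random.default_rng(7)
        boxes = random_boxes(rng, 12)
        for a, b in itertools.combinations(boxes, 2):
            assert iou3d(a, b) == pytest.approx(brute_force_iou(a, b), abs=1e-12)


class TestAveragePrecision:
    def test_perfect_predictions(self):
        truth = [Box3D((0, 0, 0), (4, 4, 4)), Box3D((10, 10, 10), (14, 14, 14))]
        preds = [Box3D(b.lo, b.hi, score=0.9) for b in truth]
        ev, precision, ap = average_precision(preds, truth, 0.5)
        assert precision == 1.0 and ap == pytest.approx(1.0)
        assert ev.tp == 2 and ev.fp == 0 and ev.fn == 0

    def test_three_correct_one_spurious(self):
        truth = [Box3D((i * 10, 0, 0), (i * 10 + 4, 4, 4)) for i in range(3)]
        preds = [Box3D(b.lo, b.hi, score=0.8) for b in truth]
        preds.append(Box3D((0, 20, 20), (4, 24, 24), score=0.7))
        _, precision, _ = average_precision(preds, truth, 0.5)
        assert precision == pytest.approx(0.75)

    def test_empty_predictions(self):
        truth = [Box3D((0, 0, 0), (2, 2, 2))]
        ev, precision, ap = average_precision([], truth, 0.5)
        assert precision == 0.0 and ap == 0.0 and ev.fn == 1

    def test_matching_equals_brute_force_oracle(self):
        # all instances up to 5 predictions x 5 truths, several seeds
        rng = np.random.default_rng(11)
        for trial in range(60):
            preds = random_boxes(rng, int(rng.integers(0, 6)), grid=14, max_side=6)
            truth = [
                Box3D(b.lo, b.hi) for b in random_boxes(rng, int(rng.integers(0, 6)), grid=14, max_side=6)
            ]
            thr = float(rng.choice([0.3, 0.5, 0.7]))
            ev, _, _ = average_precision(preds, truth, thr)
            assert ev.tp == brute_force_max_matching(preds, truth, thr)
            assert ev.tp + ev.fp == len(preds)
            assert ev.tp + ev.fn == len(truth)

    def test_each_truth_matched_at_most_once(self):
        truth = [Box3D((0, 0, 0), (4, 4, 4))]
        preds = [Box3D((0, 0, 0), (4, 4, 4), score=s) for s in (0.9, 0.8, 0.7)]
        ev, precision, _ = average_precision(preds, truth, 0.5)
        assert ev.tp == 1 and ev.fp == 2
        assert precision == pytest.approx(1 / 3)
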