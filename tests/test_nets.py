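import numpy as np
import pytest

from exactnet.imgio import Box3D
from exactnet.nets import (
    NetConfig,
    build_detector,
    build_segmenter,
    decode_detections,
    det_loss_and_grad,
    nms,
    seg_loss_and_grad,
)
from exactnet.nets._nn import Adam
from exactnet.nets.retina import DetectionOutput, LevelOutput, _level_anchors


def tiny_seg_cfg(**kw):
    base = dict(base_channels=4, depth=3, n_classes=2, patch_size=32, anchor_sizes_mm=(8.0,), seed=0)
    base.update(kw)
    return NetConfig(**base)


class TestNetConfig:
    def test_patch_depth_divisibility_enforced(self):
        with pytest.raises(ValueError, match="incompatible"):
            NetConfig(depth=4, patch_size=36)

    def test_depth_minimum(self):
        with pytest.raises(ValueError):
            NetConfig(depth=1)


class TestSegmenter:
    def test_output_shape_and_normalization(self):
        model = build_segmenter(tiny_seg_cfg())
        x = np.random.default_rng(0).random((1, 32, 32, 32), dtype=np.float32)
        p = model.predict_proba(x)
        assert p.shape == (2, 32, 32, 32)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-5)
        assert p.min() >= 0.0

    @pytest.mark.parametrize("side", [32, 48, 64, 96])
    def test_accepts_any_divisible_patch_size(self, side):
        model = build_segmenter(tiny_seg_cfg(base_channels=2))
        x = np.zeros((1, side, side, side), np.float32)
        assert model.predict_proba(x).shape == (2, side, side, side)

    def test_anisotropic_input_accepted(self):
        # the lobe variant runs on axially coarser grids: shape (16, 32, 32)
        model = build_segmenter(tiny_seg_cfg(base_channels=2, n_classes=6))
        p = model.predict_proba(np.zeros((1, 16, 32, 32), np.float32))
        assert p.shape == (6, 16, 32, 32)

    def test_incompatible_patch_raises(self):
        model = build_segmenter(tiny_seg_cfg())
        with pytest.raises(ValueError, match="divisible"):
            model.predict_proba(np.zeros((1, 30, 30, 30), np.float32))

    def test_desk_scale_parameter_count(self):
        model = build_segmenter(tiny_seg_cfg())
        assert model.n_parameters() < 10**5

    def test_seed_determinism(self):
        a = build_segmenter(tiny_seg_cfg(seed=5))
        b = build_segmenter(tiny_seg_cfg(seed=5))
        for name in a.params:
            np.testing.assert_array_equal(a.params[name].value, b.params[name].value)

    def test_checkpoint_round_trip(self, tmp_path):
        model = build_segmenter(tiny_seg_cfg(seed=3))
        model.save(tmp_path / "seg.npz")
        back = model.load(tmp_path / "seg.npz")
        x = np.random.default_rng(1).random((1, 32, 32, 32), dtype=np.float32)
        np.testing.assert_array_equal(model.predict_proba(x), back.predict_proba(x))

    def test_gradient_matches_finite_differences(self):
        cfg = NetConfig(base_channels=2, depth=2, n_classes=2, patch_size=8, anchor_sizes_mm=(8.0,), seed=2)
        m = build_segmenter(cfg)
        rng = np.random.default_rng(1)
        x = rng.random((1, 8, 8, 8), dtype=np.float32)
        y = np.zeros((2, 8, 8, 8), np.float32)
        y[1, 2:5, 2:5, 2:5] = 1
        y[0] = 1 - y[1]
        logits, cache = m.forward(x, train=True)
        _, dl = seg_loss_and_grad(logits, y)
        m.zero_grad()
        m.backward(dl, cache)
        eps = 1e-3
        for name in ("enc0a.w", "dec0b.w", "out.w"):
            par = m.params[name]
            idx = (0, 1)
            par.value[idx] += eps
            l1, _ = seg_loss_and_grad(m.forward(x)[0], y)
            par.value[idx] -= 2 * eps
            l2, _ = seg_loss_and_grad(m.forward(x)[0], y)
            par.value[idx] += eps
            assert (l1 - l2) / (2 * eps) == pytest.approx(par.grad[idx], rel=0.05, abs=1e-4)


class TestDetector:
    def det_cfg(self, **kw):
        base = dict(base_channels=4, depth=4, n_classes=2, patch_size=32, anchor_sizes_mm=(8.0, 16.0), seed=0)
        base.update(kw)
        return NetConfig(**base)

    def test_three_pyramid_levels_at_strides_4_8_16(self):
        cfg = NetConfig(
            base_channels=2, depth=5, n_classes=2, patch_size=96, anchor_sizes_mm=(8.0, 16.0, 32.0), seed=0
        )
        det = build_detector(cfg)
        out = det.predict(np.zeros((1, 96, 96, 96), np.float32))
        assert [lv.stride for lv in out.levels] == [4, 8, 16]
        assert len(out.levels) == 3
        for lv in out.levels:
            assert lv.deltas.shape == (len(lv.logits), 6)
            assert len(lv.anchors) == len(lv.logits)

    def test_zero_weights_give_half_probability(self):
        det = build_detector(self.det_cfg())
        for p in det.params.values():
            p.value[...] = 0.0
        out = det.predict(np.zeros((1, 32, 32, 32), np.float32))
        for lv in out.levels:
            np.testing.assert_allclose(lv.probs, 0.5)

    def test_seed_determinism(self):
        a = build_detector(self.det_cfg(seed=7))
        b = build_detector(self.det_cfg(seed=7))
        for name in a.params:
            np.testing.assert_array_equal(a.params[name].value, b.params[name].value)

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            build_detector(self.det_cfg(anchor_sizes_mm=()))

    def test_probabilities_in_unit_interval(self):
        det = build_detector(self.det_cfg())
        out = det.predict(np.random.default_rng(0).random((1, 32, 32, 32), dtype=np.float32))
        for lv in out.levels:
            assert np.all(lv.probs >= 0) and np.all(lv.probs <= 1)

    def test_gradient_matches_finite_differences(self):
        cfg = NetConfig(base_channels=2, depth=3, n_classes=2, patch_size=16, anchor_sizes_mm=(8.0,), seed=4)
        det = build_detector(cfg)
        x = np.random.default_rng(2).random((1, 16, 16, 16), dtype=np.float32)
        gt = [Box3D(lo=(4, 4, 4), hi=(12, 12, 12))]
        out, cache = det.forward(x, train=True)
        _, dlog, ddel = det_loss_and_grad(out, gt)
        det.zero_grad()
        det.backward(out, dlog, ddel, cache)
        eps = 1e-3
        for name in ("enc0a.w", "lat2.w", "cls_out.w", "reg_h.w"):
            par = det.params[name]
            idx = (0, 1)

            def f():
                o, _ = det.forward(x)
                return det_loss_and_grad(o, gt)[0]

            par.value[idx] += eps
            l1 = f()
            par.value[idx] -= 2 * eps
            l2 = f()
            par.value[idx] += eps
            assert (l1 - l2) / (2 * eps) == pytest.approx(par.grad[idx], rel=0.05, abs=1e-4)

    def test_training_step_reduces_loss_on_fixed_patch(self):
        cfg = NetConfig(base_channels=2, depth=3, n_classes=2, patch_size=16, anchor_sizes_mm=(8.0,), seed=0)
        det = build_detector(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((1, 16, 16, 16), dtype=np.float32)
        x[0, 5:12, 5:12, 5:12] += 1.0
        gt = [Box3D(lo=(5, 5, 5), hi=(12, 12, 12))]
        opt = Adam(lr=3e-3)
        first = det.train_step(x, gt, opt)
        for _ in range(40):
            last = det.train_step(x, gt, opt)
        assert last < first


class TestDecodeAndNMS:
    @staticmethod
    def synthetic_output(entries, shape=(32, 32, 32), stride=4, size=8.0):
        """Build a DetectionOutput with chosen anchor probabilities."""
        grid = tuple(s // stride for s in shape)
        anchors = _level_anchors(grid, stride, size)
        n = len(anchors)
        logits = np.full(n, -10.0, np.float32)
        deltas = np.zeros((n, 6), np.float32)
        for idx, logit in entries:
            logits[idx] = logit
        lv = LevelOutput(
            stride=stride, anchor_size=size, grid_shape=grid, logits=logits, deltas=deltas, anchors=anchors
        )
        return DetectionOutput(input_shape=shape, levels=[lv])

    def test_identical_boxes_suppressed_to_highest_score(self):
        a = Box3D((0, 0, 0), (4, 4, 4), score=0.9)
        b = Box3D((0, 0, 0), (4, 4, 4), score=0.8)
        kept = nms([a, b], 0.5)
        assert kept == [a]

    def test_disjoint_boxes_all_kept(self):
        boxes = [
            Box3D((0, 0, 0), (4, 4, 4), score=0.6),
            Box3D((10, 10, 10), (14, 14, 14), score=0.9),
        ]
        kept = nms(boxes, 0.0)
        assert len(kept) == 2
        assert kept[0].score == 0.9  # sorted by descending score

    def test_no_anchor_above_threshold(self):
        out = self.synthetic_output([])
        assert decode_detections(out, 0.5, 0.1) == []

    def test_decode_recovers_anchor_box(self):
        out = self.synthetic_output([(0, 10.0)])  # first anchor, prob ~1
        (box,) = decode_detections(out, 0.5, 0.1)
        assert box.lo == (0, 0, 0)  # anchor centered at (2,2,2), size 8, clipped
        assert box.score > 0.99

    def test_nms_idempotent(self):
        rng = np.random.default_rng(3)
        from .conftest import random_boxes

        boxes = random_boxes(rng, 10)
        once = nms(boxes, 0.2)
        assert nms(once, 0.2) == once
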