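"""Retina-UNet3D: single-stage 3D detector on a UNet encoder + FPN.

The detector shares the UNet3D encoder and attaches a feature-pyramid
decoder to the encoder outputs.  Pyramid levels sit at strides >= 4; each
level carries one cubic anchor per cell (edge length from
``anchor_sizes_mm``) and a pair of shared heads: a classification head
producing an objectness probability per anchor and a regression head
producing six box deltas (center offsets and log-scale extents, both
relative to the anchor edge).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ..imgio import Box3D
from ..objectives import EPS, FocalParams, iou3d
from . import _nn
from ._nn import Adam, Param
from .config import NetConfig

__all__ = [
    "DetectionModel",
    "DetectionOutput",
    "LevelOutput",
    "build_detector",
    "decode_detections",
    "nms",
    "det_loss_and_grad",
]

MIN_HEAD_STRIDE = 4


@dataclass
class LevelOutput:
    """Flattened per-anchor outputs of one pyramid level."""

    stride: int
    anchor_size: float
    grid_shape: tuple[int, int, int]
    logits: np.ndarray  # (N,)
    deltas: np.ndarray  # (N, 6): (dz, dy, dx, log sz, log sy, log sx)
    anchors: np.ndarray  # (N, 6): (z0, y0, x0, z1, y1, x1) float voxel coords

    @property
    def probs(self) -> np.ndarray:
        return _nn.sigmoid(self.logits)


@dataclass
class DetectionOutput:
    """All pyramid levels for one input patch."""

    input_shape: tuple[int, int, int]
    levels: list[LevelOutput] = field(default_factory=list)


def _level_anchors(grid_shape: tuple[int, int, int], stride: int, size: float) -> np.ndarray:
    axes = [(np.arange(s) + 0.5) * stride for s in grid_shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    centers = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3)
    half = size / 2.0
    return np.concatenate([centers - half, centers + half], axis=1).astype(np.float32)


class DetectionModel:
    """Desk-scale Retina-UNet3D over numpy."""

    def __init__(self, cfg: NetConfig):
        if not cfg.anchor_sizes_mm:
            raise ValueError("anchor size list must not be empty")
        self.cfg = cfg
        self.head_levels = [l for l in range(cfg.depth) if 2**l >= MIN_HEAD_STRIDE]
        if not self.head_levels:
            raise ValueError(f"depth {cfg.depth} yields no pyramid level at stride >= {MIN_HEAD_STRIDE}")
        if len(cfg.anchor_sizes_mm) != len(self.head_levels):
            raise ValueError(
                f"need one anchor size per pyramid level: got {len(cfg.anchor_sizes_mm)} sizes "
                f"for {len(self.head_levels)} levels (strides {[2**l for l in self.head_levels]})"
            )
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, Param] = {}
        ch = [cfg.channels(l) for l in range(cfg.depth)]
        for l in range(cfg.depth):
            cin = cfg.in_channels if l == 0 else ch[l - 1]
            self._add3(f"enc{l}a", cin, ch[l], rng)
            self._add3(f"enc{l}b", ch[l], ch[l], rng)
        self.fpn_channels = min(cfg.base_channels * 4, 32)
        for l in self.head_levels:
            self._add1(f"lat{l}", ch[l], self.fpn_channels, rng)
            self._add3(f"smooth{l}", self.fpn_channels, self.fpn_channels, rng)
        self._add3("cls_h", self.fpn_channels, self.fpn_channels, rng)
        self._add1("cls_out", self.fpn_channels, 1, rng)
        self._add3("reg_h", self.fpn_channels, self.fpn_channels, rng)
        self._add1("reg_out", self.fpn_channels, 6, rng)
        # most anchors are background: bias the objectness prior low so the
        # focal loss is not dominated by easy negatives early in training
        self.params["cls_out.b"].value[...] = -2.0

    def _add3(self, name, cin, cout, rng):
        w, b = _nn.he_conv3(cin, cout, rng)
        self.params[f"{name}.w"], self.params[f"{name}.b"] = w, b

    def _add1(self, name, cin, cout, rng):
        w, b = _nn.he_conv1(cin, cout, rng)
        self.params[f"{name}.w"], self.params[f"{name}.b"] = w, b

    def parameters(self) -> list[Param]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    # -- forward ------------------------------------------------------------

    def _conv3(self, h, name, cache, train):
        w, b = self.params[f"{name}.w"], self.params[f"{name}.b"]
        h, c = _nn.conv3_forward(h, w, b, keep_cache=train)
        cache[name] = c
        return h

    def _conv1(self, h, name, cache, train):
        w, b = self.params[f"{name}.w"], self.params[f"{name}.b"]
        h, c = _nn.conv1_forward(h, w, b, keep_cache=train)
        cache[name] = c
        return h

    def _act(self, h, key, cache, train):
        h, c = _nn.lrelu_forward(h, keep_cache=train)
        cache[key] = c
        return h

    def forward(self, x: np.ndarray, train: bool = False):
        div = 2 ** (self.cfg.depth - 1)
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(f"expected ({self.cfg.in_channels}, D, H, W) input, got {x.shape}")
        if any(s % div for s in x.shape[1:]):
            raise ValueError(f"input sides {x.shape[1:]} must be divisible by {div}")
        h = np.ascontiguousarray(x, dtype=np.float32)
        cache: dict = {"enc": {}, "pool": {}, "fpn": {}, "heads": {}}
        feats: dict[int, np.ndarray] = {}
        for l in range(self.cfg.depth):
            c: dict = {}
            h = self._conv3(h, f"enc{l}a", c, train)
            h = self._act(h, "acta", c, train)
            h = self._conv3(h, f"enc{l}b", c, train)
            h = self._act(h, "actb", c, train)
            cache["enc"][l] = c
            feats[l] = h
            if l < self.cfg.depth - 1:
                h, cache["pool"][l] = _nn.avgpool2_forward(h)

        # FPN top-down
        pyramid: dict[int, np.ndarray] = {}
        for l in reversed(self.head_levels):
            c = {}
            p = self._conv1(feats[l], f"lat{l}", c, train)
            deeper = [d for d in self.head_levels if d > l]
            if deeper:
                p = p + _nn.upsample2_forward(pyramid[min(deeper)])[0]
            pyramid[l] = p
            cache["fpn"][l] = c

        out = DetectionOutput(input_shape=tuple(int(s) for s in x.shape[1:]))
        for i, l in enumerate(self.head_levels):
            c = {}
            f = self._conv3(pyramid[l], f"smooth{l}", c, train)
            f = self._act(f, "smooth.act", c, train)
            hc = self._conv3(f, "cls_h", c, train)
            hc = self._act(hc, "cls.act", c, train)
            logits = self._conv1(hc, "cls_out", c, train)
            hr = self._conv3(f, "reg_h", c, train)
            hr = self._act(hr, "reg.act", c, train)
            deltas = self._conv1(hr, "reg_out", c, train)
            cache["heads"][l] = c
            stride = 2**l
            grid = tuple(int(s) for s in logits.shape[1:])
            out.levels.append(
                LevelOutput(
                    stride=stride,
                    anchor_size=float(self.cfg.anchor_sizes_mm[i]),
                    grid_shape=grid,
                    logits=logits.reshape(-1),
                    deltas=np.ascontiguousarray(deltas.transpose(1, 2, 3, 0)).reshape(-1, 6),
                    anchors=_level_anchors(grid, stride, float(self.cfg.anchor_sizes_mm[i])),
                )
            )
        return out, (cache if train else None)

    # -- backward -----------------------------------------------------------

    def backward(self, out: DetectionOutput, dlogits: list[np.ndarray], ddeltas: list[np.ndarray], cache) -> None:
        """Accumulate gradients given flattened per-level output gradients."""
        dpyr: dict[int, np.ndarray] = {}
        for i, l in enumerate(self.head_levels):
            c = cache["heads"][l]
            grid = out.levels[i].grid_shape
            dlog = dlogits[i].reshape(1, *grid).astype(np.float32)
            ddel = np.ascontiguousarray(ddeltas[i].reshape(*grid, 6).transpose(3, 0, 1, 2)).astype(np.float32)
            dhc = _nn.conv1_backward(dlog, self.params["cls_out.w"], self.params["cls_out.b"], c["cls_out"])
            dhc = _nn.lrelu_backward(dhc, c["cls.act"])
            df = _nn.conv3_backward(dhc, self.params["cls_h.w"], self.params["cls_h.b"], c["cls_h"])
            dhr = _nn.conv1_backward(ddel, self.params["reg_out.w"], self.params["reg_out.b"], c["reg_out"])
            dhr = _nn.lrelu_backward(dhr, c["reg.act"])
            df = df + _nn.conv3_backward(dhr, self.params["reg_h.w"], self.params["reg_h.b"], c["reg_h"])
            df = _nn.lrelu_backward(df, c["smooth.act"])
            dp = _nn.conv3_backward(df, self.params[f"smooth{l}.w"], self.params[f"smooth{l}.b"], c[f"smooth{l}"])
            dpyr[l] = dpyr.get(l, 0) + dp

        dfeat: dict[int, np.ndarray] = {}
        for l in self.head_levels:  # shallow -> deep: propagate top-down additions
            dp = dpyr[l]
            deeper = [d for d in self.head_levels if d > l]
            if deeper:
                dn = min(deeper)
                dpyr[dn] = dpyr.get(dn, 0) + _nn.upsample2_backward(dp)
            dfeat[l] = _nn.conv1_backward(
                dp, self.params[f"lat{l}.w"], self.params[f"lat{l}.b"], cache["fpn"][l][f"lat{l}"]
            )

        dh: np.ndarray | None = None
        for l in range(self.cfg.depth - 1, -1, -1):
            if dh is None:
                dcur = dfeat.get(l)
                if dcur is None:
                    continue
            else:
                dcur = _nn.avgpool2_backward(dh, cache["pool"][l])
                if l in dfeat:
                    dcur = dcur + dfeat[l]
            c = cache["enc"][l]
            dcur = _nn.lrelu_backward(dcur, c["actb"])
            dcur = _nn.conv3_backward(dcur, self.params[f"enc{l}b.w"], self.params[f"enc{l}b.b"], c[f"enc{l}b"])
            dcur = _nn.lrelu_backward(dcur, c["acta"])
            dh = _nn.conv3_backward(dcur, self.params[f"enc{l}a.w"], self.params[f"enc{l}a.b"], c[f"enc{l}a"])

    def train_step(self, x: np.ndarray, gt_boxes: list[Box3D], opt: Adam, fp: FocalParams = FocalParams()) -> float:
        self.zero_grad()
        out, cache = self.forward(x, train=True)
        loss, dlogits, ddeltas = det_loss_and_grad(out, gt_boxes, fp)
        self.backward(out, dlogits, ddeltas, cache)
        opt.step(self.parameters())
        return loss

    def predict(self, x: np.ndarray) -> DetectionOutput:
        out, _ = self.forward(x, train=False)
        return out

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {name: p.value for name, p in self.params.items()}
        np.savez(path, __config__=np.frombuffer(json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DetectionModel":
        with np.load(path) as data:
            cfg = NetConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            for name, p in model.params.items():
                p.value[...] = data[name]
        return model


def build_detector(cfg: NetConfig) -> DetectionModel:
    """Factory for the Retina-UNet3D detection model contract."""
    return DetectionModel(cfg)


# ---------------------------------------------------------------------------
# decoding and suppression


def _decode_level(level: LevelOutput, shape: tuple[int, int, int], score_threshold: float) -> list[Box3D]:
    p = level.probs
    keep = np.nonzero(p >= score_threshold)[0]
    boxes: list[Box3D] = []
    size = level.anchor_size
    for i in keep:
        a = level.anchors[i]
        ac = (a[:3] + a[3:]) / 2.0
        d = level.deltas[i]
        center = ac + d[:3] * size
        ext = size * np.exp(np.clip(d[3:], -4.0, 4.0))
        lo = np.floor(center - ext / 2.0 + 0.5).astype(int)
        hi = np.floor(center + ext / 2.0 + 0.5).astype(int)
        lo = np.clip(lo, 0, np.asarray(shape) - 1)
        hi = np.clip(np.maximum(hi, lo + 1), 1, shape)
        boxes.append(Box3D(lo=tuple(lo), hi=tuple(hi), score=float(p[i]), class_id=1))
    return boxes


def nms(boxes: list[Box3D], iou_threshold: float) -> list[Box3D]:
    """Greedy non-maximum suppression; keeps the highest score among boxes
    overlapping above the IoU threshold.  Output sorted by descending score."""
    ranked = sorted(boxes, key=lambda b: -(b.score if b.score is not None else 1.0))
    kept: list[Box3D] = []
    for b in ranked:
        if all(iou3d(b, k) <= iou_threshold for k in kept):
            kept.append(b)
    return kept


def decode_detections(out: DetectionOutput, score_threshold: float = 0.5, nms_iou: float = 0.1) -> list[Box3D]:
    """Turn raw anchor outputs into a suppressed, score-sorted candidate list."""
    if not 0.0 <= score_threshold <= 1.0 or not 0.0 <= nms_iou <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    boxes: list[Box3D] = []
    for level in out.levels:
        boxes.extend(_decode_level(level, out.input_shape, score_threshold))
    return nms(boxes, nms_iou)


# ---------------------------------------------------------------------------
# detection training loss


def _iou_matrix(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    lo = np.maximum(anchors[:, None, :3], gt[None, :, :3])
    hi = np.minimum(anchors[:, None, 3:], gt[None, :, 3:])
    inter = np.prod(np.clip(hi - lo, 0.0, None), axis=2)
    va = np.prod(anchors[:, 3:] - anchors[:, :3], axis=1)
    vg = np.prod(gt[:, 3:] - gt[:, :3], axis=1)
    return inter / (va[:, None] + vg[None, :] - inter + EPS)


def det_loss_and_grad(
    out: DetectionOutput,
    gt_boxes: list[Box3D],
    fp: FocalParams = FocalParams(),
    pos_iou: float = 0.2,
    neg_iou: float = 0.1,
):
    """Focal classification + smooth-L1 regression loss, with output grads.

    Anchors with IoU >= ``pos_iou`` against any ground-truth box are
    positive, anchors below ``neg_iou`` negative, the band between ignored;
    the best-matching anchor of every ground-truth box is forced positive.
    Classification is normalised by the positive count; regression applies
    the Huber penalty to the MAE of the encoded deltas of positive anchors.
    """
    gt = np.asarray([[*b.lo, *b.hi] for b in gt_boxes], dtype=np.float32)
    all_logits = np.concatenate([lv.logits for lv in out.levels])
    all_deltas = np.concatenate([lv.deltas for lv in out.levels])
    all_anchors = np.concatenate([lv.anchors for lv in out.levels])
    sizes = np.concatenate([np.full(len(lv.anchors), lv.anchor_size, dtype=np.float32) for lv in out.levels])
    n = len(all_logits)

    y = np.zeros(n, dtype=np.int8)  # 0 neg, 1 pos, -1 ignore
    assigned = np.full(n, -1, dtype=int)
    if len(gt):
        iou = _iou_matrix(all_anchors, gt)
        best = iou.max(axis=1)
        assigned = iou.argmax(axis=1)
        y[(best >= neg_iou) & (best < pos_iou)] = -1
        y[best >= pos_iou] = 1
        for j in range(len(gt)):
            i = int(iou[:, j].argmax())
            y[i] = 1
            assigned[i] = j

    p = _nn.sigmoid(all_logits).astype(np.float64)
    p = np.clip(p, EPS, 1.0 - EPS)
    n_pos = max(1, int((y == 1).sum()))
    use = y >= 0
    a, g = fp.alpha, fp.gamma
    per = np.where(
        y == 1,
        -a * (1.0 - p) ** g * np.log(p),
        -(1.0 - a) * p**g * np.log(1.0 - p),
    )
    cls_loss = float(per[use].sum() / n_pos)
    # d(focal)/d(logit), derived analytically (checked by finite differences)
    dz_pos = a * g * p * (1.0 - p) ** g * np.log(p) - a * (1.0 - p) ** (g + 1)
    dz_neg = -(1.0 - a) * g * (1.0 - p) * p**g * np.log(1.0 - p) + (1.0 - a) * p ** (g + 1)
    dz = np.where(y == 1, dz_pos, dz_neg)
    dz[~use] = 0.0
    dlogits_flat = (dz / n_pos).astype(np.float32)

    ddeltas_flat = np.zeros_like(all_deltas)
    reg_loss = 0.0
    pos_idx = np.nonzero(y == 1)[0]
    if len(pos_idx) and len(gt):
        ac = (all_anchors[pos_idx, :3] + all_anchors[pos_idx, 3:]) / 2.0
        asz = sizes[pos_idx][:, None]
        g_boxes = gt[assigned[pos_idx]]
        gc = (g_boxes[:, :3] + g_boxes[:, 3:]) / 2.0
        gs = g_boxes[:, 3:] - g_boxes[:, :3]
        target = np.concatenate([(gc - ac) / asz, np.log(np.clip(gs, 1e-3, None) / asz)], axis=1)
        diff = all_deltas[pos_idx] - target
        mae = float(np.abs(diff).mean())
        delta = 1.0
        if mae < delta:
            reg_loss = 0.5 * mae * mae / delta
            dmae = mae / delta
        else:
            reg_loss = mae - 0.5 * delta
            dmae = 1.0
        ddeltas_flat[pos_idx] = (dmae * np.sign(diff) / diff.size).astype(np.float32)

    # split flattened grads back per level
    dlogits, ddeltas = [], []
    off = 0
    for lv in out.levels:
        k = len(lv.logits)
        dlogits.append(dlogits_flat[off : off + k])
        ddeltas.append(ddeltas_flat[off : off + k])
        off += k
    return cls_loss + reg_loss, dlogits, ddeltas
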