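"""UNet3D: encoder-decoder segmentation network with skip connections.

The model maps a single-channel patch to per-voxel class probabilities.
It is fully convolutional: any input whose sides are divisible by
``2**(depth-1)`` works, including anisotropic shapes (the lobe-segmentation
variant runs on axially coarser grids with no code change).  Width doubles
per level (capped), downsampling is 2x average pooling, upsampling
nearest-neighbour, activations leaky-ReLU.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ..objectives import EPS, cross_entropy, dice_loss
from . import _nn
from ._nn import Adam, Param
from .config import NetConfig

__all__ = ["SegmentationModel", "build_segmenter", "seg_loss_and_grad"]


class SegmentationModel:
    """Desk-scale UNet3D over numpy; see module docstring."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, Param] = {}
        ch = [cfg.channels(l) for l in range(cfg.depth)]
        for l in range(cfg.depth):
            cin = cfg.in_channels if l == 0 else ch[l - 1]
            self._add_conv3(f"enc{l}a", cin, ch[l], rng)
            self._add_conv3(f"enc{l}b", ch[l], ch[l], rng)
        for l in range(cfg.depth - 2, -1, -1):
            self._add_conv3(f"dec{l}a", ch[l + 1] + ch[l], ch[l], rng)
            self._add_conv3(f"dec{l}b", ch[l], ch[l], rng)
        w, b = _nn.he_conv1(ch[0], cfg.n_classes, rng)
        self.params["out.w"], self.params["out.b"] = w, b

    # -- parameter plumbing -------------------------------------------------

    def _add_conv3(self, name: str, cin: int, cout: int, rng) -> None:
        w, b = _nn.he_conv3(cin, cout, rng)
        self.params[f"{name}.w"], self.params[f"{name}.b"] = w, b

    def parameters(self) -> list[Param]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params.values()))

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    # -- forward / backward -------------------------------------------------

    def _check_shape(self, x: np.ndarray) -> None:
        div = 2 ** (self.cfg.depth - 1)
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(f"expected ({self.cfg.in_channels}, D, H, W) input, got {x.shape}")
        if any(s % div for s in x.shape[1:]):
            raise ValueError(f"input sides {x.shape[1:]} must be divisible by {div}")

    def _conv_block(self, h, name, train):
        cache = {}
        for suffix in ("a", "b"):
            w, b = self.params[f"{name}{suffix}.w"], self.params[f"{name}{suffix}.b"]
            h, cache[f"{suffix}.conv"] = _nn.conv3_forward(h, w, b, keep_cache=train)
            h, cache[f"{suffix}.act"] = _nn.lrelu_forward(h, keep_cache=train)
        return h, cache

    def _conv_block_backward(self, dh, name, cache):
        for suffix in ("b", "a"):
            w, b = self.params[f"{name}{suffix}.w"], self.params[f"{name}{suffix}.b"]
            dh = _nn.lrelu_backward(dh, cache[f"{suffix}.act"])
            dh = _nn.conv3_backward(dh, w, b, cache[f"{suffix}.conv"])
        return dh

    def forward(self, x: np.ndarray, train: bool = False):
        """Return (logits, cache); logits shape (n_classes, D, H, W)."""
        self._check_shape(x)
        h = np.ascontiguousarray(x, dtype=np.float32)
        cache: dict = {"enc": {}, "dec": {}, "pool": {}}
        skips: dict[int, np.ndarray] = {}
        for l in range(self.cfg.depth):
            h, cache["enc"][l] = self._conv_block(h, f"enc{l}", train)
            if l < self.cfg.depth - 1:
                skips[l] = h
                h, cache["pool"][l] = _nn.avgpool2_forward(h)
        for l in range(self.cfg.depth - 2, -1, -1):
            h, _ = _nn.upsample2_forward(h)
            cache["dec"].setdefault(l, {})["split"] = h.shape[0]
            h = np.concatenate([h, skips[l]], axis=0)
            h, cache["dec"][l]["block"] = self._conv_block(h, f"dec{l}", train)
        logits, out_cache = _nn.conv1_forward(h, self.params["out.w"], self.params["out.b"], keep_cache=train)
        cache["out"] = out_cache
        return logits, (cache if train else None)

    def backward(self, dlogits: np.ndarray, cache) -> None:
        """Accumulate parameter gradients from dLoss/dlogits."""
        dh = _nn.conv1_backward(dlogits, self.params["out.w"], self.params["out.b"], cache["out"])
        dskip: dict[int, np.ndarray] = {}
        for l in range(self.cfg.depth - 1):
            dh = self._conv_block_backward(dh, f"dec{l}", cache["dec"][l]["block"])
            split = cache["dec"][l]["split"]
            dskip[l] = dh[split:]
            dh = _nn.upsample2_backward(dh[:split])
        for l in range(self.cfg.depth - 1, -1, -1):
            if l < self.cfg.depth - 1:
                dh = _nn.avgpool2_backward(dh, cache["pool"][l])
                dh = dh + dskip[l]
            dh = self._conv_block_backward(dh, f"enc{l}", cache["enc"][l])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-voxel class probabilities (n_classes, D, H, W), summing to 1."""
        logits, _ = self.forward(x, train=False)
        return _nn.softmax_channels(logits)

    def train_step(self, x: np.ndarray, y_onehot: np.ndarray, opt: Adam) -> float:
        self.zero_grad()
        logits, cache = self.forward(x, train=True)
        loss, dlogits = seg_loss_and_grad(logits, y_onehot)
        self.backward(dlogits, cache)
        opt.step(self.parameters())
        return loss

    # -- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {name: p.value for name, p in self.params.items()}
        np.savez(path, __config__=np.frombuffer(json.dumps(self.cfg.to_dict()).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        with np.load(path) as data:
            cfg = NetConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            for name, p in model.params.items():
                p.value[...] = data[name]
        return model


def build_segmenter(cfg: NetConfig) -> SegmentationModel:
    """Factory for the UNet3D segmentation model contract."""
    return SegmentationModel(cfg)


def seg_loss_and_grad(logits: np.ndarray, y_onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Dual segmentation loss (cross-entropy + Dice) and its logit gradient.

    Cross-entropy is averaged over voxels; the Dice term is averaged over
    foreground classes.  The gradient chains the probability-space gradient
    through the softmax Jacobian.
    """
    if logits.shape != y_onehot.shape:
        raise ValueError(f"shape mismatch: {logits.shape} vs {y_onehot.shape}")
    p = _nn.softmax_channels(logits).astype(np.float64)
    y = y_onehot.astype(np.float64)
    loss = cross_entropy(p, y) + dice_loss(p, y)

    n_vox = p[0].size
    g = -(y / np.clip(p, EPS, None)) / n_vox  # d(CE)/dp
    n_cls = p.shape[0]
    fg = range(1, n_cls) if n_cls >= 2 else range(n_cls)
    n_fg = max(1, len(list(fg)))
    for c in fg:
        inter = (y[c] * p[c]).sum()
        denom = (y[c] ** 2).sum() + (p[c] ** 2).sum() + EPS
        g[c] += (-(2.0 * y[c] * denom - 4.0 * p[c] * inter) / denom**2) / n_fg
    dlogits = p * (g - (g * p).sum(axis=0, keepdims=True))
    return float(loss), dlogits.astype(np.float32)
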