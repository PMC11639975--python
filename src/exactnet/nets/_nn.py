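"""Minimal numpy building blocks for small 3D convolutional networks.

Everything here is stateless: each op returns ``(output, cache)`` and the
matching ``*_backward`` consumes the cache, so a layer's weights can be
shared across pyramid levels without cache collisions.  Single-sample
(batch 1) semantics throughout; tensors are channel-first ``(C, D, H, W)``
float32.  This is deliberately desk-scale machinery: 3x3x3 convolutions via
im2col, average pooling, nearest-neighbour upsampling, leaky-ReLU, and an
Adam optimizer.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Param",
    "Adam",
    "he_conv3",
    "he_conv1",
    "conv3_forward",
    "conv3_backward",
    "conv1_forward",
    "conv1_backward",
    "lrelu_forward",
    "lrelu_backward",
    "avgpool2_forward",
    "avgpool2_backward",
    "upsample2_forward",
    "upsample2_backward",
    "sigmoid",
    "softmax_channels",
]

LEAK = 0.1


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Adam:
    """Adam with per-parameter state, keyed by parameter identity."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._t = 0

    def step(self, params: list[Param]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self._t
        bias2 = 1.0 - b2**self._t
        for p in params:
            m, v = self._state.setdefault(id(p), (np.zeros_like(p.value), np.zeros_like(p.value)))
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def he_conv3(c_in: int, c_out: int, rng: np.random.Generator) -> tuple[Param, Param]:
    std = np.sqrt(2.0 / (c_in * 27))
    w = rng.normal(0.0, std, size=(c_out, c_in * 27)).astype(np.float32)
    return Param(w), Param(np.zeros(c_out, dtype=np.float32))


def he_conv1(c_in: int, c_out: int, rng: np.random.Generator) -> tuple[Param, Param]:
    std = np.sqrt(2.0 / c_in)
    w = rng.normal(0.0, std, size=(c_out, c_in)).astype(np.float32)
    return Param(w), Param(np.zeros(c_out, dtype=np.float32))


# ---------------------------------------------------------------------------
# 3x3x3 convolution, stride 1, zero padding 1 (shape-preserving)


def _im2col(x: np.ndarray) -> np.ndarray:
    c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))
    # (C, D, H, W, 3,3,3) -> (D*H*W, C*27)
    return np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(d * h * w, c * 27)


def conv3_forward(x: np.ndarray, w: Param, b: Param, keep_cache: bool = True):
    c, d, hh, ww = x.shape
    cols = _im2col(x)
    y = cols @ w.value.T + b.value
    y = y.reshape(d, hh, ww, -1).transpose(3, 0, 1, 2)
    cache = (cols, x.shape) if keep_cache else None
    return np.ascontiguousarray(y), cache


def conv3_backward(dy: np.ndarray, w: Param, b: Param, cache) -> np.ndarray:
    cols, xshape = cache
    c, d, hh, ww = xshape
    dym = np.ascontiguousarray(dy.transpose(1, 2, 3, 0)).reshape(-1, dy.shape[0])
    w.grad += dym.T @ cols
    b.grad += dym.sum(axis=0)
    dcols = (dym @ w.value).reshape(d, hh, ww, c, 3, 3, 3)
    dxp = np.zeros((c, d + 2, hh + 2, ww + 2), dtype=np.float32)
    for a, bb, cc in product(range(3), repeat=3):
        dxp[:, a : a + d, bb : bb + hh, cc : cc + ww] += dcols[:, :, :, :, a, bb, cc].transpose(3, 0, 1, 2)
    return dxp[:, 1:-1, 1:-1, 1:-1]


# ---------------------------------------------------------------------------
# 1x1x1 convolution


def conv1_forward(x: np.ndarray, w: Param, b: Param, keep_cache: bool = True):
    y = np.tensordot(w.value, x, axes=([1], [0])) + b.value[:, None, None, None]
    return y.astype(np.float32), (x if keep_cache else None)


def conv1_backward(dy: np.ndarray, w: Param, b: Param, cache) -> np.ndarray:
    x = cache
    w.grad += np.tensordot(dy, x, axes=([1, 2, 3], [1, 2, 3]))
    b.grad += dy.sum(axis=(1, 2, 3))
    return np.tensordot(w.value.T, dy, axes=([1], [0])).astype(np.float32)


# ---------------------------------------------------------------------------
# activations / resampling


def lrelu_forward(x: np.ndarray, keep_cache: bool = True):
    y = np.where(x > 0, x, LEAK * x).astype(np.float32)
    return y, (x > 0 if keep_cache else None)


def lrelu_backward(dy: np.ndarray, cache) -> np.ndarray:
    return np.where(cache, dy, LEAK * dy).astype(np.float32)


def avgpool2_forward(x: np.ndarray):
    c, d, h, w = x.shape
    y = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))
    return y.astype(np.float32), x.shape


def avgpool2_backward(dy: np.ndarray, xshape) -> np.ndarray:
    up = upsample2_forward(dy)[0]
    return (up / 8.0).astype(np.float32)


def upsample2_forward(x: np.ndarray):
    y = np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)
    return y.astype(np.float32), None


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6)).astype(np.float32)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float32)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return (e / e.sum(axis=0, keepdims=True)).astype(np.float32)
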