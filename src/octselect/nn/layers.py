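"""Layers operating on single samples shaped (C, H, W).

Backward passes return the input gradient and accumulate parameter gradients
in-place (``dW``, ``db``), so a mini-batch is processed sample by sample and
the optimizer steps once per batch.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; layers are stateful between forward and backward."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    @property
    def params(self):
        return ()


class Conv2d(Layer):
    """2D convolution (cross-correlation) with 'same'-style zero padding.

    Kernel size 3 uses padding 1; kernel size 1 uses padding 0. Output spatial
    size is ``ceil(H / stride)`` for those combinations. He-uniform init.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 *, rng: np.random.Generator, dtype=np.float32):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2
        fan_in = in_ch * kernel * kernel
        bound = float(np.sqrt(6.0 / fan_in))
        self.W = rng.uniform(-bound, bound, size=(out_ch, in_ch, kernel, kernel)).astype(dtype)
        self.b = np.zeros(out_ch, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._in_shape = None

    @property
    def params(self):
        return (("W", "dW"), ("b", "db"))

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]
        ho, wo = win.shape[1], win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 3, 4, 1, 2)).reshape(c * k * k, ho * wo)
        self._cols, self._in_shape = cols, (c, h, w)
        y = self.W.reshape(self.out_ch, -1) @ cols + self.b[:, None]
        return y.reshape(self.out_ch, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._in_shape
        k, s, p = self.kernel, self.stride, self.pad
        o, ho, wo = dy.shape
        dym = dy.reshape(o, ho * wo)
        self.dW += (dym @ self._cols.T).reshape(self.W.shape)
        self.db += dym.sum(axis=1)
        dcols = (self.W.reshape(o, -1).T @ dym).reshape(c, k, k, ho, wo)
        dxp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=dy.dtype)
        for u in range(k):
            for v in range(k):
                dxp[:, u:u + s * ho:s, v:v + s * wo:s] += dcols[:, u, v]
        self._cols = None
        return dxp[:, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class Sigmoid(Layer):
    def forward(self, x):
        # numerically stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        self._out = out
        return out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)


class UpsampleNearest2(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        c, h2, w2 = dy.shape
        return dy.reshape(c, h2 // 2, 2, w2 // 2, 2).sum(axis=(2, 4))
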