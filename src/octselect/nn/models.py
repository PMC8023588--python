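"""Compact encoder-decoder networks for single-channel polar frames.

Two topologies from the same family:

* :class:`ConvAutoencoder` — encoder, bottleneck, decoder, **no** skip
  connections, so the bottleneck is a true information funnel and its feature
  maps characterise the frame (used for per-VOI feature extraction).
* :class:`UNet` — the segmenter: same contracting path plus skip connections
  and a sigmoid pixel-probability head.

Inputs are single samples shaped ``(1, H, W)``; spatial dims are zero-padded
internally to a multiple of ``2**n_stages`` and the output is cropped back.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, ReLU, Sigmoid, UpsampleNearest2


class _Net:
    """Shared parameter plumbing."""

    def __init__(self, dtype):
        self.dtype = dtype
        self._layers: list = []

    def _conv(self, cin, cout, *, stride=1, kernel=3, rng):
        layer = Conv2d(cin, cout, kernel=kernel, stride=stride, rng=rng, dtype=self.dtype)
        self._layers.append(layer)
        return layer

    def param_layers(self):
        return [l for l in self._layers if isinstance(l, Conv2d)]

    def zero_grad(self):
        for l in self.param_layers():
            l.dW[...] = 0
            l.db[...] = 0

    def get_weights(self):
        return [(l.W.copy(), l.b.copy()) for l in self.param_layers()]

    def set_weights(self, weights):
        for l, (w, b) in zip(self.param_layers(), weights, strict=True):
            l.W[...] = w
            l.b[...] = b

    def n_parameters(self) -> int:
        return sum(l.W.size + l.b.size for l in self.param_layers())

    # -- padding helpers ---------------------------------------------------
    def _pad_input(self, x: np.ndarray, n_stages: int):
        m = 1 << n_stages
        _, h, w = x.shape
        ph, pw = (-h) % m, (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, ph), (0, pw)))
        return x, (h, w)

    @staticmethod
    def _crop_output(y: np.ndarray, hw):
        h, w = hw
        return y[:, :h, :w]

    @staticmethod
    def _embed_grad(dy: np.ndarray, padded_hw):
        c = dy.shape[0]
        out = np.zeros((c,) + padded_hw, dtype=dy.dtype)
        out[:, :dy.shape[1], :dy.shape[2]] = dy
        return out


class ConvAutoencoder(_Net):
    """Strided-conv encoder, 3x3 bottleneck, nearest-upsample decoder.

    Parameters
    ----------
    enc_widths
        Channel widths of the stride-2 encoder stages; their count sets the
        downsampling factor (``2**len(enc_widths)``).
    bottleneck_ch
        Channels of the stride-1 bottleneck convolution whose (ReLU) feature
        maps are exposed for feature extraction.
    dec_widths
        Channel widths of the upsampling decoder stages; one fewer than the
        encoder, because the last 2x step is a parameter-light nearest-upsample
        plus 1x1 convolution head — 3x3 convolutions at full frame resolution
        dominate CPU cost while adding little to reconstructions of smoothed
        frames.
    """

    def __init__(self, in_ch: int = 1, enc_widths=(8, 16, 24, 32),
                 bottleneck_ch: int = 32, dec_widths=(16, 8, 4),
                 *, seed: int = 0, dtype=np.float32):
        if len(dec_widths) != len(enc_widths) - 1:
            raise ValueError("dec_widths must have len(enc_widths) - 1 entries")
        super().__init__(dtype)
        rng = np.random.default_rng(seed)
        self.enc_widths = tuple(enc_widths)
        self.bottleneck_ch = bottleneck_ch
        self.n_stages = len(self.enc_widths)

        self._enc = []
        prev = in_ch
        for w in self.enc_widths:
            self._enc.append((self._conv(prev, w, stride=2, rng=rng), ReLU()))
            prev = w
        self._bottleneck_conv = self._conv(prev, bottleneck_ch, rng=rng)
        self._bottleneck_relu = ReLU()

        self._dec = []
        prev = bottleneck_ch
        for w in dec_widths:
            self._dec.append((UpsampleNearest2(), self._conv(prev, w, rng=rng), ReLU()))
            prev = w
        self._head_up = UpsampleNearest2()
        self._head = self._conv(prev, in_ch, kernel=1, rng=rng)
        self._out_act = Sigmoid()

        self.bottleneck: np.ndarray | None = None
        self._hw = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        h, self._hw = self._pad_input(x, self.n_stages)
        self._padded_hw = h.shape[1:]
        for conv, act in self._enc:
            h = act.forward(conv.forward(h))
        h = self._bottleneck_relu.forward(self._bottleneck_conv.forward(h))
        self.bottleneck = h
        for up, conv, act in self._dec:
            h = act.forward(conv.forward(up.forward(h)))
        y = self._out_act.forward(self._head.forward(self._head_up.forward(h)))
        return self._crop_output(y, self._hw)

    def backward(self, dy: np.ndarray) -> None:
        g = self._embed_grad(dy, self._padded_hw)
        g = self._head_up.backward(self._head.backward(self._out_act.backward(g)))
        for up, conv, act in reversed(self._dec):
            g = up.backward(conv.backward(act.backward(g)))
        g = self._bottleneck_conv.backward(self._bottleneck_relu.backward(g))
        for conv, act in reversed(self._enc):
            g = conv.backward(act.backward(g))

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Bottleneck feature maps (C, H/2^n, W/2^n) for one frame."""
        h, _ = self._pad_input(np.asarray(x, dtype=self.dtype), self.n_stages)
        for conv, act in self._enc:
            h = act.forward(conv.forward(h))
        return self._bottleneck_relu.forward(self._bottleneck_conv.forward(h))


class UNet(_Net):
    """Compact U-net: strided-conv downsampling, skip concatenation, sigmoid head."""

    def __init__(self, in_ch: int = 1, widths=(8, 16, 32), *, seed: int = 0,
                 dtype=np.float32):
        super().__init__(dtype)
        rng = np.random.default_rng(seed)
        self.widths = tuple(widths)
        self.n_stages = len(self.widths)

        # encoder stage i: conv(prev->w) [skip tap] + strided conv(w->w)
        self._enc = []
        prev = in_ch
        for w in self.widths:
            self._enc.append((
                self._conv(prev, w, rng=rng), ReLU(),
                self._conv(w, w, stride=2, rng=rng), ReLU(),
            ))
            prev = w
        self._bottom_conv = self._conv(prev, prev, rng=rng)
        self._bottom_relu = ReLU()

        # decoder stage i: upsample, concat skip (w_i ch), conv -> w_{i-1}
        self._dec = []
        dec_out = list(self.widths[-2::-1]) + [self.widths[0]]
        prev_ch = prev
        for w_skip, w_out in zip(self.widths[::-1], dec_out):
            self._dec.append((
                UpsampleNearest2(),
                self._conv(prev_ch + w_skip, w_out, rng=rng), ReLU(),
            ))
            prev_ch = w_out
        self._head = self._conv(prev_ch, 1, kernel=1, rng=rng)
        self._out_act = Sigmoid()

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        h, self._hw = self._pad_input(x, self.n_stages)
        self._padded_hw = h.shape[1:]
        skips = []
        for c1, a1, c2, a2 in self._enc:
            s = a1.forward(c1.forward(h))
            skips.append(s)
            h = a2.forward(c2.forward(s))
        h = self._bottom_relu.forward(self._bottom_conv.forward(h))
        self._skip_ch = [s.shape[0] for s in skips]
        for (up, conv, act), s in zip(self._dec, reversed(skips)):
            h = act.forward(conv.forward(np.concatenate([up.forward(h), s], axis=0)))
        y = self._out_act.forward(self._head.forward(h))
        return self._crop_output(y, self._hw)

    def backward(self, dy: np.ndarray) -> None:
        g = self._embed_grad(dy, self._padded_hw)
        g = self._head.backward(self._out_act.backward(g))
        # decoder stage j consumed skip (n_stages-1-j), so walking the decoder
        # backwards yields skip gradients in ascending skip order
        dskips = []
        for (up, conv, act), ch in zip(reversed(self._dec), self._skip_ch):
            g = conv.backward(act.backward(g))
            up_ch = g.shape[0] - ch
            dskips.append(g[up_ch:])
            g = up.backward(g[:up_ch])
        g = self._bottom_conv.backward(self._bottom_relu.backward(g))
        for (c1, a1, c2, a2), ds in zip(reversed(self._enc), reversed(dskips)):
            g = c2.backward(a2.backward(g))
            g = c1.backward(a1.backward(g + ds))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)
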