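"""Adam optimizer over the conv layers of a network."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, net, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._state = {}
        for i, layer in enumerate(net.param_layers()):
            for name, _ in layer.params:
                p = getattr(layer, name)
                self._state[(i, name)] = (np.zeros_like(p), np.zeros_like(p))

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, layer in enumerate(self.net.param_layers()):
            for name, gname in layer.params:
                p = getattr(layer, name)
                g = getattr(layer, gname)
                m, v = self._state[(i, name)]
                m *= self.b1
                m += (1.0 - self.b1) * g
                v *= self.b2
                v += (1.0 - self.b2) * (g * g)
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
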