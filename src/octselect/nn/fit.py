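"""Mini-batch epoch runner shared by autoencoder and segmenter training.

Samples are processed one at a time with gradient accumulation, so an epoch's
peak memory is one sample's activations regardless of batch size.
"""

from __future__ import annotations

import numpy as np


def run_epoch(net, optimizer, x: np.ndarray, y: np.ndarray, loss_fn,
              batch_size: int, rng: np.random.Generator, *, shuffle: bool = True) -> float:
    """One training epoch; returns the mean per-sample loss.

    ``x`` and ``y`` are stacks shaped (N, C, H, W); ``loss_fn(pred, target)``
    returns ``(loss, grad)``.
    """
    n = x.shape[0]
    order = rng.permutation(n) if shuffle else np.arange(n)
    total = 0.0
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        net.zero_grad()
        for i in idx:
            pred = net.forward(x[i])
            loss, grad = loss_fn(pred, y[i])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss ({loss}) at sample {i}")
            net.backward(grad / len(idx))
            total += loss
        optimizer.step()
    return total / n


def evaluate_loss(net, x: np.ndarray, y: np.ndarray, loss_fn) -> float:
    """Mean per-sample loss without gradient updates."""
    total = 0.0
    for i in range(x.shape[0]):
        pred = net.forward(x[i])
        loss, _ = loss_fn(pred, y[i])
        total += loss
    return total / x.shape[0]
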