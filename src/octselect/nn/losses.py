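"""Pixelwise losses with analytic gradients."""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean per-pixel squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad


def weighted_bce(prob_map: np.ndarray, target_mask: np.ndarray, weights) -> float:
    """Class-weighted binary cross-entropy, mean over pixels.

    ``weights`` is ``(w_positive, w_negative)``; with (0.5, 0.5) this is half
    the standard BCE. Probabilities are clipped away from {0, 1}.
    """
    if prob_map.shape != target_mask.shape:
        raise ValueError("prob_map and target_mask shapes differ")
    w_pos, w_neg = weights
    p = np.clip(prob_map, _EPS, 1.0 - _EPS)
    y = target_mask
    ll = w_pos * y * np.log(p) + w_neg * (1.0 - y) * np.log1p(-p)
    return float(-np.mean(ll))


def weighted_bce_with_grad(prob_map: np.ndarray, target_mask: np.ndarray, weights):
    """Loss value plus gradient w.r.t. the probability map."""
    w_pos, w_neg = weights
    p = np.clip(prob_map, _EPS, 1.0 - _EPS)
    y = target_mask
    ll = w_pos * y * np.log(p) + w_neg * (1.0 - y) * np.log1p(-p)
    loss = float(-np.mean(ll))
    grad = (-w_pos * y / p + w_neg * (1.0 - y) / (1.0 - p)) / p.size
    return loss, grad.astype(prob_map.dtype, copy=False)
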