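"""Segmentation metrics and agreement analyses.

Per-class pixel F1, precision-recall / average precision (AP) with the
normal-VOI exclusion rule, clinical calcification attributes (angle, depth,
thickness) with Bland-Altman agreement, and the paired statistics used to
compare samplers. Precision-recall rather than ROC throughout, because the
pixel classes are heavily imbalanced (~10% calcific).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve


@dataclass
class MetricsReport:
    f1_calcific: float
    f1_other: float
    ap: float
    pr_curve: list[tuple[float, float]] = field(default_factory=list)  # (recall, precision)
    n_frames_included: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"f1_calcific": self.f1_calcific,
                              "f1_other": self.f1_other, "ap": self.ap,
                              "n_frames_included": self.n_frames_included}])


@dataclass
class CalcAttributes:
    """Clinical lesion descriptors derived from an aligned polar mask."""
    angle_deg: float
    depth_mm: float
    thickness_mm: float


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0


def f1_per_class(pred_masks: np.ndarray, true_masks: np.ndarray) -> tuple[float, float]:
    """Pixel-level F1 for (calcific, other), pooled over all frames."""
    p = np.asarray(pred_masks).astype(bool)
    t = np.asarray(true_masks).astype(bool)
    if p.shape != t.shape:
        raise ValueError("prediction/truth shape mismatch")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return _f1(tp, fp, fn), _f1(tn, fn, fp)


def f1_per_frame(pred_masks: np.ndarray, true_masks: np.ndarray) -> np.ndarray:
    """Calcific F1 of each frame separately (frames along axis 0)."""
    return np.array([f1_per_class(p, t)[0] for p, t in zip(pred_masks, true_masks)])


def average_precision(prob_maps, true_masks, exclude_normal: bool = True):
    """Pooled-pixel AP and PR curve over the evaluation set.

    Frames without a single calcific truth pixel make precision-recall
    undefined; with ``exclude_normal`` they are dropped before pooling (the
    count of retained frames is reported), otherwise their presence with zero
    positives raises.
    """
    probs = [np.asarray(p) for p in prob_maps]
    trues = [np.asarray(t) for t in true_masks]
    has_pos = [t.any() for t in trues]
    if exclude_normal:
        probs = [p for p, h in zip(probs, has_pos) if h]
        trues = [t for t, h in zip(trues, has_pos) if h]
    if not probs or not any(t.any() for t in trues):
        raise ValueError("no positive pixels in evaluation set; AP undefined")
    y = np.concatenate([t.ravel() for t in trues]).astype(int)
    s = np.concatenate([p.ravel() for p in probs])
    ap = float(average_precision_score(y, s))
    prec, rec, _ = precision_recall_curve(y, s)
    curve = list(zip(rec[::-1].tolist(), prec[::-1].tolist()))  # recall ascending
    return ap, curve, len(probs)


def average_precision_per_frame(prob_maps, true_masks) -> np.ndarray:
    """One AP per calcification-containing frame (each frame an independent
    sample); frames without positives are skipped."""
    out = []
    for p, t in zip(prob_maps, true_masks):
        t = np.asarray(t)
        if t.any():
            out.append(float(average_precision_score(t.ravel().astype(int),
                                                     np.asarray(p).ravel())))
    return np.asarray(out)


def metrics_report(pred_masks, prob_maps, true_masks) -> MetricsReport:
    f1c, f1o = f1_per_class(np.asarray(pred_masks), np.asarray(true_masks))
    ap, curve, n_inc = average_precision(prob_maps, true_masks, exclude_normal=True)
    return MetricsReport(f1_calcific=f1c, f1_other=f1o, ap=ap,
                         pr_curve=curve, n_frames_included=n_inc)


def calc_attributes(mask: np.ndarray, pixel_pitch_mm: float = 0.005,
                    deg_per_aline: float | None = None) -> CalcAttributes:
    """Angle, depth and thickness of the calcification in an aligned mask.

    The mask is lumen-aligned (row 0 = lumen boundary). Angle: the number of
    A-lines containing any calcific pixel times the angular pitch. Depth: the
    minimum first-calcific-row over lesion A-lines, in mm. Thickness: the mean
    radial extent (last - first + 1) over lesion A-lines, in mm. An empty mask
    maps to all zeros.
    """
    m = np.asarray(mask).astype(bool)
    nr, na = m.shape
    if deg_per_aline is None:
        deg_per_aline = 360.0 / na
    cols = m.any(axis=0)
    if not cols.any():
        return CalcAttributes(0.0, 0.0, 0.0)
    idx = np.flatnonzero(cols)
    firsts = np.array([np.argmax(m[:, a]) for a in idx])
    lasts = np.array([nr - 1 - np.argmax(m[::-1, a]) for a in idx])
    angle = float(len(idx) * deg_per_aline)
    depth = float(firsts.min() * pixel_pitch_mm)
    thickness = float(np.mean(lasts - firsts + 1) * pixel_pitch_mm)
    return CalcAttributes(min(angle, 360.0), depth, thickness)


def bland_altman(pred_attrs: np.ndarray, true_attrs: np.ndarray):
    """Mean difference (bias) and 95% limits of agreement for paired values."""
    d = np.asarray(pred_attrs, dtype=float) - np.asarray(true_attrs, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one pair")
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def bland_altman_table(pred_masks, true_masks, pixel_pitch_mm: float = 0.005) -> pd.DataFrame:
    """Per-attribute Bland-Altman summary over paired frame masks."""
    rows = {}
    for name in ("angle_deg", "depth_mm", "thickness_mm"):
        pv = np.array([getattr(calc_attributes(m, pixel_pitch_mm), name) for m in pred_masks])
        tv = np.array([getattr(calc_attributes(m, pixel_pitch_mm), name) for m in true_masks])
        bias, (lo, hi) = bland_altman(pv, tv)
        rows[name] = {"bias": bias, "loa_low": lo, "loa_high": hi}
    return pd.DataFrame(rows).T


def paired_t_test(ap_a: np.ndarray, ap_b: np.ndarray):
    """Paired t-test on per-frame AP vectors of two models.

    Degenerate difference vectors (zero variance) fall back to an exact
    two-sided sign-flip permutation: p = 1 for identical vectors, 2^(1-n) for
    a constant non-zero difference.
    """
    a = np.asarray(ap_a, dtype=float)
    b = np.asarray(ap_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must share length")
    d = a - b
    if np.allclose(d.std(), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), float(2.0 ** (1 - d.size))
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def wilcoxon_vs_baseline(values: np.ndarray, baseline: float,
                         alternative: str = "less"):
    """One-sample Wilcoxon signed-rank test of ``values`` against a baseline
    (default alternative: values fall below the baseline)."""
    v = np.asarray(values, dtype=float) - baseline
    if np.allclose(v, 0.0):
        return 0.0, 1.0
    stat, p = stats.wilcoxon(v, alternative=alternative)
    return float(stat), float(p)


def compare_models(ap_a: np.ndarray, ap_b: np.ndarray) -> dict:
    """Paired comparison of two models' per-frame AP vectors."""
    t, p = paired_t_test(ap_a, ap_b)
    return {"t_statistic": t, "p_value": p,
            "mean_difference": float(np.mean(np.asarray(ap_a) - np.asarray(ap_b))),
            "n": int(np.asarray(ap_a).size)}
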