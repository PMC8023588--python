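"""Metrics: F1 and AP oracles, attribute recovery from phantom ground truth,
Bland-Altman, and the paired statistics."""

import numpy as np
import pytest
from scipy import stats

from octselect.evaluate import (average_precision, average_precision_per_frame,
                                bland_altman, bland_altman_table,
                                calc_attributes, compare_models, f1_per_class,
                                f1_per_frame, paired_t_test,
                                wilcoxon_vs_baseline)
from octselect.phantom import LesionParams, generate_voi
from octselect.preprocess import preprocess_voi

from conftest import small_config, small_preprocess


# ------------------------------------------------------------------- F1

def test_perfect_prediction():
    t = (np.random.default_rng(0).random((3, 8, 8)) > 0.7).astype(int)
    assert f1_per_class(t, t) == (1.0, 1.0)


def test_all_negative_prediction_zero_calcific_f1():
    t = np.zeros((2, 4, 4), dtype=int)
    t[0, 1, 1] = 1
    f1c, f1o = f1_per_class(np.zeros_like(t), t)
    assert f1c == 0.0 and f1o > 0.9


def test_counts_toy_example():
    # TP=2, FP=1, FN=1 -> F1 = 2*2/(4+1+1) = 0.6667
    pred = np.array([[1, 1, 1, 0, 0]])
    true = np.array([[1, 1, 0, 1, 0]])
    f1c, _ = f1_per_class(pred, true)
    assert f1c == pytest.approx(2 * 2 / 6)


def test_class_swap_symmetry(rng):
    p = (rng.random((2, 6, 6)) > 0.6).astype(int)
    t = (rng.random((2, 6, 6)) > 0.6).astype(int)
    f1c, f1o = f1_per_class(p, t)
    f1c_sw, f1o_sw = f1_per_class(1 - p, 1 - t)
    assert f1c == pytest.approx(f1o_sw) and f1o == pytest.approx(f1c_sw)


def test_per_frame_f1_matches_pooled_on_single_frame(rng):
    p = (rng.random((1, 5, 5)) > 0.5).astype(int)
    t = (rng.random((1, 5, 5)) > 0.5).astype(int)
    assert f1_per_frame(p, t)[0] == pytest.approx(f1_per_class(p, t)[0])


# ------------------------------------------------------------------- AP

def test_four_pixel_worked_example():
    # labels (1,0,1,0), scores (.9,.8,.7,.1): AP = 1*0.5 + (2/3)*0.5 = 0.8333
    ap, curve, n = average_precision([np.array([[0.9, 0.8, 0.7, 0.1]])],
                                     [np.array([[1, 0, 1, 0]])])
    assert ap == pytest.approx(5 / 6, abs=1e-9)
    recalls = [r for r, _ in curve]
    assert recalls == sorted(recalls)


def test_perfect_ranking_gives_ap_one(rng):
    t = (rng.random((1, 10, 10)) > 0.8).astype(int)
    ap, _, _ = average_precision([t[0].astype(float)], [t[0]])
    assert ap == pytest.approx(1.0)


def test_random_scores_ap_near_positive_fraction(rng):
    n, q = 10000, 0.15
    y = (rng.random(n) < q).astype(int)
    s = rng.random(n)
    ap, _, _ = average_precision([s.reshape(100, 100)], [y.reshape(100, 100)])
    assert ap == pytest.approx(y.mean(), abs=0.02)


def test_normal_frames_excluded_and_counted(rng):
    pos = (rng.random((6, 6)) > 0.6).astype(int)
    neg = np.zeros((6, 6), dtype=int)
    scores = rng.random((6, 6))
    ap_with, _, n_inc = average_precision([scores, scores], [pos, neg])
    assert n_inc == 1
    ap_only, _, _ = average_precision([scores], [pos])
    assert ap_with == pytest.approx(ap_only)


def test_no_positives_without_exclusion_raises(rng):
    with pytest.raises(ValueError):
        average_precision([rng.random((4, 4))], [np.zeros((4, 4), dtype=int)],
                          exclude_normal=False)


def test_ap_invariant_to_monotone_score_transform(rng):
    t = (rng.random((1, 12, 12)) > 0.7).astype(int)
    s = rng.random((12, 12))
    ap1, _, _ = average_precision([s], [t[0]])
    ap2, _, _ = average_precision([np.exp(3 * s) + 5], [t[0]])
    assert ap1 == pytest.approx(ap2)


def test_per_frame_ap_skips_normal_frames(rng):
    pos = (rng.random((5, 5)) > 0.5).astype(int)
    neg = np.zeros((5, 5), dtype=int)
    aps = average_precision_per_frame([rng.random((5, 5))] * 3, [pos, neg, pos])
    assert aps.shape == (2,)


# ------------------------------------------------------------- attributes

def test_empty_mask_zero_attributes():
    a = calc_attributes(np.zeros((10, 12)))
    assert (a.angle_deg, a.depth_mm, a.thickness_mm) == (0.0, 0.0, 0.0)


def test_full_circumference_angle_360():
    assert calc_attributes(np.ones((10, 24))).angle_deg == pytest.approx(360.0)


def test_phantom_lesion_attributes_recovered():
    """Angle/depth/thickness measured from the aligned mask match the
    generator's lesion parameters within discretization error."""
    lesion = LesionParams(arc_center_deg=180.0, arc_extent_deg=90.0,
                          depth_px=20.0, thickness_px=30.0,
                          center_drift_deg_per_frame=0.0, extent_mod_frac=0.0,
                          depth_mod_px=0.0, thickness_mod_frac=0.0)
    cfg = small_config(n_alines=360, n_radial=200, n_frames=1, seed=2,
                       lumen_radius_mean=40.0, lumen_amplitude=8.0,
                       guidewire_width=10, guidewire_center_deg=20.0,
                       lesion=lesion)
    pb = generate_voi(cfg)
    frames = preprocess_voi(pb, small_preprocess())
    pitch = 1.0   # report in pixels for direct comparison
    att = calc_attributes(frames[0].mask, pixel_pitch_mm=pitch)
    deg_per_aline = 1.0
    assert att.angle_deg == pytest.approx(90.0, abs=2 * deg_per_aline + 1e-9)
    assert att.depth_mm == pytest.approx(20.0, abs=1.0)
    assert att.thickness_mm == pytest.approx(30.0, abs=1.0)


# ------------------------------------------------------------ Bland-Altman

def test_identical_pairs_zero_bias_zero_limits():
    v = np.array([1.0, 2.0, 3.0])
    bias, (lo, hi) = bland_altman(v, v)
    assert bias == 0.0 and lo == 0.0 and hi == 0.0


def test_constant_offset():
    v = np.array([1.0, 2.0, 3.0])
    bias, (lo, hi) = bland_altman(v + 5, v)
    assert bias == pytest.approx(5.0)
    assert lo == pytest.approx(5.0) and hi == pytest.approx(5.0)


def test_zero_mean_differences_have_small_bias(rng):
    d = rng.standard_normal(400)
    bias, (lo, hi) = bland_altman(d, np.zeros_like(d))
    assert abs(bias) < 1.96 * d.std(ddof=1) / np.sqrt(d.size)
    assert lo < bias < hi


def test_bland_altman_table_shape(rng):
    masks = [(rng.random((12, 16)) > 0.8).astype(int) for _ in range(4)]
    tbl = bland_altman_table(masks, masks)
    assert list(tbl.index) == ["angle_deg", "depth_mm", "thickness_mm"]
    assert np.allclose(tbl["bias"], 0.0)


# -------------------------------------------------------------- statistics

def test_identical_vectors_t_zero_p_one():
    v = np.array([0.5, 0.6, 0.7])
    t, p = paired_t_test(v, v)
    assert t == 0.0 and p == 1.0


def test_constant_positive_difference_significant_at_n8():
    a = np.full(8, 0.9)
    b = np.full(8, 0.7)
    _, p = paired_t_test(a, b)
    assert p == pytest.approx(2.0 ** -7)
    assert p < 0.05


def test_paired_t_matches_scipy_on_generic_data(rng):
    a = rng.random(20)
    b = a + 0.1 + 0.05 * rng.standard_normal(20)
    t, p = paired_t_test(a, b)
    t_ref, p_ref = stats.ttest_rel(a, b)
    assert t == pytest.approx(t_ref) and p == pytest.approx(p_ref)


def test_wilcoxon_direction():
    below = np.array([0.4, 0.45, 0.5, 0.42, 0.48, 0.41])
    _, p_less = wilcoxon_vs_baseline(below, 0.66, "less")
    assert p_less < 0.05
    symmetric = np.array([-0.2, -0.1, 0.1, 0.2, -0.15, 0.15]) + 0.66
    _, p_sym = wilcoxon_vs_baseline(symmetric, 0.66, "less")
    assert p_sym > 0.2


def test_compare_models_reports_fields(rng):
    a, b = rng.random(15), rng.random(15)
    out = compare_models(a, b)
    assert set(out) == {"t_statistic", "p_value", "mean_difference", "n"}
    assert out["n"] == 15


def test_monte_carlo_power_matches_closed_form(rng):
    """Paired t-test power under a shift alternative agrees with the
    noncentral-t closed form within 5 points."""
    n, effect, alpha, reps = 12, 0.9, 0.05, 800
    rejections = 0
    for _ in range(reps):
        d = rng.standard_normal(n) + effect
        _, p = stats.ttest_1samp(d, 0.0)
        rejections += p < alpha
    empirical = rejections / reps
    nc = effect * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    power = (1 - stats.nct.cdf(tcrit, n - 1, nc)) + stats.nct.cdf(-tcrit, n - 1, nc)
    assert empirical == pytest.approx(power, abs=0.05)
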