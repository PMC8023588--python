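"""Frame samplers: target counts, equal spacing, autoencoder features, PCA
reduction, PAM k-medoids (against a brute-force oracle), and the composed
clustering sampler."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octselect.phantom import LesionParams, generate_voi_with_archetypes
from octselect.preprocess import preprocess_voi
from octselect.select import (SamplerConfig, clustering_sample,
                              equal_spacing_indices,
                              extract_bottleneck_features, k_medoids,
                              per_voi_seed, read_plan, reduce_pca, sample_voi,
                              target_count, train_autoencoder, write_plan,
                              FeatureMatrix)

from conftest import small_config, small_preprocess, small_sampler


# ------------------------------------------------------------- target_count

@pytest.mark.parametrize("n,ratio,expect", [
    (9, Fraction(1, 3), 3),
    (10, Fraction(1, 10), 1),
    (7, Fraction(1, 2), 4),       # ceil(3.5); matches stride-2 {0,2,4,6}
    (1, Fraction(1, 10), 1),      # never less than one frame
    (5, 1, 5),
])
def test_target_count_examples(n, ratio, expect):
    assert target_count(n, ratio) == expect


# ------------------------------------------------------------ equal spacing

@pytest.mark.parametrize("n,ratio,expect", [
    (9, Fraction(1, 3), [0, 3, 6]),       # the every-third rule
    (5, 1, [0, 1, 2, 3, 4]),
    (10, Fraction(1, 10), [0]),
    (7, Fraction(1, 2), [0, 2, 4, 6]),
])
def test_equal_spacing_examples(n, ratio, expect):
    assert equal_spacing_indices(n, ratio).selected_frame_ids == expect


@settings(max_examples=200, deadline=None, derandomize=True)
@given(n=st.integers(1, 200),
       ratio=st.fractions(min_value=Fraction(1, 200), max_value=1))
def test_equal_spacing_cardinality_and_bounds(n, ratio):
    """|selected| always equals ceil(n*ratio); indices unique, sorted, in range."""
    sel = equal_spacing_indices(n, ratio).selected_frame_ids
    assert len(sel) == target_count(n, ratio)
    assert sel == sorted(set(sel))
    assert sel[0] == 0 and sel[-1] < n


# ---------------------------------------------------------------- k-medoids

def brute_force_k_medoids_cost(X: np.ndarray, k: int) -> float:
    """Exhaustive optimum over all C(n, k) medoid sets (oracle)."""
    from scipy.spatial.distance import cdist
    D = cdist(X, X)
    return min(D[:, list(meds)].min(axis=1).sum()
               for meds in itertools.combinations(range(len(X)), k))


def test_two_well_separated_pairs():
    r = k_medoids(np.array([0.0, 1.0, 10.0, 11.0]), k=2)
    meds = set(r.medoid_indices.tolist())
    assert len(meds & {0, 1}) == 1 and len(meds & {2, 3}) == 1
    assert r.total_cost == pytest.approx(2.0)


def test_k_equals_n_zero_cost(rng):
    X = rng.random((6, 3))
    r = k_medoids(X, k=6)
    assert r.total_cost == pytest.approx(0.0)
    assert sorted(r.medoid_indices.tolist()) == list(range(6))


def test_k_one_picks_medianlike_element(rng):
    X = rng.random(9)
    r = k_medoids(X, k=1)
    costs = [np.abs(X - X[i]).sum() for i in range(9)]
    assert costs[r.medoid_indices[0]] == pytest.approx(min(costs))


def test_duplicate_points_allowed():
    X = np.array([1.0, 1.0, 1.0, 5.0])
    r = k_medoids(X, k=2)
    assert r.total_cost == pytest.approx(0.0)


def test_k_out_of_range_raises(rng):
    with pytest.raises(ValueError):
        k_medoids(rng.random((4, 2)), k=5)


def test_pam_matches_exhaustive_oracle(rng):
    """PAM never beats the exhaustive optimum and matches it on small inputs."""
    matches = 0
    trials = 40
    for _ in range(trials):
        n = int(rng.integers(4, 9))
        k = int(rng.integers(1, 4))
        X = rng.random((n, 2))
        pam = k_medoids(X, k).total_cost
        opt = brute_force_k_medoids_cost(X, k)
        assert pam >= opt - 1e-9
        matches += pam <= opt + 1e-9
    assert matches >= 0.95 * trials


def test_assignments_point_to_nearest_medoid(rng):
    X = rng.random((12, 3))
    r = k_medoids(X, k=3)
    from scipy.spatial.distance import cdist
    D = cdist(X, X[r.medoid_indices])
    assert np.array_equal(r.assignments, D.argmin(axis=1))


# ---------------------------------------------------------------------- PCA

def test_collinear_data_needs_one_component(rng):
    t = rng.random(10)
    X = np.outer(t, rng.random(16))
    fm = FeatureMatrix(matrix=X, frame_ids=list(range(10)), stage="bottleneck")
    assert reduce_pca(fm, 0.95).matrix.shape[1] == 1


def test_full_variance_keeps_rank(rng):
    X = rng.random((6, 4))
    fm = FeatureMatrix(matrix=X, frame_ids=list(range(6)), stage="bottleneck")
    out = reduce_pca(fm, 1.0)
    assert out.matrix.shape[1] == np.linalg.matrix_rank(X - X.mean(0))


def test_threshold_is_tight_against_eigenvalue_cumsum(rng):
    X = rng.standard_normal((10, 64))
    fm = FeatureMatrix(matrix=X, frame_ids=list(range(10)), stage="bottleneck")
    m = reduce_pca(fm, 0.95).matrix.shape[1]
    Xc = X - X.mean(0)
    ev = np.sort(np.linalg.svd(Xc, compute_uv=False) ** 2)[::-1]
    ratio = np.cumsum(ev) / ev.sum()
    assert ratio[m - 1] >= 0.95
    assert m == 1 or ratio[m - 2] < 0.95


def test_identical_frames_warn_and_return_constant():
    X = np.ones((5, 8))
    fm = FeatureMatrix(matrix=X, frame_ids=list(range(5)), stage="bottleneck")
    with pytest.warns(UserWarning):
        out = reduce_pca(fm, 0.95)
    assert out.matrix.shape == (5, 1)


# -------------------------------------------------------------- autoencoder

@pytest.fixture(scope="module")
def trained_ae(small_frames):
    cfg = small_sampler(ae_epochs=12, seed=5)
    return train_autoencoder(small_frames, cfg), cfg


def test_training_loss_trends_down(trained_ae):
    (model, record), _ = trained_ae
    losses = np.array(record.epoch_loss)
    assert losses[-1] < losses[0]
    rises = np.sum(np.diff(losses) > 0)
    assert rises <= 0.25 * len(losses)


def test_same_seed_identical_final_loss(small_frames):
    cfg = small_sampler(ae_epochs=3, seed=9)
    _, r1 = train_autoencoder(small_frames, cfg)
    _, r2 = train_autoencoder(small_frames, cfg)
    assert r1.epoch_loss == r2.epoch_loss


def test_duplicate_frames_get_identical_feature_rows(trained_ae, small_frames):
    (model, _), _ = trained_ae
    fm = extract_bottleneck_features(model, [small_frames[0], small_frames[3],
                                             small_frames[0]])
    assert np.array_equal(fm.matrix[0], fm.matrix[2])
    assert not np.array_equal(fm.matrix[0], fm.matrix[1])


def test_single_frame_feature_matrix(trained_ae, small_frames):
    (model, _), _ = trained_ae
    fm = extract_bottleneck_features(model, small_frames[:1])
    assert fm.matrix.shape == (1, 12)


def test_archetype_features_separate(trained_ae):
    """Frames from two very different lesion morphologies are farther apart
    in feature space than frames within a morphology."""
    archs = [LesionParams(arc_extent_deg=40, depth_px=4, thickness_px=8),
             LesionParams(arc_extent_deg=260, depth_px=10, thickness_px=30)]
    pb = generate_voi_with_archetypes(small_config(n_frames=12, seed=21), archs)
    frames = preprocess_voi(pb, small_preprocess())
    cfg = small_sampler(ae_epochs=12, seed=5)
    model, _ = train_autoencoder(frames, cfg)
    fm = extract_bottleneck_features(model, frames).matrix
    a, b = fm[:6], fm[6:]
    within = np.mean([np.linalg.norm(x - y) for g in (a, b)
                      for x in g for y in g])
    between = np.mean([np.linalg.norm(x - y) for x in a for y in b])
    assert within < between


# ------------------------------------------------------------- composition

def test_identical_frames_cluster_to_single_choice(small_frames):
    frames = [small_frames[0]] * 3
    plan = clustering_sample(frames, small_sampler(ratio=Fraction(1, 3), ae_epochs=2))
    assert len(plan.selected_frame_ids) == 1


def test_ratio_one_selects_all(small_frames):
    plan = clustering_sample(small_frames, small_sampler(ratio=1))
    assert plan.selected_frame_ids == list(range(len(small_frames)))


def test_sampler_cardinality_all_methods(small_frames):
    n = len(small_frames)
    for method in ("all", "equal_spacing", "clustering"):
        cfg = small_sampler(method=method, ratio=Fraction(1, 4), ae_epochs=2)
        plan = sample_voi(small_frames, cfg)
        expect = n if method == "all" else target_count(n, Fraction(1, 4))
        assert len(plan.selected_frame_ids) == expect
        assert plan.selected_frame_ids == sorted(set(plan.selected_frame_ids))


def test_clustering_selection_is_more_feature_diverse():
    """Medoid-selected frames are spread at least as widely in feature space
    as equal-spaced frames on a solid majority of seeds (7/10)."""
    archs = [LesionParams(arc_center_deg=40, arc_extent_deg=50, depth_px=4,
                          thickness_px=10, attenuation=0.35),
             LesionParams(arc_center_deg=200, arc_extent_deg=140, depth_px=8,
                          thickness_px=22, attenuation=0.22),
             LesionParams(arc_center_deg=300, arc_extent_deg=260, depth_px=12,
                          thickness_px=35, attenuation=0.12)]
    wins = 0
    for seed in range(10):
        pb = generate_voi_with_archetypes(
            small_config(n_frames=30, seed=300 + seed), archs, [0.45, 0.45, 0.10])
        frames = preprocess_voi(pb, small_preprocess())
        cfg = small_sampler(ratio=Fraction(1, 10), ae_epochs=8, seed=seed)
        model, _ = train_autoencoder(frames, cfg)
        feats = reduce_pca(extract_bottleneck_features(model, frames), 0.95).matrix

        def spread(ids):
            pts = feats[list(ids)]
            return np.mean([np.linalg.norm(a - b)
                            for i, a in enumerate(pts) for b in pts[i + 1:]])

        k = target_count(30, Fraction(1, 10))
        medoid_ids = k_medoids(feats, k, seed).medoid_indices
        equal_ids = equal_spacing_indices(30, Fraction(1, 10)).selected_frame_ids
        wins += spread(medoid_ids) >= spread(equal_ids)
    assert wins >= 7


def test_per_voi_seeds_are_order_independent():
    seeds_fwd = [per_voi_seed(7, i) for i in range(5)]
    seeds_rev = [per_voi_seed(7, i) for i in reversed(range(5))]
    assert seeds_fwd == seeds_rev[::-1]
    assert len(set(seeds_fwd)) == 5


def test_plan_json_round_trip(tmp_path, small_frames):
    plan = clustering_sample(small_frames, small_sampler(ratio=Fraction(1, 4),
                                                         ae_epochs=2, seed=3))
    write_plan(plan, tmp_path / "plan.json")
    back = read_plan(tmp_path / "plan.json")
    assert back.selected_frame_ids == plan.selected_frame_ids
    assert back.method == plan.method and back.seed == plan.seed
    assert "n_pca_components" in back.extras
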