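"""Training-frame subset selection for annotation-efficient segmentation.

Two samplers choose which frames of a VOI get annotated and used for
training:

* **equal spacing** — frames at equal z-intervals through the stack,
  exploiting the strong spatial correlation of neighbouring slices;
* **clustering** — a convolutional autoencoder is trained on the VOI's
  (preprocessed) frames, global-average-pooled bottleneck feature maps give a
  per-frame feature vector, PCA keeps the leading components explaining at
  least 95% of the variance, and k-medoids (PAM) in that reduced space picks
  ``k = target_count`` medoid frames — the most mutually dissimilar
  representatives of the VOI.

Both samplers return a :class:`SamplingPlan` with full provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import ceil
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

from .nn import Adam, ConvAutoencoder, mse_loss, run_epoch
from .preprocess import AlignedFrame

EQUAL_SPACING = "equal_spacing"
CLUSTERING = "clustering"
ALL = "all"


@dataclass
class SamplerConfig:
    method: str = CLUSTERING
    ratio: float | Fraction = Fraction(1, 3)
    ae_epochs: int = 100
    ae_lr: float = 0.001
    ae_batch: int = 64
    pca_variance: float = 0.95
    ae_widths: tuple = (8, 16, 24, 32)
    ae_bottleneck: int = 32
    ae_dec_widths: tuple = (16, 8, 4)
    feature_reduction: str = "gap"       # "gap" or "flatten"
    seed: int = 0

    def validate(self) -> None:
        if self.method not in (EQUAL_SPACING, CLUSTERING, ALL):
            raise ValueError(f"unknown method {self.method!r}")
        r = Fraction(self.ratio).limit_denominator(10**6)
        if not 0 < r <= 1:
            raise ValueError("ratio must lie in (0, 1]")
        if not 0 < self.pca_variance <= 1:
            raise ValueError("pca_variance must lie in (0, 1]")


@dataclass
class FeatureMatrix:
    matrix: np.ndarray            # (n_frames, d)
    frame_ids: list[int]
    stage: str                    # "bottleneck" or "pca"

    def validate(self) -> None:
        if self.matrix.shape[0] != len(self.frame_ids):
            raise ValueError("rows must align with frame_ids")
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("matrix must be n_frames x d with d >= 1")


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray       # (n,) cluster index per point
    medoid_indices: np.ndarray    # (k,) indices into the input set
    total_cost: float


@dataclass
class SamplingPlan:
    voi_id: str
    method: str
    ratio: str
    selected_frame_ids: list[int]
    seed: int
    extras: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "voi_id": self.voi_id, "method": self.method, "ratio": self.ratio,
            "seed": self.seed, "selected_frame_ids": self.selected_frame_ids,
            **self.extras})

    @staticmethod
    def from_json(text: str) -> "SamplingPlan":
        d = json.loads(text)
        extras = {k: v for k, v in d.items()
                  if k not in ("voi_id", "method", "ratio", "seed", "selected_frame_ids")}
        return SamplingPlan(voi_id=d["voi_id"], method=d["method"], ratio=d["ratio"],
                            selected_frame_ids=d["selected_frame_ids"],
                            seed=d["seed"], extras=extras)


def _as_fraction(ratio) -> Fraction:
    return Fraction(ratio).limit_denominator(10**6)


def target_count(n_frames: int, ratio) -> int:
    """Number of frames to select: ceil(n * ratio), at least 1."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    r = _as_fraction(ratio)
    if not 0 < r <= 1:
        raise ValueError("ratio must lie in (0, 1]")
    return max(1, ceil(n_frames * r))


def equal_spacing_indices(n_frames: int, ratio, *, voi_id: str = "voi") -> SamplingPlan:
    """Frames at equal z-spacing starting from index 0.

    Index j of the m = ceil(n*ratio) selections is ``floor(j / ratio)``; for
    the unit-fraction ratios 1/s this is exactly the stride-s rule (every
    s-th frame), and for any rational ratio it yields exactly m distinct
    indices inside the stack. Deterministic — no randomness involved.
    """
    r = _as_fraction(ratio)
    m = target_count(n_frames, r)
    idx = [int(j / r) for j in range(m)]   # Fraction division, exact floor via int()
    return SamplingPlan(voi_id=voi_id, method=EQUAL_SPACING, ratio=str(r),
                        selected_frame_ids=idx, seed=0)


# ---------------------------------------------------------------------------
# autoencoder features
# ---------------------------------------------------------------------------

@dataclass
class TrainingRecord:
    epoch_loss: list[float]

    @property
    def final_loss(self) -> float:
        return self.epoch_loss[-1]


def _stack(frames) -> np.ndarray:
    imgs = [f.image if isinstance(f, AlignedFrame) else np.asarray(f) for f in frames]
    shapes = {i.shape for i in imgs}
    if len(shapes) != 1:
        raise ValueError(f"frames must share one shape, got {sorted(shapes)}")
    return np.stack(imgs).astype(np.float32)[:, None]   # (N, 1, H, W)


def train_autoencoder(frames, cfg: SamplerConfig):
    """Train the per-VOI reconstruction autoencoder.

    All frames of the VOI are both inputs and targets; MSE loss, Adam, exactly
    ``cfg.ae_epochs`` epochs at ``cfg.ae_lr`` with batch ``cfg.ae_batch``.
    Returns ``(model, TrainingRecord)``; RNG is fully determined by
    ``cfg.seed``.
    """
    cfg.validate()
    if len(frames) < 1:
        raise ValueError("need at least one frame")
    x = _stack(frames)
    ss = np.random.SeedSequence([cfg.seed, 0xae])
    init_seed, shuffle_seed = ss.spawn(2)
    net = ConvAutoencoder(
        enc_widths=cfg.ae_widths, bottleneck_ch=cfg.ae_bottleneck,
        dec_widths=cfg.ae_dec_widths,
        seed=int(init_seed.generate_state(1)[0] % 2**31))
    opt = Adam(net, lr=cfg.ae_lr)
    rng = np.random.default_rng(shuffle_seed)
    record = TrainingRecord(epoch_loss=[])
    for _ in range(cfg.ae_epochs):
        loss = run_epoch(net, opt, x, x, mse_loss, cfg.ae_batch, rng)
        record.epoch_loss.append(loss)
    return net, record


def reconstruction_mse(model, frames) -> float:
    """Mean per-pixel squared reconstruction error over the given frames."""
    x = _stack(frames)
    total, npx = 0.0, 0
    for i in range(x.shape[0]):
        rec = model.forward(x[i])
        total += float(np.sum((rec - x[i]) ** 2))
        npx += x[i].size
    return total / npx


def extract_bottleneck_features(model, frames, *, reduction: str = "gap") -> FeatureMatrix:
    """Per-frame feature vectors from the trained autoencoder's bottleneck.

    ``gap``: global average pool each bottleneck channel (dimension equals the
    channel count, independent of frame size); ``flatten``: ravel the maps.
    """
    x = _stack(frames)
    rows = []
    for i in range(x.shape[0]):
        fm = model.encode(x[i])
        if reduction == "gap":
            rows.append(fm.mean(axis=(1, 2)))
        elif reduction == "flatten":
            rows.append(fm.ravel())
        else:
            raise ValueError(f"unknown reduction {reduction!r}")
    fm = FeatureMatrix(matrix=np.stack(rows).astype(np.float64),
                       frame_ids=list(range(x.shape[0])), stage="bottleneck")
    fm.validate()
    return fm


def reduce_pca(features: FeatureMatrix, variance: float = 0.95) -> FeatureMatrix:
    """Keep the fewest principal components explaining >= ``variance``."""
    if features.matrix.shape[0] < 2:
        raise ValueError("PCA needs at least two frames")
    X = features.matrix
    if np.allclose(X.var(axis=0), 0.0):
        warnings.warn("all frames identical in feature space; "
                      "returning a single constant component")
        out = FeatureMatrix(matrix=np.zeros((X.shape[0], 1)),
                            frame_ids=list(features.frame_ids), stage="pca")
        out.validate()
        return out
    n_components = variance if variance < 1.0 else min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    Z = pca.fit_transform(X)
    out = FeatureMatrix(matrix=Z, frame_ids=list(features.frame_ids), stage="pca")
    out.validate()
    return out


# ---------------------------------------------------------------------------
# k-medoids (PAM)
# ---------------------------------------------------------------------------

def _pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import cdist
    return cdist(X, X)


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD: start from the point minimising total distance, then
    repeatedly add the point with the best marginal cost reduction."""
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gain = np.maximum(dmin[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -np.inf
        medoids.append(int(np.argmax(gain)))
    return medoids


def _farthest_first(D: np.ndarray, k: int) -> list[int]:
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        dmin[medoids] = -np.inf
        medoids.append(int(np.argmax(dmin)))
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Steepest improving (medoid, non-medoid) exchanges to convergence."""
    n = D.shape[0]

    def cost_of(meds):
        return float(D[:, meds].min(axis=1).sum())

    current = cost_of(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            for h in range(n):
                if h in med_set:
                    continue
                delta = current - cost_of(others + [h])
                if delta > best[0] + 1e-12:
                    best = (delta, mi, h)
        if best[1] is not None:
            medoids = list(medoids)
            medoids[best[1]] = best[2]
            current = cost_of(medoids)
            improved = True
    return medoids, current


def k_medoids(points: FeatureMatrix | np.ndarray, k: int, seed: int = 0,
              n_restarts: int = 2) -> ClusterResult:
    """Partitioning Around Medoids on the Euclidean distance matrix.

    SWAP (steepest improving exchange to convergence) is run from the greedy
    BUILD initialization and, to escape the occasional shallow local minimum,
    from a farthest-first initialization plus ``n_restarts`` seeded random
    ones; the lowest-cost converged solution wins (ties toward the earlier
    start). Deterministic given ``seed``.
    """
    X = points.matrix if isinstance(points, FeatureMatrix) else np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must lie in [1, {n}]")
    D = _pairwise_euclidean(X)

    inits = [_pam_build(D, k), _farthest_first(D, k)]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9a]))
    for _ in range(n_restarts):
        inits.append(sorted(rng.choice(n, size=k, replace=False).tolist()))

    best_meds, best_cost = None, np.inf
    for init in inits:
        meds, cost = _pam_swap(D, init)
        if cost < best_cost - 1e-12:
            best_meds, best_cost = meds, cost

    medoids_sorted = sorted(best_meds)
    cost = float(D[:, medoids_sorted].min(axis=1).sum())
    assignments = np.argmin(D[:, medoids_sorted], axis=1)
    return ClusterResult(k=k, assignments=assignments,
                         medoid_indices=np.asarray(medoids_sorted, dtype=np.int64),
                         total_cost=cost)


# ---------------------------------------------------------------------------
# composed samplers
# ---------------------------------------------------------------------------

def clustering_sample(voi_frames, cfg: SamplerConfig, *, voi_id: str = "voi") -> SamplingPlan:
    """autoencoder -> bottleneck features -> PCA -> k-medoids -> medoid frames."""
    cfg.validate()
    n = len(voi_frames)
    k = target_count(n, cfg.ratio)
    if k >= n:
        return SamplingPlan(voi_id=voi_id, method=CLUSTERING, ratio=str(_as_fraction(cfg.ratio)),
                            selected_frame_ids=list(range(n)), seed=cfg.seed)
    model, record = train_autoencoder(voi_frames, cfg)
    feats = extract_bottleneck_features(model, voi_frames, reduction=cfg.feature_reduction)
    reduced = reduce_pca(feats, cfg.pca_variance)
    clusters = k_medoids(reduced, k, cfg.seed)
    selected = sorted(int(i) for i in clusters.medoid_indices)
    return SamplingPlan(
        voi_id=voi_id, method=CLUSTERING, ratio=str(_as_fraction(cfg.ratio)),
        selected_frame_ids=selected, seed=cfg.seed,
        extras={"n_pca_components": int(reduced.matrix.shape[1]),
                "ae_final_loss": record.final_loss,
                "medoid_cost": clusters.total_cost})


def sample_voi(voi_frames, cfg: SamplerConfig, *, voi_id: str = "voi") -> SamplingPlan:
    """Dispatch on ``cfg.method``; every plan satisfies
    ``len(selected) == target_count(n, ratio)``."""
    cfg.validate()
    n = len(voi_frames)
    if cfg.method == ALL:
        return SamplingPlan(voi_id=voi_id, method=ALL, ratio="1",
                            selected_frame_ids=list(range(n)), seed=cfg.seed)
    if cfg.method == EQUAL_SPACING:
        plan = equal_spacing_indices(n, cfg.ratio, voi_id=voi_id)
        plan.seed = cfg.seed
        return plan
    return clustering_sample(voi_frames, cfg, voi_id=voi_id)


def per_voi_seed(master_seed: int, voi_index: int) -> int:
    """Independent per-VOI sampler seed; immune to VOI processing order."""
    return int(np.random.SeedSequence([master_seed, voi_index]).generate_state(1)[0] % 2**31)


def write_plan(plan: SamplingPlan, path: str | Path) -> None:
    Path(path).write_text(plan.to_json())


def read_plan(path: str | Path) -> SamplingPlan:
    return SamplingPlan.from_json(Path(path).read_text())
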