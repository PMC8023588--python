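"""Experiment protocol: held-out rotation, stratified VOI folds, the
seven-model sampler comparison, and the fewer-VOIs experiment.

VOIs — never frames — are the unit of splitting, so no frame of a held-out
VOI can leak into training. Within the training portion, samplers decide
which frames are annotated; inside the cross-validation only those selected
frames carry labels (that is the premise of annotation reduction), while
held-out VOIs are fully annotated for evaluation. Sampler comparisons reuse
identical split plans and segmentation seeds, so the sampler is the only
varying factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from math import ceil

import numpy as np
import pandas as pd

from .evaluate import (average_precision_per_frame, f1_per_class,
                       metrics_report, wilcoxon_vs_baseline)
from .phantom import CALCIFICATION, PolarPullback
from .preprocess import PreprocessConfig, preprocess_voi
from .segment import (SegTrainConfig, predict_mask, predict_probability,
                      train_fixed_epochs, train_segmenter)
from .select import (ALL, CLUSTERING, EQUAL_SPACING, SamplerConfig,
                     per_voi_seed, sample_voi)


@dataclass
class SplitPlan:
    iteration: int                       # 1-based
    heldout_voi_ids: list[str]
    fold_assignment: dict[str, int]      # training voi_id -> fold (1..k)
    labels: dict[str, str]

    def training_voi_ids(self) -> list[str]:
        return sorted(self.fold_assignment)

    def validate(self, k: int) -> None:
        held = set(self.heldout_voi_ids)
        train = set(self.fold_assignment)
        if held & train:
            raise ValueError("held-out and training VOIs overlap")
        folds = {}
        for v, f in self.fold_assignment.items():
            folds.setdefault(f, []).append(v)
        if set(folds) - set(range(1, k + 1)):
            raise ValueError("fold indices out of range")
        # stratification: per-fold calcification count within +-1 of balanced
        calc_counts = [sum(self.labels[v] == CALCIFICATION for v in vs)
                       for vs in folds.values()]
        if calc_counts and max(calc_counts) - min(calc_counts) > 1:
            raise ValueError("folds not label-stratified within +-1 VOI")


def make_split_plans(voi_ids: list[str], labels: dict[str, str],
                     n_iter: int = 4, k: int = 5, seed: int = 0) -> list[SplitPlan]:
    """Disjoint held-out rotation plus stratified training folds.

    The VOI set is partitioned into ``n_iter`` stratified held-out sets whose
    union covers every VOI exactly once (roughly 1/n_iter each); within each
    iteration the remaining VOIs go round-robin into ``k`` folds per label.
    """
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[str]] = {}
    for v in voi_ids:
        by_label.setdefault(labels[v], []).append(v)
    heldout: list[list[str]] = [[] for _ in range(n_iter)]
    for lab in sorted(by_label):
        order = list(rng.permutation(sorted(by_label[lab])))
        for i, chunk in enumerate(np.array_split(order, n_iter)):
            heldout[i].extend(chunk.tolist())

    plans = []
    for i in range(n_iter):
        held = set(heldout[i])
        assignment: dict[str, int] = {}
        for lab in sorted(by_label):
            train = [v for v in sorted(by_label[lab]) if v not in held]
            order = list(rng.permutation(train))
            for j, v in enumerate(order):
                assignment[v] = 1 + j % k
        plan = SplitPlan(iteration=i + 1, heldout_voi_ids=sorted(held),
                         fold_assignment=assignment, labels=dict(labels))
        plan.validate(k)
        plans.append(plan)
    # every VOI held out exactly once
    all_held = [v for h in heldout for v in h]
    if sorted(all_held) != sorted(voi_ids):
        raise AssertionError("held-out sets must partition the VOI set")
    return plans


@dataclass
class ExperimentConfig:
    """Scale knobs for the protocol; defaults are desk-scale but structural
    elements (stratification, rotation, grid, patience) match the full study."""

    ratios: tuple = (Fraction(1, 2), Fraction(1, 3), Fraction(1, 10))
    n_iterations: int = 4
    cv_folds: int = 5
    cv_rounds: int | None = None          # None -> cv_folds rotations
    n_shuffles: int = 10
    grid: tuple = ((1e-3, 8),)            # (lr, batch) candidates
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    segment: SegTrainConfig = field(default_factory=SegTrainConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    master_seed: int = 0

    def seven_model_grid(self) -> list[tuple[str, Fraction | int]]:
        out = [(ALL, Fraction(1, 1))]
        out += [(EQUAL_SPACING, r) for r in self.ratios]
        out += [(CLUSTERING, r) for r in self.ratios]
        return out


def preprocess_dataset(dataset: list[PolarPullback],
                       cfg: PreprocessConfig | None = None) -> dict[str, list]:
    cfg = cfg or PreprocessConfig()
    return {pb.voi_id: preprocess_voi(pb, cfg) for pb in dataset}


def _sampling_plans(frames_by_voi, voi_ids, sampler_cfg: SamplerConfig,
                    master_seed: int):
    plans = {}
    order = {v: i for i, v in enumerate(sorted(frames_by_voi))}
    for v in voi_ids:
        cfg = replace(sampler_cfg, seed=per_voi_seed(master_seed, order[v]))
        plans[v] = sample_voi(frames_by_voi[v], cfg, voi_id=v)
    return plans


def run_model(frames_by_voi: dict[str, list], split_plan: SplitPlan,
              sampler_cfg: SamplerConfig, seg_cfg: SegTrainConfig,
              grid=((1e-3, 8),), cv_rounds: int | None = None,
              cv_folds: int = 5, master_seed: int = 0) -> dict:
    """One sampler/iteration cell of the protocol.

    Samples frames per training VOI, grid-searches (lr, batch) by k-fold CV
    mean calcific F1 on the test folds, retrains on the full training set for
    the CV-average epoch count, and evaluates on the fully annotated held-out
    VOIs. Returns the metrics report, per-frame APs, and provenance.
    """
    train_ids = split_plan.training_voi_ids()
    plans = _sampling_plans(frames_by_voi, train_ids, sampler_cfg, master_seed)
    selected = {v: [frames_by_voi[v][i] for i in plans[v].selected_frame_ids]
                for v in train_ids}

    # leakage guard: training frames come only from non-held-out VOIs
    assert not set(train_ids) & set(split_plan.heldout_voi_ids)

    folds: dict[int, list[str]] = {}
    for v in train_ids:
        folds.setdefault(split_plan.fold_assignment[v], []).append(v)
    fold_ids = sorted(folds)
    rounds = cv_rounds if cv_rounds is not None else len(fold_ids)

    def frames_of(vois):
        return [f for v in vois for f in selected[v]]

    if len(fold_ids) < 2:
        # too few training VOIs for VOI-level folds (fewer-VOIs rivals at
        # small scale): frame-level 80/20 train/val split with early stopping
        frames = frames_of(train_ids)
        n_val = max(1, len(frames) // 5)
        lr, batch = grid[0]
        cfg = replace(seg_cfg, lr=lr, batch_size=batch,
                      seed=int(np.random.SeedSequence(
                          [master_seed, split_plan.iteration]).generate_state(1)[0] % 2**31))
        model, _ = train_segmenter(frames[:-n_val] or frames, frames[-n_val:], cfg)
        best = {"score": np.nan, "lr": lr, "batch": batch, "epochs": None}
    else:
        best = None
        for lr, batch in grid:
            scores, epochs = [], []
            for j in range(min(rounds, len(fold_ids))):
                val_f = fold_ids[j]
                # with <3 folds there is no spare fold; validation doubles as test
                test_f = fold_ids[(j + 1) % len(fold_ids)] if len(fold_ids) >= 3 else val_f
                train_vois = [v for f in fold_ids if f not in (val_f, test_f)
                              for v in folds[f]]
                cfg = replace(seg_cfg, lr=lr, batch_size=batch,
                              seed=int(np.random.SeedSequence(
                                  [master_seed, split_plan.iteration, j]).generate_state(1)[0] % 2**31))
                model, rec = train_segmenter(frames_of(train_vois),
                                             frames_of(folds[val_f]), cfg)
                test_frames = frames_of(folds[test_f])
                pm = predict_mask(model, test_frames)
                tm = np.stack([f.mask for f in test_frames])
                scores.append(f1_per_class(pm, tm)[0])
                epochs.append(rec.stopped_epoch)
            mean_score = float(np.mean(scores))
            if best is None or mean_score > best["score"] + 1e-12:
                best = {"score": mean_score, "lr": lr, "batch": batch,
                        "epochs": int(round(np.mean(epochs)))}

        final_cfg = replace(seg_cfg, lr=best["lr"], batch_size=best["batch"],
                            seed=int(np.random.SeedSequence(
                                [master_seed, split_plan.iteration]).generate_state(1)[0] % 2**31))
        model, _ = train_fixed_epochs(frames_of(train_ids), best["epochs"], final_cfg)

    held_frames = [f for v in split_plan.heldout_voi_ids for f in frames_by_voi[v]]
    probs = predict_probability(model, held_frames)
    masks = (probs >= 0.5).astype(np.uint8)
    truth = np.stack([f.mask for f in held_frames])
    report = metrics_report(masks, probs, truth)
    per_frame_ap = average_precision_per_frame(probs, truth)
    return {"report": report, "per_frame_ap": per_frame_ap, "plans": plans,
            "best_hyperparams": best, "model": model,
            "n_train_frames": sum(len(v) for v in selected.values())}


def run_seven_model_comparison(dataset: list[PolarPullback],
                               cfg: ExperimentConfig) -> pd.DataFrame:
    """Mean +- standard error of each metric across held-out iterations for
    the seven sampler models (rows shaped like the study's summary table)."""
    frames_by_voi = preprocess_dataset(dataset, cfg.preprocess)
    labels = {pb.voi_id: pb.voi_label for pb in dataset}
    plans = make_split_plans(sorted(labels), labels, cfg.n_iterations,
                             cfg.cv_folds, cfg.master_seed)
    rows = []
    for method, ratio in cfg.seven_model_grid():
        scfg = replace(cfg.sampler, method=method, ratio=ratio)
        f1c, f1o, aps = [], [], []
        for plan in plans:
            res = run_model(frames_by_voi, plan, scfg, cfg.segment,
                            grid=cfg.grid, cv_rounds=cfg.cv_rounds,
                            cv_folds=cfg.cv_folds, master_seed=cfg.master_seed)
            f1c.append(res["report"].f1_calcific)
            f1o.append(res["report"].f1_other)
            aps.append(res["report"].ap)
        se = lambda v: float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        rows.append({"model": f"{method}_{ratio}" if method != ALL else ALL,
                     "f1_calcific": float(np.mean(f1c)), "f1_calcific_se": se(f1c),
                     "f1_other": float(np.mean(f1o)), "f1_other_se": se(f1o),
                     "ap": float(np.mean(aps)), "ap_se": se(aps)})
    return pd.DataFrame(rows)


def serial_voi_prefix(train_ids: list[str], frames_by_voi, budget: int,
                      rng: np.random.Generator) -> list[str]:
    """Shuffle VOIs and take whole VOIs one after another until the frame
    budget is reached; the VOI crossing the budget is included whole."""
    order = list(rng.permutation(train_ids))
    chosen, total = [], 0
    for v in order:
        chosen.append(v)
        total += len(frames_by_voi[v])
        if total >= budget:
            break
    return chosen


def run_fewer_vois_experiment(dataset: list[PolarPullback], cfg: ExperimentConfig,
                              ratio=Fraction(1, 10)) -> list[dict]:
    """Does drawing the same image budget from fewer VOIs hurt?

    Per iteration: the clustered sampler at ``ratio`` is the baseline; each of
    ``n_shuffles`` rival models trains on whole VOIs taken in a shuffled
    serial order until one-tenth of the training frames is reached. Rival APs
    are compared to the baseline AP with a one-sample Wilcoxon test
    (alternative: rivals lower).
    """
    frames_by_voi = preprocess_dataset(dataset, cfg.preprocess)
    labels = {pb.voi_id: pb.voi_label for pb in dataset}
    plans = make_split_plans(sorted(labels), labels, cfg.n_iterations,
                             cfg.cv_folds, cfg.master_seed)
    out = []
    for plan in plans:
        scfg = replace(cfg.sampler, method=CLUSTERING, ratio=ratio)
        base = run_model(frames_by_voi, plan, scfg, cfg.segment, grid=cfg.grid,
                         cv_rounds=cfg.cv_rounds, cv_folds=cfg.cv_folds,
                         master_seed=cfg.master_seed)
        baseline_ap = base["report"].ap
        train_ids = plan.training_voi_ids()
        total = sum(len(frames_by_voi[v]) for v in train_ids)
        budget = ceil(total * float(ratio))

        rival_aps, orders = [], []
        for s in range(cfg.n_shuffles):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.master_seed, plan.iteration, s, 0xf])
            )
            chosen = serial_voi_prefix(train_ids, frames_by_voi, budget, rng)
            orders.append(chosen)
            sub_plan = SplitPlan(iteration=plan.iteration,
                                 heldout_voi_ids=plan.heldout_voi_ids,
                                 fold_assignment={v: plan.fold_assignment[v] for v in chosen},
                                 labels=plan.labels)
            res = run_model(frames_by_voi, sub_plan,
                            replace(cfg.sampler, method=ALL), cfg.segment,
                            grid=cfg.grid, cv_rounds=1, cv_folds=cfg.cv_folds,
                            master_seed=cfg.master_seed + 1000 + s)
            rival_aps.append(res["report"].ap)
        stat, p = wilcoxon_vs_baseline(np.asarray(rival_aps), baseline_ap, "less")
        out.append({"iteration": plan.iteration, "baseline_ap": baseline_ap,
                    "rival_aps": rival_aps, "voi_orders": orders,
                    "wilcoxon_statistic": stat, "p_value": p,
                    "median_rival_ap": float(np.median(rival_aps))})
    return out
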