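"""End-to-end pruning experiments and evaluation metrics.

Runs the full pipeline on a feature table: stratified 7:2:1
train/prune/test split, overproduction of M bootstrap-trained trees,
per-classifier marking under a chosen pruning measure, selection of the
top-T sub-ensemble, and majority-vote evaluation with accuracy,
sensitivity (true-positive rate), specificity (true-negative rate) and
rank-based AUC.  Repeated Monte-Carlo validation (default 50 independent
stratified splits) aggregates mean and std per metric.  A rank-scoring
rule compares several models across metrics: per metric the best model
receives n_models points, the next n_models - 1, and so on, ties sharing
the mean of their would-be points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score

from .ensemble import (DatasetSplit, EnsemblePool, PrunedEnsemble,
                       compute_margins, compute_vote_matrix, predict, train_pool)
from .measures import (MDMConfig, MSMConfig, mdm_scores, msm_scores,
                       sdacc_greedy_select, umep_scores)

__all__ = [
    "ExperimentConfig",
    "ConfusionCounts",
    "MetricsReport",
    "MEASURES",
    "stratified_split",
    "run_msep",
    "confusion_metrics",
    "auc_score",
    "cross_validate",
    "rank_scores",
]

MEASURES = ("msm", "mep", "umep", "mdm", "sdacc", "full")

METRIC_NAMES = ("acc", "sen", "spe", "auc")


@dataclass
class ExperimentConfig:
    """One pruning experiment: split ratio, pool/sub-ensemble sizes,
    measure choice and its parameters, repetition count, master seed.

    Defaults follow the standard protocol for this method family:
    M = 101 overproduced trees, T = 11 kept (about 10%), 7:2:1
    train/prune/test, 50 repeated stratified splits.
    """

    split_ratio: tuple[float, float, float] = (7.0, 2.0, 1.0)
    repetitions: int = 50
    M: int = 101
    T: int = 11
    sample_fraction: float = 0.3
    measure: str = "msm"
    msm: MSMConfig = field(default_factory=MSMConfig)
    mdm: MDMConfig = field(default_factory=MDMConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.split_ratio) or len(self.split_ratio) != 3:
            raise ValueError("split_ratio must be three positive numbers")
        if self.T > self.M or self.M % 2 == 0 or self.T % 2 == 0:
            raise ValueError("require odd T <= odd M")
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Per-repetition metric values with mean/std aggregates.

    Undefined values (e.g. sensitivity with no positives in the test
    part) are stored as NaN and excluded from the aggregates;
    ``n_defined`` records how many repetitions contributed to each."""

    per_repetition: list[dict]
    mean: dict
    std: dict
    n_defined: dict


def _largest_remainder(n: int, ratio: np.ndarray) -> np.ndarray:
    quota = n * ratio / ratio.sum()
    base = np.floor(quota).astype(int)
    rem = quota - base
    for k in np.argsort(-rem)[: n - base.sum()]:
        base[k] += 1
    return base


def stratified_split(y: np.ndarray, ratio: tuple[float, float, float],
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint train/prune/test index arrays, stratified by class, part
    sizes by largest-remainder rounding of the ratio within each class."""
    y = np.asarray(y, dtype=int)
    ratio_arr = np.asarray(ratio, dtype=float)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        counts = _largest_remainder(len(idx), ratio_arr)
        if np.any(counts == 0):
            raise ValueError(
                f"class {cls} (n={len(idx)}) cannot populate all three parts "
                f"at ratio {tuple(ratio)}"
            )
        bounds = np.cumsum(counts)
        parts[0].extend(idx[: bounds[0]])
        parts[1].extend(idx[bounds[0]: bounds[1]])
        parts[2].extend(idx[bounds[1]:])
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


def _score_pool(votes, margins, config: ExperimentConfig) -> PrunedEnsemble:
    if config.measure == "full":
        return PrunedEnsemble(np.arange(config.M), "full")
    if config.measure == "sdacc":
        return sdacc_greedy_select(votes, config.T)
    if config.measure == "msm":
        ranking = msm_scores(votes, margins, config.msm)
    elif config.measure == "mep":
        cfg = MSMConfig(theta=config.msm.theta, bonus_enabled=False)
        ranking = msm_scores(votes, margins, cfg)
    elif config.measure == "umep":
        ranking = umep_scores(votes, margins)
    else:  # mdm
        ranking = mdm_scores(votes, margins, config.mdm)
    return ranking.top(config.T)


def run_msep(X: np.ndarray, y: np.ndarray, config: ExperimentConfig,
             seed: int | None = None) -> tuple[PrunedEnsemble, dict]:
    """Execute one full ordering-ensemble-pruning run on a single split.

    Returns the selected sub-ensemble and a metrics dict (confusion
    counts, acc/sen/spe/auc) for the test part.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tr, pr, te = stratified_split(y, config.split_ratio, rng)
    split = DatasetSplit(X[tr], y[tr], X[pr], y[pr], X[te], y[te])

    pool_seed = int(rng.integers(2 ** 31 - 1))
    pool = train_pool(split.X_train, split.y_train, M=config.M,
                      sample_fraction=config.sample_fraction, seed=pool_seed)
    votes = compute_vote_matrix(pool, split.X_prune, split.y_prune)
    margins = compute_margins(votes)
    pruned = _score_pool(votes, margins, config)

    y_pred, scores = predict(pool, pruned.selected, split.X_test)
    metrics = confusion_metrics(split.y_test, y_pred)
    metrics["auc"] = auc_score(split.y_test, scores)
    return pruned, metrics


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    """Confusion counts and acc/sen/spe, positive class = 1.

    Undefined ratios (zero denominator) are returned as NaN — flagged as
    missing rather than coerced to 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    counts = ConfusionCounts(tp, fp, tn, fn)
    return {
        "counts": counts,
        "acc": (tp + tn) / counts.total,
        "sen": tp / (tp + fn) if tp + fn > 0 else float("nan"),
        "spe": tn / (fp + tn) if fp + tn > 0 else float("nan"),
    }


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted half; NaN if only
    one class is present."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        return float("nan")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def cross_validate(X: np.ndarray, y: np.ndarray,
                   config: ExperimentConfig) -> MetricsReport:
    """Repeated Monte-Carlo validation: ``config.repetitions`` independent
    stratified splits, each a full train/prune/select/test run."""
    master = np.random.default_rng(config.seed)
    rep_seeds = master.integers(2 ** 31 - 1, size=config.repetitions)
    per_rep = []
    for s in rep_seeds:
        _, metrics = run_msep(X, y, config, seed=int(s))
        per_rep.append({k: metrics[k] for k in METRIC_NAMES})
    mean, std, n_def = {}, {}, {}
    for k in METRIC_NAMES:
        vals = np.array([r[k] for r in per_rep], dtype=float)
        ok = vals[~np.isnan(vals)]
        n_def[k] = int(ok.size)
        mean[k] = float(ok.mean()) if ok.size else float("nan")
        std[k] = float(ok.std(ddof=0)) if ok.size else float("nan")
    return MetricsReport(per_rep, mean, std, n_def)


def rank_scores(metric_table: pd.DataFrame) -> pd.DataFrame:
    """Rank-scoring comparison of models (rows) across metrics (columns).

    Per metric, the best model gets n_models points, the runner-up
    n_models - 1, and so on; tied models share the mean of their
    would-be points.  Missing values are excluded pairwise (with a
    warning) and the per-model average is taken over its defined metrics.
    Returns the per-metric points plus an ``average`` column.
    """
    if metric_table.shape[0] < 2:
        raise ValueError("need at least 2 models to rank")
    points = pd.DataFrame(index=metric_table.index, dtype=float)
    for col in metric_table.columns:
        vals = metric_table[col].to_numpy(dtype=float)
        missing = np.isnan(vals)
        if missing.any():
            warnings.warn(f"metric {col!r}: {missing.sum()} missing value(s) excluded")
        col_points = np.full(len(vals), np.nan)
        if (~missing).sum() >= 1:
            # ascending average ranks == points (best value -> most points)
            col_points[~missing] = rankdata(vals[~missing], method="average")
        points[col] = col_points
    points["average"] = points.mean(axis=1, skipna=True)
    return points
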