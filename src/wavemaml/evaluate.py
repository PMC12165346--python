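"""Metrics, cross-validated model comparison, and feature export.

Binary classification is scored from the confusion counts:

    accuracy = (TP + TN) / (TP + TN + FP + FN)
    F1       = 2 TP / (2 TP + FP + FN)

Model comparison uses stratified k-fold cross-validation (optionally grouped
by subject so one subject's epochs never straddle a fold boundary) followed
by a paired t-test on the per-fold metric differences:

    t = mean(d) / (sd(d) / sqrt(k)),  df = k - 1,

with sd the k-1-denominator sample standard deviation and a two-sided
p-value from Student's t distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .data import ImageSet

__all__ = [
    "ConfusionCounts",
    "FoldResults",
    "PairedTTestResult",
    "confusion",
    "accuracy",
    "f1",
    "kfold_cv",
    "paired_ttest",
    "student_t_sf_df4",
    "embed_features",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-table counts; they partition the evaluated examples."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class FoldResults:
    """Per-fold values of one metric for one model, as percentages."""

    values: tuple[float, ...]
    model_id: str = ""
    metric: str = "accuracy"

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValueError("need at least 2 folds")

    @property
    def k(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    df: int
    p: float


def confusion(y_true, y_pred, positive_class=1) -> ConfusionCounts:
    """Confusion counts of binary label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 1:
        raise ValueError("empty label vectors")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionCounts(
        TP=int(np.sum(pos_t & pos_p)),
        TN=int(np.sum(~pos_t & ~pos_p)),
        FP=int(np.sum(~pos_t & pos_p)),
        FN=int(np.sum(pos_t & ~pos_p)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise ValueError("accuracy undefined for zero examples")
    return (c.TP + c.TN) / c.total


def f1(c: ConfusionCounts) -> float:
    """2 TP / (2 TP + FP + FN); defined as 0 when no positives exist at all."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        warnings.warn("F1 undefined (no true or predicted positives); returning 0", stacklevel=2)
        return 0.0
    return 2 * c.TP / denom


def kfold_cv(
    dataset: ImageSet,
    k: int,
    train_fn: Callable[[ImageSet], object],
    eval_fn: Callable[[object, ImageSet], dict[str, float]],
    seed: int = 0,
    group_by_subject: bool = True,
    model_id: str = "",
) -> dict[str, FoldResults]:
    """Stratified k-fold cross-validation, seeded and optionally subject-grouped.

    Each fold trains on k-1 parts via ``train_fn`` and scores the held-out
    part via ``eval_fn`` (which returns metric name -> fraction). Metric
    values are collected per fold as percentages. With
    ``group_by_subject=True`` (the leakage-safe default) all epochs of a
    subject stay within a single fold; the metadata must then carry a
    ``subject`` column.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = dataset.labels
    if group_by_subject:
        if dataset.meta is None or "subject" not in dataset.meta.columns:
            raise ValueError("subject grouping requires a 'subject' metadata column")
        groups = dataset.meta["subject"].to_numpy()
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(y)), y, groups)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(y)), y)
    per_metric: dict[str, list[float]] = {}
    for train_idx, test_idx in splits:
        test_y = y[test_idx]
        if len(np.unique(test_y)) < len(np.unique(y)):
            raise ValueError("a class is absent from one fold; use more data or fewer folds")
        model = train_fn(dataset.subset(train_idx))
        scores = eval_fn(model, dataset.subset(test_idx))
        for name, value in scores.items():
            per_metric.setdefault(name, []).append(100.0 * value)
    return {
        name: FoldResults(tuple(vals), model_id=model_id, metric=name)
        for name, vals in per_metric.items()
    }


def paired_ttest(a: FoldResults, b: FoldResults) -> PairedTTestResult:
    """Paired t-test on per-fold differences a - b (two-sided)."""
    if a.k != b.k:
        raise ValueError(f"fold counts differ: {a.k} vs {b.k}")
    d = np.asarray(a.values, dtype=float) - np.asarray(b.values, dtype=float)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical fold values: no difference at all
            return PairedTTestResult(t=0.0, df=a.k - 1, p=1.0)
        raise ValueError("zero variance of paired differences; t statistic undefined")
    k = a.k
    t = d.mean() / (sd / np.sqrt(k))
    p = 2.0 * stats.t.sf(abs(t), df=k - 1)
    return PairedTTestResult(t=float(t), df=k - 1, p=float(p))


def student_t_sf_df4(t: float) -> float:
    """Closed-form one-sided survival P(T > t) for Student's t with df=4.

    P(T > t) = 1/2 - (3/4) s + (1/4) s^3 with s = t / sqrt(t^2 + 4).
    Used as an exact analytic cross-check of the p-value computation.
    """
    s = t / np.sqrt(t * t + 4.0)
    return 0.5 - 0.75 * s + 0.25 * s**3


def embed_features(state, images) -> np.ndarray:
    """Penultimate-layer embeddings of the dual model (weight-scaled concat).

    Returns ``[w1 * feat_a, w2 * feat_b]`` per image, suitable for export to
    external projection tools (e.g. t-SNE). Deterministic in eval mode.
    """
    from .models import forward

    _, fa = forward(state.params_a, images, return_features=True)
    _, fb = forward(state.params_b, images, return_features=True)
    w1, w2 = state.weights.weights
    return np.concatenate([w1 * fa.data, w2 * fb.data], axis=1)
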