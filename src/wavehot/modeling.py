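"""Gradient-boosted tree training, stratified cross-validation with
leakage-safe in-fold balancing, and the SEN/SPE/PRE/F1/ACC/MCC/AUC metrics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .balance import DEFAULT_SMOTE_SEED, random_augment, smote_augment
from .schema import FeatureTable, SchemaError

__all__ = [
    "ClassifierConfig",
    "ConfusionCounts",
    "MetricSet",
    "TrainedModel",
    "train_classifier",
    "confusion",
    "metrics_from_confusion",
    "roc_auc",
    "cross_validate",
    "mean_metrics",
]

SCORE_THRESHOLD = 0.5


@dataclass(frozen=True)
class ClassifierConfig:
    """Histogram-based gradient-boosted tree configuration.

    Defaults follow the tuned model: max_depth=15, num_leaves=50,
    n_estimators=1000. ``factory``, when given, overrides the default
    estimator and must return an object with sklearn's
    fit/predict_proba contract.
    """

    max_depth: int = 15
    num_leaves: int = 50
    n_estimators: int = 1000
    seed: int = 0
    factory: Optional[Callable[["ClassifierConfig"], object]] = None

    def __post_init__(self) -> None:
        if min(self.max_depth, self.num_leaves, self.n_estimators) < 1:
            raise ValueError("classifier parameters must be positive")

    def make(self):
        if self.factory is not None:
            return self.factory(self)
        return HistGradientBoostingClassifier(
            max_depth=self.max_depth,
            max_leaf_nodes=self.num_leaves,
            max_iter=self.n_estimators,
            early_stopping=False,
            random_state=self.seed,
        )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    sen: float
    spe: float
    pre: float
    f1: float
    acc: float
    mcc: float
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        out = {"sen": self.sen, "spe": self.spe, "pre": self.pre,
               "f1": self.f1, "acc": self.acc, "mcc": self.mcc}
        if self.auc is not None:
            out["auc"] = self.auc
        return out


class TrainedModel:
    """Fitted classifier bound to its training feature columns."""

    def __init__(self, estimator, columns: Sequence[str]):
        self.estimator = estimator
        self.columns = list(columns)

    def predict_proba(self, table: FeatureTable) -> np.ndarray:
        """Positive-class probability per row; columns must match training."""
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        idx = [table.columns.index(c) for c in self.columns]
        proba = self.estimator.predict_proba(table.values[:, idx])
        positive = list(self.estimator.classes_).index(1)
        return proba[:, positive]


def train_classifier(
    table: FeatureTable,
    labels: Optional[np.ndarray] = None,
    config: ClassifierConfig = ClassifierConfig(),
) -> TrainedModel:
    """Fit the configured classifier on a labeled feature table."""
    y = table.labels if labels is None else np.asarray(labels, dtype=int)
    if y is None:
        raise ValueError("labels are required to train")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples per class to train")
    estimator = config.make()
    estimator.fit(table.values, y)
    return TrainedModel(estimator, table.columns)


def confusion(labels, scores, threshold: float = SCORE_THRESHOLD) -> ConfusionCounts:
    """Tally the confusion matrix; score >= threshold predicts positive."""
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.size != s.size:
        raise ValueError("labels and scores must have the same length")
    pred = s >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is zero; reporting 0", RuntimeWarning)
        return 0.0
    return num / den


def metrics_from_confusion(c: ConfusionCounts) -> MetricSet:
    """SEN, SPE, PRE, F1, ACC, MCC from confusion counts.

    Degenerate denominators yield 0 with a warning.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    sen = _ratio(tp, tp + fn, "SEN")
    spe = _ratio(tn, tn + fp, "SPE")
    pre = _ratio(tp, tp + fp, "PRE")
    f1 = _ratio(2.0 * sen * pre, sen + pre, "F1")
    acc = _ratio(tp + tn, c.total, "ACC")
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(float(tp) * tn - float(fp) * fn, mcc_den, "MCC")
    return MetricSet(sen=sen, spe=spe, pre=pre, f1=f1, acc=acc, mcc=mcc)


def roc_auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) AUC with ties credited 0.5."""
    y = np.asarray(labels, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(s)  # average ranks handle ties as half-wins
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _metrics_with_auc(y: np.ndarray, scores: np.ndarray) -> MetricSet:
    base = metrics_from_confusion(confusion(y, scores))
    return replace(base, auc=roc_auc(y, scores))


def _balance_train(X, y, method: str, seed: int, k_neighbors: int):
    if method == "none":
        return X, y
    rng = np.random.default_rng(seed)
    if method == "smote":
        return smote_augment(X, y, k_neighbors=k_neighbors, rng=rng)
    if method == "random":
        return random_augment(X, y, rng=rng)
    raise ValueError(f"unknown balance method {method!r}")


def cross_validate(
    table: FeatureTable | np.ndarray,
    labels: Optional[np.ndarray] = None,
    folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    balance: str = "smote",
    config: ClassifierConfig = ClassifierConfig(),
    k_neighbors: int = 5,
    balance_before_cv: bool = False,
) -> list[MetricSet]:
    """Repeated stratified k-fold CV with out-of-fold pooled metrics.

    Balancing is applied to the training portion of each fold only
    (leakage-safe) unless ``balance_before_cv`` is set, which reproduces
    the whole-table-first alternative. Repeat r uses derived seed
    ``seed + r``. Returns one MetricSet per repeat.
    """
    if isinstance(table, FeatureTable):
        X = table.values
        y = table.labels if labels is None else np.asarray(labels, dtype=int)
    else:
        X = np.asarray(table, dtype=float)
        y = np.asarray(labels, dtype=int)
    if y is None:
        raise ValueError("labels are required for cross-validation")
    if folds < 2:
        raise ValueError(f"cross_validate: fold count must be >= 2, got {folds}")
    minority = int(np.unique(y, return_counts=True)[1].min())
    if folds > minority:
        raise ValueError(
            f"cross_validate: fold count ({folds}) exceeds minority class size ({minority})"
        )

    if balance_before_cv and balance != "none":
        X, y = _balance_train(X, y, balance, seed, k_neighbors)
        balance = "none"

    results: list[MetricSet] = []
    for r in range(repeats):
        rep_seed = seed + r
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        oof = np.full(y.shape, np.nan)
        for fold_i, (tr, te) in enumerate(skf.split(X, y)):
            X_tr, y_tr = _balance_train(
                X[tr], y[tr], balance, seed=rep_seed * 1000 + fold_i,
                k_neighbors=k_neighbors,
            )
            est = replace(config, seed=rep_seed).make()
            est.fit(X_tr, y_tr)
            positive = list(est.classes_).index(1)
            oof[te] = est.predict_proba(X[te])[:, positive]
        assert not np.any(np.isnan(oof)), "every row must be scored exactly once"
        results.append(_metrics_with_auc(y, oof))
    return results


def mean_metrics(results: Sequence[MetricSet]) -> MetricSet:
    """Component-wise mean over per-repeat metric sets."""
    if not results:
        raise ValueError("no results to average")
    aucs = [m.auc for m in results if m.auc is not None]
    return MetricSet(
        sen=float(np.mean([m.sen for m in results])),
        spe=float(np.mean([m.spe for m in results])),
        pre=float(np.mean([m.pre for m in results])),
        f1=float(np.mean([m.f1 for m in results])),
        acc=float(np.mean([m.acc for m in results])),
        mcc=float(np.mean([m.mcc for m in results])),
        auc=float(np.mean(aucs)) if aucs else None,
    )
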