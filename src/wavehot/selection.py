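"""Two-step feature selection: mutual-information mRMR ranking followed by
sequential forward selection under cross-validated AUC.

The mRMR criterion is the difference (MID) scheme with plug-in mutual
information on a three-bin mean +/- sigma discretization: the first feature
maximizes I(f; y); each subsequent feature maximizes
I(f; y) - (1/|S|) * sum_{s in S} I(f; s) over the selected set S.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .modeling import ClassifierConfig, cross_validate
from .schema import FeatureTable

__all__ = [
    "SelectionResult",
    "discretize_feature",
    "mutual_information",
    "mrmr_rank",
    "sfs_select",
]


@dataclass
class SelectionResult:
    ranked: list[str]
    chosen: list[str]
    cv_scores: list[float]
    best_size: int

    def to_dict(self) -> dict:
        return {
            "ranked": self.ranked,
            "chosen": self.chosen,
            "cv_scores": self.cv_scores,
            "best_size": self.best_size,
        }


def discretize_feature(values) -> np.ndarray:
    """Three-bin discretization at mean +/- population sigma.

    Bin 0 for values at or below mu - sigma, bin 2 for values at or above
    mu + sigma, bin 1 between; constant vectors map to all-1.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 samples to discretize")
    mu = v.mean()
    sigma = v.std(ddof=0)
    if sigma == 0.0:
        return np.ones(v.size, dtype=int)
    cats = np.ones(v.size, dtype=int)
    cats[v <= mu - sigma] = 0
    cats[v >= mu + sigma] = 2
    return cats


def mutual_information(x, y) -> float:
    """Plug-in mutual information (nats) from empirical joint frequencies."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    n = x.size
    mi = 0.0
    xs, x_counts = np.unique(x, return_counts=True)
    ys, y_counts = np.unique(y, return_counts=True)
    px = {v: c / n for v, c in zip(xs, x_counts)}
    py = {v: c / n for v, c in zip(ys, y_counts)}
    for xv in xs:
        mask = x == xv
        for yv in ys:
            pxy = np.sum(mask & (y == yv)) / n
            if pxy > 0:
                mi += pxy * np.log(pxy / (px[xv] * py[yv]))
    return max(float(mi), 0.0)


def mrmr_rank(
    table: FeatureTable,
    labels: Optional[np.ndarray] = None,
    top_k: Optional[int] = None,
) -> list[str]:
    """Greedy MID-scheme mRMR ranking of all (or the top_k) features.

    Deterministic: ties in the greedy criterion break by feature name.
    """
    y = table.labels if labels is None else np.asarray(labels, dtype=int)
    if y is None:
        raise ValueError("labels are required for mRMR ranking")
    if np.unique(y).size < 2:
        raise ValueError("labels are single-class; relevance undefined")
    names = list(table.columns)
    if len(names) < 1:
        raise ValueError("no features to rank")
    k = len(names) if top_k is None else min(top_k, len(names))

    disc = {name: discretize_feature(table.column(name)) for name in names}
    relevance = {name: mutual_information(disc[name], y) for name in names}

    pair_mi: dict[tuple[str, str], float] = {}

    def redundancy(candidate: str, selected: list[str]) -> float:
        total = 0.0
        for s in selected:
            key = (candidate, s) if candidate < s else (s, candidate)
            if key not in pair_mi:
                pair_mi[key] = mutual_information(disc[key[0]], disc[key[1]])
            total += pair_mi[key]
        return total / len(selected)

    ranked: list[str] = []
    remaining = sorted(names)  # name order fixes tie-breaking
    while remaining and len(ranked) < k:
        if not ranked:
            scores = [(-relevance[name], name) for name in remaining]
        else:
            scores = [
                (-(relevance[name] - redundancy(name, ranked)), name)
                for name in remaining
            ]
        # max score, ties -> lexicographically smallest name
        _, best = min(scores)
        ranked.append(best)
        remaining.remove(best)
    return ranked


def sfs_select(
    ranked: Sequence[str],
    table: FeatureTable,
    labels: Optional[np.ndarray] = None,
    cv_folds: int = 10,
    config: ClassifierConfig = ClassifierConfig(),
    seed: int = 0,
    balance: str = "smote",
    k_neighbors: int = 5,
    max_features: Optional[int] = None,
) -> SelectionResult:
    """Sequential forward selection along an mRMR-ranked feature order.

    Each feature is tentatively added and the candidate subset scored by
    mean stratified ``cv_folds``-fold CV AUC (balancing applied inside
    training folds); the feature is kept iff the score strictly improves
    the incumbent best. ``max_features`` caps how far down the ranking the
    walk goes.
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("ranked feature list is empty")
    y = table.labels if labels is None else np.asarray(labels, dtype=int)
    if y is None:
        raise ValueError("labels are required for SFS")
    walk = ranked if max_features is None else ranked[:max_features]

    chosen: list[str] = []
    cv_scores: list[float] = []
    best = -np.inf
    for name in walk:
        candidate = chosen + [name]
        sub = table.select(candidate)
        results = cross_validate(
            sub.values, y, folds=cv_folds, repeats=1, seed=seed,
            balance=balance, config=config, k_neighbors=k_neighbors,
        )
        score = float(results[0].auc)
        cv_scores.append(score)
        if score > best:
            best = score
            chosen.append(name)
    return SelectionResult(
        ranked=ranked,
        chosen=chosen,
        cv_scores=cv_scores,
        best_size=len(chosen),
    )
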