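"""Class balancing: k-NN interpolation oversampling (SMOTE) and the
random-repeat oversampling baseline.

Synthetic minority points are drawn on the segment between a minority
sample X and one of its k nearest minority neighbours X_n:
``X_new = X + u * (X_n - X)`` with ``u ~ Uniform(0, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .schema import FeatureTable

__all__ = [
    "SmoteConfig",
    "smote_augment",
    "random_augment",
    "smote_balance",
    "random_oversample",
]

DEFAULT_SMOTE_SEED = 114


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    seed: int = DEFAULT_SMOTE_SEED

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be positive")


def _class_split(y: np.ndarray) -> tuple[int, int]:
    """Return (minority_label, majority_label); ties treated as balanced."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present to balance")
    if classes.size > 2:
        raise ValueError("only binary labels are supported")
    order = np.argsort(counts)
    return int(classes[order[0]]), int(classes[order[1]])


def smote_augment(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    rng: Optional[np.random.Generator] = None,
    seed: int = DEFAULT_SMOTE_SEED,
    u_override: Optional[Callable[[], float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(X_bal, y_bal)`` with equal class counts.

    Original rows are retained first, synthetic minority rows appended.
    ``u_override`` is a test hook replacing the Uniform(0,1) draw.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y must have the same number of rows")
    rng = np.random.default_rng(seed) if rng is None else rng
    minority, majority = _class_split(y)
    n_min = int(np.sum(y == minority))
    n_needed = int(np.sum(y == majority)) - n_min
    if n_needed == 0:
        return X.copy(), y.copy()
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class size {n_min} must exceed k_neighbors={k_neighbors}; "
            "use a smaller k"
        )
    X_min = X[y == minority]
    # k nearest minority neighbours of each minority point (self excluded)
    dist = cdist(X_min, X_min)
    np.fill_diagonal(dist, np.inf)
    neighbor_idx = np.argsort(dist, axis=1, kind="stable")[:, :k_neighbors]

    synthetic = np.empty((n_needed, X.shape[1]))
    for i in range(n_needed):
        base = int(rng.integers(n_min))
        neighbor = int(neighbor_idx[base, rng.integers(k_neighbors)])
        u = float(u_override()) if u_override is not None else float(rng.random())
        synthetic[i] = X_min[base] + u * (X_min[neighbor] - X_min[base])
    X_bal = np.vstack([X, synthetic])
    y_bal = np.concatenate([y, np.full(n_needed, minority, dtype=int)])
    return X_bal, y_bal


def random_augment(
    X: np.ndarray,
    y: np.ndarray,
    rng: Optional[np.random.Generator] = None,
    seed: int = DEFAULT_SMOTE_SEED,
) -> tuple[np.ndarray, np.ndarray]:
    """Duplicate uniformly sampled minority rows until counts are equal."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed) if rng is None else rng
    minority, majority = _class_split(y)
    n_needed = int(np.sum(y == majority)) - int(np.sum(y == minority))
    if n_needed == 0:
        return X.copy(), y.copy()
    X_min = X[y == minority]
    picks = rng.integers(X_min.shape[0], size=n_needed)
    X_bal = np.vstack([X, X_min[picks]])
    y_bal = np.concatenate([y, np.full(n_needed, minority, dtype=int)])
    return X_bal, y_bal


def _augment_table(table: FeatureTable, X_bal, y_bal) -> FeatureTable:
    return FeatureTable(
        columns=list(table.columns),
        values=X_bal,
        labels=y_bal,
        stage=table.stage,
        meta=None,  # synthetic rows have no residue identity
        provenance=(table.provenance + "|balanced").lstrip("|"),
    )


def smote_balance(
    table: FeatureTable,
    config: SmoteConfig = SmoteConfig(),
    u_override: Optional[Callable[[], float]] = None,
) -> FeatureTable:
    """SMOTE-balance a labeled feature table (any stage)."""
    if table.labels is None:
        raise ValueError("table must carry labels to balance")
    X_bal, y_bal = smote_augment(
        table.values, table.labels,
        k_neighbors=config.k_neighbors, seed=config.seed, u_override=u_override,
    )
    return _augment_table(table, X_bal, y_bal)


def random_oversample(table: FeatureTable, seed: int = DEFAULT_SMOTE_SEED) -> FeatureTable:
    """Random-repeat oversampling baseline on a labeled feature table."""
    if table.labels is None:
        raise ValueError("table must carry labels to balance")
    X_bal, y_bal = random_augment(table.values, table.labels, seed=seed)
    return _augment_table(table, X_bal, y_bal)
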