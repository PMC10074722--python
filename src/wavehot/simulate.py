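"""Synthetic labeled residue tables and short test signals.

The generative model is deliberately simple: every feature column is
Gaussian noise, informative columns get a class-conditional mean shift, the
hydrogen-bond column is rounded to a non-negative integer, and ddg is drawn
so the hot-spot labeling rule reproduces the latent class exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import (
    DDG_COLUMN,
    TRADITIONAL_COLUMNS,
    FeatureTable,
    label_from_ddg,
)

__all__ = ["SimulationConfig", "simulate_table", "simulate_signal"]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# default informative block: the monomer-state solvent-accessibility group
DEFAULT_INFORMATIVE: tuple[str, ...] = TRADITIONAL_COLUMNS[0:8]


@dataclass(frozen=True)
class SimulationConfig:
    n_pos: int = 101
    n_neg: int = 170
    informative_columns: tuple[str, ...] = DEFAULT_INFORMATIVE
    effect_size: float = 2.0
    noise_sigma: float = 1.0
    ddg_pos_range: tuple[float, float] = (1.0, 5.0)
    ddg_neg_range: tuple[float, float] = (-2.0, 0.99)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be >= 1")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        unknown = [c for c in self.informative_columns if c not in TRADITIONAL_COLUMNS]
        if unknown:
            raise ValueError(f"unknown informative columns: {unknown}")
        if not (label_from_ddg(self.ddg_pos_range[0]) == 1
                and label_from_ddg(self.ddg_neg_range[1]) == 0):
            raise ValueError("ddg ranges must straddle the 1.0 kcal/mol threshold")


def simulate_table(config: SimulationConfig = SimulationConfig()) -> FeatureTable:
    """Generate a traditional-stage table with ddg metadata and labels."""
    rng = np.random.default_rng(config.seed)
    n = config.n_pos + config.n_neg
    labels = np.concatenate([
        np.ones(config.n_pos, dtype=int),
        np.zeros(config.n_neg, dtype=int),
    ])

    sigma = config.noise_sigma
    values = rng.normal(0.0, sigma, size=(n, len(TRADITIONAL_COLUMNS)))
    col_index = {c: j for j, c in enumerate(TRADITIONAL_COLUMNS)}
    for col in config.informative_columns:
        values[labels == 1, col_index[col]] += config.effect_size * sigma

    # hydrogen-bond counts are small non-negative integers
    hb = col_index["hbond_count"]
    values[:, hb] = np.clip(np.round(values[:, hb] + 3.0 * sigma), 0, None)

    ddg = np.where(
        labels == 1,
        rng.uniform(*config.ddg_pos_range, size=n),
        rng.uniform(*config.ddg_neg_range, size=n),
    )
    assert all(label_from_ddg(d) == l for d, l in zip(ddg, labels))

    meta = pd.DataFrame({
        "pdb_id": [f"S{i:03d}" for i in range(n)],
        "chain": ["A"] * n,
        "position": np.arange(1, n + 1),
        "wt_residue": [_AMINO_ACIDS[int(k)] for k in rng.integers(20, size=n)],
        DDG_COLUMN: ddg,
    })
    return FeatureTable(
        columns=list(TRADITIONAL_COLUMNS),
        values=values,
        labels=labels,
        stage="traditional",
        meta=meta,
        provenance=f"simulated:seed={config.seed}",
    )


def simulate_signal(length: int, kind: str = "random", seed: int = 0,
                    value: float = 1.0) -> np.ndarray:
    """Fixture vectors for wavelet unit tests (lengths 6 and 8 only)."""
    if length not in (6, 8):
        raise ValueError(f"length must be 6 or 8, got {length}")
    if kind == "constant":
        return np.full(length, float(value))
    if kind == "alternating":
        return np.array([value if i % 2 == 0 else -value for i in range(length)])
    if kind == "random":
        return np.random.default_rng(seed).normal(size=length)
    raise ValueError(f"unknown signal kind {kind!r}")
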