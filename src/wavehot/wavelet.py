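"""Multilevel Haar DWT, level-3 wavelet packet transform, and the
energy/entropy summaries computed from their coefficients.

All transforms use the orthonormal Haar (db1) analysis pair
``g = (1/sqrt2, 1/sqrt2)``, ``h = (1/sqrt2, -1/sqrt2)`` with a periodized
boundary rule: odd-length inputs are extended by repeating the last sample
before convolution-decimation. For power-of-two lengths both transforms
conserve energy exactly (Parseval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HAAR_LOWPASS",
    "HAAR_HIGHPASS",
    "WaveletDecomposition",
    "WPTerminalNodes",
    "DwtEnergySummary",
    "EntropyVector",
    "haar_analysis_step",
    "dwt_multilevel",
    "wpt_level3",
    "dwt_energy_summary",
    "wpt_energy_summary",
    "shannon_entropy",
    "log_energy_entropy",
    "threshold_sure_norm_entropies",
    "entropy_vector",
    "dwt_coefficient_vector",
    "wpt_coefficient_vector",
]

_SQRT2 = math.sqrt(2.0)

HAAR_LOWPASS = (1.0 / _SQRT2, 1.0 / _SQRT2)
HAAR_HIGHPASS = (1.0 / _SQRT2, -1.0 / _SQRT2)

# fixed defaults of the entropy family
THRESHOLD_ENTROPY_CUTOFF = 0.2
SURE_ENTROPY_CUTOFF = 3.0
NORM_ENTROPY_POWER = 1.3


def _as_signal(signal, minimum: int = 1) -> np.ndarray:
    s = np.asarray(signal, dtype=float).ravel()
    if s.size < minimum:
        raise ValueError(f"signal must have at least {minimum} sample(s), got {s.size}")
    if not np.all(np.isfinite(s)):
        raise ValueError("signal contains non-finite values")
    return s


def haar_analysis_step(signal) -> tuple[np.ndarray, np.ndarray]:
    """One Haar filter-bank analysis step (convolution + dyadic decimation).

    Returns ``(approx, detail)`` of length ``ceil(len(signal) / 2)``. An
    odd-length input is first extended by repeating its last sample.
    """
    s = _as_signal(signal, minimum=1)
    if s.size % 2 == 1:
        s = np.append(s, s[-1])
    even, odd = s[0::2], s[1::2]
    approx = (even + odd) / _SQRT2
    detail = (even - odd) / _SQRT2
    return approx, detail


@dataclass(frozen=True)
class WaveletDecomposition:
    """Per-level approximation/detail coefficients of a multilevel Haar DWT.

    ``approx[j-1]`` and ``detail[j-1]`` hold the level-j coefficient vectors.
    """

    levels: int
    approx: tuple[np.ndarray, ...]
    detail: tuple[np.ndarray, ...]
    input_length: int


@dataclass(frozen=True)
class WPTerminalNodes:
    """The 8 terminal subband coefficient vectors of a level-3 wavelet
    packet split, in natural (filter-order) indexing n = 0..7."""

    nodes: tuple[np.ndarray, ...]
    input_length: int

    def __post_init__(self) -> None:
        if len(self.nodes) != 8:
            raise ValueError(f"expected 8 terminal nodes, got {len(self.nodes)}")


@dataclass(frozen=True)
class DwtEnergySummary:
    """Approximation energy percentages per level plus summary stats."""

    ea: tuple[float, float, float]
    ea_mean: float
    ea_std: float
    ed: float


@dataclass(frozen=True)
class EntropyVector:
    shannon: float
    log_energy: float
    threshold: float
    sure: float
    norm: float

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.shannon, self.log_energy, self.threshold, self.sure, self.norm)


def dwt_multilevel(signal, levels: int = 3) -> WaveletDecomposition:
    """Recursive Haar analysis of the approximation branch.

    Always performs the requested number of levels; length-1 approximations
    are extended by the boundary rule so deeper levels stay defined.
    """
    if levels < 1:
        raise ValueError(f"levels must be >= 1, got {levels}")
    s = _as_signal(signal, minimum=2)
    approx_levels: list[np.ndarray] = []
    detail_levels: list[np.ndarray] = []
    current = s
    for _ in range(levels):
        a, d = haar_analysis_step(current)
        approx_levels.append(a)
        detail_levels.append(d)
        current = a
    return WaveletDecomposition(
        levels=levels,
        approx=tuple(approx_levels),
        detail=tuple(detail_levels),
        input_length=s.size,
    )


def wpt_level3(signal) -> WPTerminalNodes:
    """Level-3 wavelet packet split: both branches split at every level,
    yielding 8 terminal subbands in natural order."""
    s = _as_signal(signal, minimum=2)
    nodes: list[np.ndarray] = [s]
    for _ in range(3):
        next_nodes: list[np.ndarray] = []
        for node in nodes:
            a, d = haar_analysis_step(node)
            next_nodes.append(a)
            next_nodes.append(d)
        nodes = next_nodes
    return WPTerminalNodes(nodes=tuple(nodes), input_length=s.size)


def _energy(v: np.ndarray) -> float:
    return float(np.sum(np.square(v)))


def dwt_energy_summary(decomp: WaveletDecomposition) -> DwtEnergySummary:
    """Per-level approximation energy percentage, its mean/std, and the
    complementary detail percentage.

    ``ea[j]`` is the approximation's share (in percent) of the total
    level-j decomposition energy (approximation at level j plus all detail
    energies down to level j); ``ed = 100 - ea[levels]``. ``ea_std`` is the
    population standard deviation over the per-level values.
    """
    if decomp.levels != 3:
        raise ValueError("energy summary is defined for 3-level decompositions")
    detail_energies = [_energy(d) for d in decomp.detail]
    ea = []
    for j in range(decomp.levels):
        approx_e = _energy(decomp.approx[j])
        total = approx_e + sum(detail_energies[: j + 1])
        if total == 0.0:
            raise ValueError("all-zero decomposition: energy percentages undefined")
        ea.append(100.0 * approx_e / total)
    ea_arr = np.asarray(ea)
    return DwtEnergySummary(
        ea=tuple(ea),
        ea_mean=float(ea_arr.mean()),
        ea_std=float(ea_arr.std(ddof=0)),
        ed=100.0 - ea[-1],
    )


def wpt_energy_summary(
    nodes: WPTerminalNodes,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Absolute node energies, relative percentages, and their sum."""
    absolute = np.array([_energy(n) for n in nodes.nodes])
    total = float(absolute.sum())
    if total == 0.0:
        raise ValueError("all-zero nodes: relative energies undefined")
    relative = 100.0 * absolute / total
    return absolute, relative, total


def shannon_entropy(coeffs) -> float:
    """-sum(s_i^2 * ln(s_i^2)) with zero terms contributing 0."""
    s = np.asarray(coeffs, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("coefficients contain non-finite values")
    sq = np.square(s)
    sq = sq[sq > 0.0]  # zero terms (incl. squared underflow) contribute 0
    if sq.size == 0:
        return 0.0
    return float(-np.sum(sq * np.log(sq)))


def log_energy_entropy(coeffs) -> float:
    """sum(ln(s_i^2)) with zero terms contributing 0 (so E[0] = 0)."""
    s = np.asarray(coeffs, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("coefficients contain non-finite values")
    sq = np.square(s)
    sq = sq[sq > 0.0]  # zero terms (incl. squared underflow) contribute 0
    if sq.size == 0:
        return 0.0
    return float(np.sum(np.log(sq)))


def threshold_sure_norm_entropies(coeffs) -> tuple[float, float, float]:
    """Threshold (cutoff 0.2), SURE (cutoff 3), and norm (power 1.3)
    entropies.

    * threshold: count of coefficients with |s_i| > 0.2;
    * SURE: ``n - #{|s_i| <= 3} + sum(min(s_i^2, 9))``;
    * norm: ``sum(|s_i| ** 1.3)``.
    """
    s = np.asarray(coeffs, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("coefficients contain non-finite values")
    absolute = np.abs(s)
    threshold = float(np.sum(absolute > THRESHOLD_ENTROPY_CUTOFF))
    eps = SURE_ENTROPY_CUTOFF
    sure = float(s.size - np.sum(absolute <= eps) + np.sum(np.minimum(s**2, eps**2)))
    norm = float(np.sum(absolute**NORM_ENTROPY_POWER))
    return threshold, sure, norm


def entropy_vector(coeffs) -> EntropyVector:
    """The five wavelet entropies in fixed order
    (shannon, log_energy, threshold, sure, norm)."""
    threshold, sure, norm = threshold_sure_norm_entropies(coeffs)
    return EntropyVector(
        shannon=shannon_entropy(coeffs),
        log_energy=log_energy_entropy(coeffs),
        threshold=threshold,
        sure=sure,
        norm=norm,
    )


def dwt_coefficient_vector(decomp: WaveletDecomposition) -> np.ndarray:
    """Concatenated DWT coefficients: deepest approximation, then details
    from deepest to shallowest."""
    parts = [decomp.approx[-1]] + [decomp.detail[j] for j in range(decomp.levels - 1, -1, -1)]
    return np.concatenate(parts)


def wpt_coefficient_vector(nodes: WPTerminalNodes) -> np.ndarray:
    """Concatenated terminal-node coefficients in natural node order."""
    return np.concatenate(nodes.nodes)
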