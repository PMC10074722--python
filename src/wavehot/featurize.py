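"""Signal-group construction and wavelet featurization.

Four per-residue descriptor groups are treated as short digital signals:
three length-8 solvent-accessibility groups (monomer state ``ASA``, complex
state ``uASA``, relative change ``dASA``) and the length-6 secondary
structure group ``DSSP``. Each group contributes 11 DWT descriptors and 22
WPT descriptors, so a 43-column traditional table grows by 4*11 + 4*22 = 132
wavelet columns to 175 feature columns in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import wavelet
from .schema import (
    ASA_COLUMNS,
    SS_COLUMNS,
    TRADITIONAL_COLUMNS,
    FeatureTable,
    ResidueRecord,
    SchemaError,
)

__all__ = [
    "GROUP_ORDER",
    "GROUP_COLUMNS",
    "DWT_DESCRIPTORS",
    "WPT_DESCRIPTORS",
    "DWT_FEATURE_COLUMNS",
    "WPT_FEATURE_COLUMNS",
    "WAVELET_FEATURE_COLUMNS",
    "FULL175_COLUMNS",
    "SignalGroup",
    "build_signal_groups",
    "dwt_features",
    "wpt_features",
    "featurize_record",
    "featurize_table",
]

GROUP_ORDER: tuple[str, ...] = ("ASA", "uASA", "dASA", "DSSP")

GROUP_COLUMNS: dict[str, tuple[str, ...]] = {
    "ASA": ASA_COLUMNS[0:8],    # monomer state
    "uASA": ASA_COLUMNS[8:16],  # complex state
    "dASA": ASA_COLUMNS[16:24], # relative change
    "DSSP": SS_COLUMNS,
}

ENTROPY_DESCRIPTORS = ("shannon", "log_energy", "threshold", "sure", "norm")

DWT_DESCRIPTORS: tuple[str, ...] = (
    "ea1", "ea2", "ea3", "ea_std", "ea_mean", "ed", *ENTROPY_DESCRIPTORS,
)
WPT_DESCRIPTORS: tuple[str, ...] = (
    *(f"rel{n}" for n in range(8)),
    *(f"abs{n}" for n in range(8)),
    "abs_sum",
    *ENTROPY_DESCRIPTORS,
)

DWT_FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{group}_dwt_{desc}" for group in GROUP_ORDER for desc in DWT_DESCRIPTORS
)
WPT_FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{group}_wpt_{desc}" for group in GROUP_ORDER for desc in WPT_DESCRIPTORS
)
WAVELET_FEATURE_COLUMNS: tuple[str, ...] = DWT_FEATURE_COLUMNS + WPT_FEATURE_COLUMNS
FULL175_COLUMNS: tuple[str, ...] = TRADITIONAL_COLUMNS + WAVELET_FEATURE_COLUMNS

assert len(DWT_FEATURE_COLUMNS) == 44
assert len(WPT_FEATURE_COLUMNS) == 88
assert len(WAVELET_FEATURE_COLUMNS) == 132
assert len(FULL175_COLUMNS) == 175


@dataclass(frozen=True)
class SignalGroup:
    """An ordered short feature vector treated as a digital signal."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.name not in GROUP_ORDER:
            raise ValueError(f"unknown group {self.name!r}; expected one of {GROUP_ORDER}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        expected = len(GROUP_COLUMNS[self.name])
        if self.values.shape != (expected,):
            raise ValueError(
                f"group {self.name!r} must have length {expected}, got {self.values.shape}"
            )


def _group_values(traditional: Mapping[str, float]) -> list[SignalGroup]:
    return [
        SignalGroup(name, np.array([float(traditional[c]) for c in GROUP_COLUMNS[name]]))
        for name in GROUP_ORDER
    ]


def build_signal_groups(record: ResidueRecord) -> list[SignalGroup]:
    """Extract the four signal groups from a validated residue record,
    in fixed order (ASA, uASA, dASA, DSSP)."""
    record.validate()
    return _group_values(record.traditional)


def _check_groups(groups: Sequence[SignalGroup]) -> None:
    names = tuple(g.name for g in groups)
    if names != GROUP_ORDER:
        raise ValueError(
            f"groups must be supplied in canonical order {GROUP_ORDER}, got {names}"
        )


def dwt_features(groups: Sequence[SignalGroup]) -> dict[str, float]:
    """11 DWT descriptors per group: per-level approximation energy
    percentages, their std and mean, the detail percentage, and the five
    entropies of the concatenated coefficient vector."""
    _check_groups(groups)
    out: dict[str, float] = {}
    for group in groups:
        try:
            decomp = wavelet.dwt_multilevel(group.values, levels=3)
            summary = wavelet.dwt_energy_summary(decomp)
        except ValueError as exc:
            raise ValueError(f"group {group.name!r}: {exc}") from exc
        entropies = wavelet.entropy_vector(wavelet.dwt_coefficient_vector(decomp))
        values = (
            summary.ea[0], summary.ea[1], summary.ea[2],
            summary.ea_std, summary.ea_mean, summary.ed,
            *entropies.as_tuple(),
        )
        for desc, value in zip(DWT_DESCRIPTORS, values):
            out[f"{group.name}_dwt_{desc}"] = float(value)
    return out


def wpt_features(groups: Sequence[SignalGroup]) -> dict[str, float]:
    """22 WPT descriptors per group: terminal-node relative energies,
    absolute energies, their sum, and the five entropies of the
    concatenated terminal coefficients."""
    _check_groups(groups)
    out: dict[str, float] = {}
    for group in groups:
        try:
            nodes = wavelet.wpt_level3(group.values)
            absolute, relative, total = wavelet.wpt_energy_summary(nodes)
        except ValueError as exc:
            raise ValueError(f"group {group.name!r}: {exc}") from exc
        entropies = wavelet.entropy_vector(wavelet.wpt_coefficient_vector(nodes))
        values = (*relative, *absolute, total, *entropies.as_tuple())
        for desc, value in zip(WPT_DESCRIPTORS, values):
            out[f"{group.name}_wpt_{desc}"] = float(value)
    return out


def featurize_record(traditional: Mapping[str, float]) -> dict[str, float]:
    """All 132 wavelet descriptors for one residue's traditional features."""
    groups = _group_values(traditional)
    out = dwt_features(groups)
    out.update(wpt_features(groups))
    return out


def featurize_table(table: FeatureTable) -> FeatureTable:
    """Append the 132 wavelet columns to a traditional-stage table.

    Row order, labels, and metadata are preserved; output has exactly 175
    feature columns.
    """
    if table.stage != "traditional":
        raise SchemaError(f"featurize_table expects a traditional-stage table, got {table.stage!r}")
    table.validate()
    wavelet_values = np.empty((table.n_rows, len(WAVELET_FEATURE_COLUMNS)))
    for i in range(table.n_rows):
        traditional = dict(zip(table.columns, table.values[i]))
        try:
            feats = featurize_record(traditional)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        wavelet_values[i] = [feats[c] for c in WAVELET_FEATURE_COLUMNS]
    return FeatureTable(
        columns=list(FULL175_COLUMNS),
        values=np.hstack([table.values, wavelet_values]) if table.n_rows else np.empty((0, 175)),
        labels=None if table.labels is None else table.labels.copy(),
        stage="full175",
        meta=None if table.meta is None else table.meta.copy(),
        provenance=(table.provenance + "|featurized").lstrip("|"),
    )
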