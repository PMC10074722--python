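"""Residue feature data model, canonical column schema, and tabular I/O.

The traditional per-residue descriptor table has exactly 43 feature columns
partitioned into four blocks:

* 24 solvent-accessibility columns: absolute (``asa``) and relative (``rsa``)
  accessibility for four atomic classes (all atoms, nonpolar side chain,
  polar side chain, all side chains), each in the monomer state, the complex
  state, and as the relative change between states;
* 6 secondary-structure columns (carbonyl angle, bond angle, three torsion
  angles, water-molecule count);
* 12 depth/protrusion columns: mean-over-all-atoms and side-chain standard
  deviation of the depth index (``dpx``) and protrusion index (``cx``) in
  bound and unbound states plus the four relative changes;
* 1 hydrogen-bond count.

Column identities and order are fixed here so that downstream signal-group
construction is deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ASA_COLUMNS",
    "SS_COLUMNS",
    "DPXCX_COLUMNS",
    "HBOND_COLUMNS",
    "TRADITIONAL_COLUMNS",
    "META_COLUMNS",
    "DDG_COLUMN",
    "LABEL_COLUMN",
    "HOTSPOT_DDG_THRESHOLD",
    "SchemaError",
    "ParseError",
    "ResidueRecord",
    "FeatureTable",
    "DatasetSplit",
    "label_from_ddg",
    "read_feature_table",
    "write_feature_table",
    "split_summary",
    "write_schema_json",
]

# hot-spot labeling threshold on the binding free-energy change, kcal/mol
HOTSPOT_DDG_THRESHOLD = 1.0

_ATOM_CLASSES = ("all", "nonpolar", "polar", "side")
_ASA_STATES = ("mono", "comp", "delta")

ASA_COLUMNS: tuple[str, ...] = tuple(
    f"{measure}_{state}_{cls}"
    for state in _ASA_STATES
    for measure in ("asa", "rsa")
    for cls in _ATOM_CLASSES
)

SS_COLUMNS: tuple[str, ...] = (
    "ss_tco",
    "ss_kappa",
    "ss_alpha",
    "ss_phi",
    "ss_psi",
    "ss_nwater",
)

DPXCX_COLUMNS: tuple[str, ...] = tuple(
    f"{index}_{summary}_{state}"
    for index in ("dpx", "cx")
    for summary in ("mean", "std")
    for state in ("bound", "unbound")
) + tuple(
    f"{index}_{summary}_delta"
    for index in ("dpx", "cx")
    for summary in ("mean", "std")
)

HBOND_COLUMNS: tuple[str, ...] = ("hbond_count",)

TRADITIONAL_COLUMNS: tuple[str, ...] = (
    ASA_COLUMNS + SS_COLUMNS + DPXCX_COLUMNS + HBOND_COLUMNS
)

assert len(ASA_COLUMNS) == 24
assert len(DPXCX_COLUMNS) == 12
assert len(TRADITIONAL_COLUMNS) == 43

META_COLUMNS: tuple[str, ...] = ("pdb_id", "chain", "position", "wt_residue")
DDG_COLUMN = "ddg"
LABEL_COLUMN = "label"

STAGES = ("traditional", "full175", "selected")


class SchemaError(ValueError):
    """A table does not match the declared column schema."""


class ParseError(ValueError):
    """A feature cell could not be parsed as a finite number."""


def label_from_ddg(ddg: float) -> int:
    """Binary hot-spot label: 1 iff ``ddg`` >= 1.0 kcal/mol."""
    ddg = float(ddg)
    if not math.isfinite(ddg):
        raise ValueError(f"ddg must be finite, got {ddg!r}")
    return 1 if ddg >= HOTSPOT_DDG_THRESHOLD else 0


@dataclass
class ResidueRecord:
    """One mutated interface residue with its 43 traditional descriptors."""

    pdb_id: str
    chain: str
    position: int
    wt_residue: str
    ddg: float
    traditional: dict[str, float]
    label: Optional[int] = None

    def validate(self) -> None:
        if len(self.pdb_id) != 4:
            raise SchemaError(f"pdb_id must be 4 characters, got {self.pdb_id!r}")
        if tuple(self.traditional.keys()) != TRADITIONAL_COLUMNS:
            missing = [c for c in TRADITIONAL_COLUMNS if c not in self.traditional]
            if missing:
                raise SchemaError(f"missing traditional columns: {missing}")
            raise SchemaError("traditional columns out of canonical order")
        for name, value in self.traditional.items():
            if not math.isfinite(float(value)):
                raise ParseError(f"non-finite value in column {name!r}: {value!r}")
        hb = float(self.traditional["hbond_count"])
        if hb < 0 or hb != round(hb):
            raise SchemaError(f"hbond_count must be a non-negative integer, got {hb}")

    def assign_label(self) -> "ResidueRecord":
        self.label = label_from_ddg(self.ddg)
        return self


@dataclass
class FeatureTable:
    """Rows of named numeric feature columns plus optional labels/metadata.

    ``values`` is an (n_rows, n_features) float array aligned to ``columns``.
    ``meta`` optionally carries residue identity and ddg columns; it is
    written back to CSV alongside the features.
    """

    columns: list[str]
    values: np.ndarray
    labels: Optional[np.ndarray] = None
    stage: str = "selected"
    meta: Optional[pd.DataFrame] = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values.reshape(0, len(self.columns)) if self.values.size == 0 else self.values.reshape(1, -1)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            dupes = sorted({c for c in self.columns if self.columns.count(c) > 1})
            raise SchemaError(f"duplicate column names: {dupes}")
        if self.values.shape[1] != len(self.columns):
            raise SchemaError(
                f"row width {self.values.shape[1]} != {len(self.columns)} columns"
            )
        if self.labels is not None and len(self.labels) != self.n_rows:
            raise SchemaError("labels length does not match row count")
        if self.meta is not None and len(self.meta) != self.n_rows:
            raise SchemaError("meta length does not match row count")
        if self.stage not in STAGES:
            raise SchemaError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.stage == "traditional" and list(self.columns) != list(TRADITIONAL_COLUMNS):
            missing = [c for c in TRADITIONAL_COLUMNS if c not in self.columns]
            if missing:
                raise SchemaError(f"missing required column(s): {missing}")
            raise SchemaError("traditional columns present but out of canonical order")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"non-finite value at row {int(r)}, column {self.columns[int(c)]!r}"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            columns=list(self.columns),
            values=self.values.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            stage=self.stage,
            meta=None if self.meta is None else self.meta.copy(),
            provenance=self.provenance,
        )

    def column(self, name: str) -> np.ndarray:
        try:
            idx = self.columns.index(name)
        except ValueError:
            raise SchemaError(f"missing required column(s): [{name!r}]") from None
        return self.values[:, idx]

    def select(self, names: Sequence[str]) -> "FeatureTable":
        """Project onto a feature subset (stage becomes 'selected')."""
        idx = []
        for name in names:
            if name not in self.columns:
                raise SchemaError(f"missing required column(s): [{name!r}]")
            idx.append(self.columns.index(name))
        return FeatureTable(
            columns=list(names),
            values=self.values[:, idx],
            labels=None if self.labels is None else self.labels.copy(),
            stage="selected",
            meta=None if self.meta is None else self.meta.copy(),
            provenance=self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        parts = []
        if self.meta is not None:
            parts.append(self.meta.reset_index(drop=True))
        parts.append(pd.DataFrame(self.values, columns=self.columns))
        frame = pd.concat(parts, axis=1)
        if self.labels is not None:
            frame[LABEL_COLUMN] = self.labels
        return frame


def _stage_columns(stage: str) -> Optional[list[str]]:
    if stage == "traditional":
        return list(TRADITIONAL_COLUMNS)
    if stage == "full175":
        # deferred import: featurize defines the 175-column order
        from .featurize import FULL175_COLUMNS

        return list(FULL175_COLUMNS)
    return None


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_feature_table(path: str | Path, stage: str = "selected") -> FeatureTable:
    """Read a CSV/TSV feature table, validating the stage schema.

    The delimiter is auto-detected from the header line. Feature columns are
    the stage's canonical columns when the stage fixes a schema, otherwise
    every column that is not a metadata/ddg/label column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = _stage_columns(stage)
    if required is not None:
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        feature_cols = required
    else:
        reserved = set(META_COLUMNS) | {DDG_COLUMN, LABEL_COLUMN}
        feature_cols = [c for c in frame.columns if c not in reserved]

    values = np.empty((len(frame), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        raw = frame[col].to_numpy()
        try:
            values[:, j] = raw.astype(float)
        except ValueError:
            for i, cell in enumerate(raw):
                try:
                    float(cell)
                except ValueError:
                    raise ParseError(
                        f"non-numeric value {cell!r} at row {i}, column {col!r}"
                    ) from None
            raise  # pragma: no cover - unreachable

    labels = None
    if LABEL_COLUMN in frame.columns:
        labels = frame[LABEL_COLUMN].astype(float).astype(int).to_numpy()

    meta_cols = [c for c in (*META_COLUMNS, DDG_COLUMN) if c in frame.columns]
    meta = None
    if meta_cols:
        meta = frame[meta_cols].copy()
        if "position" in meta.columns:
            meta["position"] = meta["position"].astype(float).astype(int)
        if DDG_COLUMN in meta.columns:
            meta[DDG_COLUMN] = meta[DDG_COLUMN].astype(float)

    return FeatureTable(
        columns=list(feature_cols),
        values=values,
        labels=labels,
        stage=stage,
        meta=meta,
        provenance=f"read:{path.name}",
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a table as CSV; :func:`read_feature_table` inverts it."""
    table.validate()
    path = Path(path)
    frame = table.to_frame()
    # repr round-trips float64 exactly
    frame.to_csv(path, index=False, float_format=None)


@dataclass
class DatasetSplit:
    """Train/test partition with class-count bookkeeping."""

    train: FeatureTable
    test: FeatureTable

    counts: dict = field(init=False, default_factory=dict)
    ratio: dict = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        summary = split_summary(self)
        self.counts = {
            part: (summary[part]["n_pos"], summary[part]["n_neg"])
            for part in ("train", "test")
        }
        self.ratio = {part: summary[part]["ratio"] for part in ("train", "test")}


def split_summary(split: "DatasetSplit") -> dict:
    """Per-split positive/negative counts and pos/neg ratio.

    ``ratio_str`` formats the ratio to three decimals.
    """
    out = {}
    for part in ("train", "test"):
        table: FeatureTable = getattr(split, part)
        if table.labels is None:
            raise ValueError(f"{part} split has no labels")
        n_pos = int(np.sum(table.labels == 1))
        n_neg = int(np.sum(table.labels == 0))
        if n_neg == 0:
            raise ValueError(f"{part} split has no negatives; ratio undefined")
        ratio = n_pos / n_neg
        out[part] = {
            "n_pos": n_pos,
            "n_neg": n_neg,
            "ratio": ratio,
            "ratio_str": f"{ratio:.3f}",
        }
    return out


def write_schema_json(path: str | Path) -> None:
    """Write the canonical 43-column schema as a JSON sidecar."""
    payload = {
        "feature_columns": list(TRADITIONAL_COLUMNS),
        "blocks": {
            "solvent_accessibility": list(ASA_COLUMNS),
            "secondary_structure": list(SS_COLUMNS),
            "depth_protrusion": list(DPXCX_COLUMNS),
            "hydrogen_bond": list(HBOND_COLUMNS),
        },
        "meta_columns": list(META_COLUMNS),
        "ddg_column": DDG_COLUMN,
        "label_column": LABEL_COLUMN,
        "hotspot_ddg_threshold_kcal_per_mol": HOTSPOT_DDG_THRESHOLD,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
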