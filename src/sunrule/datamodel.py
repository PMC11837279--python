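"""Labelled numeric feature tables, CSV I/O and min-max normalization.

A :class:`FeatureTable` is an ``n x d`` matrix of raw sensor readings
(heterogeneous scales), one class label per row, and unique channel names
per column.  Rules are expressed in raw units, while the optimisation
search runs in a normalized box, so :class:`NormalizationSpec` provides an
exact, invertible per-channel min-max map.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "NormalizationSpec",
    "FormatError",
    "LabelError",
    "RowParseError",
    "read_table",
    "write_table",
    "fit_normalization",
    "apply_normalization",
    "invert_normalization",
    "normalize_table",
    "load_fixture_table",
    "load_fixture_rules",
    "FIXTURE_LABEL_MAPS",
]

#: Default canonicalization of printed fixture labels to rule-consequent
#: classes.  The follicle-table glyphs are mapped A->L, U->O; the CL-table
#: glyphs V->P, Y->A.  The follicle mapping is a best guess and is logged.
FIXTURE_LABEL_MAPS = {
    "cl": {"V": "P", "Y": "A"},
    "follicle": {"A": "L", "U": "O"},
}


class FormatError(ValueError):
    """Structural problem in an input file (missing column, bad header...)."""


class LabelError(ValueError):
    """A row carries a label outside the declared label set."""


class RowParseError(ValueError):
    """A feature cell failed to parse as a real number.

    Attributes
    ----------
    rows : list[int]
        Zero-based indices of the offending data rows.
    """

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(message)
        self.rows = list(rows)


@dataclass
class FeatureTable:
    """Numeric feature matrix with per-row labels and per-column names."""

    values: np.ndarray
    channels: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise FormatError("table must have at least one row and one column")
        if len(self.channels) != d:
            raise FormatError(
                f"{len(self.channels)} channel names for {d} columns"
            )
        if len(set(self.channels)) != d:
            raise FormatError("channel names must be unique")
        if self.labels.shape != (n,):
            raise FormatError("one label required per row")
        if not np.all(np.isfinite(self.values)):
            bad = sorted(set(np.argwhere(~np.isfinite(self.values))[:, 0]))
            raise RowParseError(f"non-finite values in rows {bad}", bad)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def label_set(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def class_counts(self) -> dict[str, int]:
        return dict(Counter(self.labels))

    def column(self, channel: str) -> np.ndarray:
        try:
            j = self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}") from None
        return self.values[:, j]

    def row_mapping(self, i: int) -> dict[str, float]:
        """Row ``i`` as a channel -> value mapping."""
        return dict(zip(self.channels, self.values[i]))

    def subset(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        return FeatureTable(self.values[mask], list(self.channels), self.labels[mask])

    def class_rows(self, label: str) -> "FeatureTable":
        if label not in self.labels:
            raise KeyError(f"class {label!r} absent from table")
        return self.subset(self.labels == label)


def read_table(
    path: str | Path,
    class_column: str = "Class",
    label_map: Mapping[str, str] | None = None,
    label_set: Sequence[str] | None = None,
) -> FeatureTable:
    """Load a labelled CSV feature table.

    Comma-separated, dot-decimal, one header row.  Rows with missing cells
    are rejected (a warning reports the count); non-numeric feature cells
    raise :class:`RowParseError` listing the offending rows.  Labels are
    passed through ``label_map`` (identity for unmapped labels) and, when
    ``label_set`` is given, validated against it after mapping.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if class_column not in df.columns:
        raise FormatError(
            f"class column {class_column!r} missing from {path.name}; "
            f"found columns {list(df.columns)}"
        )
    missing = df.isna().any(axis=1)
    if missing.any():
        logger.warning(
            "%s: rejected %d row(s) with missing cells", path.name, int(missing.sum())
        )
        df = df[~missing]
    if df.empty:
        raise FormatError(f"{path.name}: no complete rows")

    feature_cols = [c for c in df.columns if c != class_column]
    if not feature_cols:
        raise FormatError(f"{path.name}: no feature columns")
    def _parse_cell(s: str) -> float:
        # python's strtod is correctly rounded; pandas' fast path is not
        try:
            return float(s)
        except ValueError:
            return float("nan")

    numeric = df[feature_cols].map(_parse_cell)
    bad_rows = sorted(np.nonzero(numeric.isna().any(axis=1).to_numpy())[0])
    if bad_rows:
        raise RowParseError(
            f"{path.name}: unparseable feature cell(s) in data row(s) {bad_rows}",
            bad_rows,
        )

    raw_labels = df[class_column].astype(str).tolist()
    if label_map:
        labels = [label_map.get(lab, lab) for lab in raw_labels]
        if labels != raw_labels:
            logger.info("applied label map %s", dict(label_map))
    else:
        labels = raw_labels
    if label_set is not None:
        unknown = sorted(set(labels) - set(label_set))
        if unknown:
            raise LabelError(f"labels {unknown} outside declared set {list(label_set)}")
    return FeatureTable(numeric.to_numpy(dtype=float), feature_cols, np.array(labels, dtype=object))


def write_table(table: FeatureTable, path: str | Path, class_column: str = "Class") -> None:
    """Write a table as CSV at full float precision (`repr` round-trip)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join([*table.channels, class_column]) + "\n")
        for row, lab in zip(table.values, table.labels):
            cells = [repr(float(v)) for v in row]
            fh.write(",".join([*cells, str(lab)]) + "\n")


@dataclass
class NormalizationSpec:
    """Per-channel min-max map onto a target interval (default ``[0, 1]``).

    Constant channels (``max == min``) map every value to the target lower
    bound and are flagged so downstream search can skip them.
    """

    channels: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    target: tuple[float, float] = (0.0, 1.0)
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValueError("per-channel max must be >= min")
        if not self.target[1] > self.target[0]:
            raise ValueError("target interval must have positive length")
        self._index = {c: j for j, c in enumerate(self.channels)}

    @property
    def constant_mask(self) -> np.ndarray:
        return self.maxs == self.mins

    def channel_index(self, channel: str) -> int:
        try:
            return self._index[channel]
        except KeyError:
            raise KeyError(f"unknown channel {channel!r}") from None


def fit_normalization(
    table: FeatureTable, target: tuple[float, float] = (0.0, 1.0)
) -> NormalizationSpec:
    """Fit per-channel extrema on ``table`` (typically the training split)."""
    mins = table.values.min(axis=0)
    maxs = table.values.max(axis=0)
    spec = NormalizationSpec(list(table.channels), mins, maxs, target)
    n_const = int(spec.constant_mask.sum())
    if n_const:
        const = [c for c, m in zip(spec.channels, spec.constant_mask) if m]
        logger.info("constant channel(s) %s excluded from rule search", const)
    return spec


def apply_normalization(spec: NormalizationSpec, x: float, channel: str) -> float:
    """Raw value -> normalized target-interval value (not clipped)."""
    j = spec.channel_index(channel)
    nb, nh = spec.target
    if spec.mins[j] == spec.maxs[j]:
        return nb
    frac = (x - spec.mins[j]) / (spec.maxs[j] - spec.mins[j])
    return nb + frac * (nh - nb)


def invert_normalization(spec: NormalizationSpec, y: float, channel: str) -> float:
    """Normalized value -> raw units (exact inverse on non-constant channels)."""
    j = spec.channel_index(channel)
    nb, nh = spec.target
    if spec.mins[j] == spec.maxs[j]:
        return float(spec.mins[j])
    frac = (y - nb) / (nh - nb)
    return float(spec.mins[j] + frac * (spec.maxs[j] - spec.mins[j]))


def normalize_table(spec: NormalizationSpec, table: FeatureTable) -> np.ndarray:
    """Normalize every column of ``table``; constant channels collapse to N_b."""
    if table.channels != spec.channels:
        raise KeyError("table channels do not match normalization spec")
    nb, nh = spec.target
    span = np.where(spec.constant_mask, 1.0, spec.maxs - spec.mins)
    frac = (table.values - spec.mins) / span
    out = nb + frac * (nh - nb)
    out[:, spec.constant_mask] = nb
    return out


def _fixture_path(name: str) -> Path:
    res = importlib.resources.files("sunrule") / "fixtures" / name
    return Path(str(res))


def load_fixture_table(which: str, canonical_labels: bool = False) -> FeatureTable:
    """Load a packaged 19-row fixture table: ``"cl"`` or ``"follicle"``.

    With ``canonical_labels`` the printed glyphs are mapped to the classes
    the printed rules conclude (see :data:`FIXTURE_LABEL_MAPS`).
    """
    files = {"cl": "cl_19rows.csv", "follicle": "follicle_19rows.csv"}
    if which not in files:
        raise KeyError(f"unknown fixture {which!r}; expected one of {sorted(files)}")
    label_map = FIXTURE_LABEL_MAPS[which] if canonical_labels else None
    return read_table(_fixture_path(files[which]), label_map=label_map)


def load_fixture_rules(which: str) -> list[dict]:
    """Load packaged rule fixtures as plain dicts (``"cl"`` or ``"follicle"``)."""
    files = {"cl": "rules_cl.json", "follicle": "rules_follicle.json"}
    if which not in files:
        raise KeyError(f"unknown fixture {which!r}; expected one of {sorted(files)}")
    with _fixture_path(files[which]).open() as fh:
        return json.load(fh)
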