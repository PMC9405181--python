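"""Feature-table I/O, min-max normalization, and label-scheme mapping.

Tables follow the UCI "Epileptic Seizure Recognition" layout: one row per
1-second EEG segment, numeric feature columns ``X1..Xd`` and an integer label
column ``y``.  Raw labels are ``1..5`` with 1 = ictal (seizure); the published
class scheme instead uses 0 = seizure, so :func:`read_feature_table` remaps
raw labels on read (binary: raw 1 -> 0, raw 2-5 -> 1; multiclass: raw k -> k-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "NormalizationParams",
    "read_feature_table",
    "write_feature_table",
    "remap_labels",
    "fit_minmax",
    "apply_minmax",
    "invert_minmax",
    "ParseError",
    "LabelError",
]

VALID_SCHEMES = ("binary", "multiclass", "raw")


class ParseError(ValueError):
    """Input file missing, empty, or containing non-numeric cells."""


class LabelError(ValueError):
    """A label value not admissible under the requested scheme."""


@dataclass
class FeatureTable:
    """An n x d numeric feature matrix with integer labels.

    Attributes
    ----------
    values : ndarray, shape (n, d)
        Feature values (EEG segment amplitudes, arbitrary units).
    labels : ndarray, shape (n,)
        Non-negative integer class labels.
    feature_names : list of str
        Column identifiers, length d.
    label_scheme : {"binary", "multiclass", "raw"}
    """

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    label_scheme: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n < 1 or d < 1:
            raise ValueError("feature table must have at least one row and column")
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal the row count")
        if not self.feature_names:
            self.feature_names = [f"X{j + 1}" for j in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal the column count")
        if self.label_scheme not in VALID_SCHEMES:
            raise ValueError(f"unknown label scheme {self.label_scheme!r}")
        if np.any(self.labels < 0):
            raise LabelError("labels must be non-negative")
        allowed = {"binary": {0, 1}, "multiclass": {0, 1, 2, 3, 4}}.get(self.label_scheme)
        if allowed is not None and not set(np.unique(self.labels)) <= allowed:
            raise LabelError(
                f"labels {sorted(set(self.labels) - allowed)} invalid under "
                f"{self.label_scheme!r} scheme"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class NormalizationParams:
    """Per-feature observed extremes used by the min-max map."""

    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float)
        self.x_max = np.asarray(self.x_max, dtype=float)
        if self.x_min.shape != self.x_max.shape or self.x_min.ndim != 1:
            raise ValueError("x_min and x_max must be 1-D vectors of equal length")
        if np.any(self.x_min > self.x_max):
            raise ValueError("x_min must not exceed x_max")


def remap_labels(raw_labels: np.ndarray, label_scheme: str) -> np.ndarray:
    """Map raw UCI labels {1..5} to the published class scheme.

    Binary: raw 1 (seizure) -> 0, raw 2-5 -> 1.  Multiclass: raw k -> k-1.
    ``raw`` leaves labels untouched.
    """
    raw = np.asarray(raw_labels, dtype=int)
    if label_scheme == "raw":
        return raw
    bad = set(np.unique(raw)) - {1, 2, 3, 4, 5}
    if bad:
        raise LabelError(f"raw labels {sorted(bad)} outside the expected range 1..5")
    if label_scheme == "binary":
        return np.where(raw == 1, 0, 1)
    if label_scheme == "multiclass":
        return raw - 1
    raise ValueError(f"unknown label scheme {label_scheme!r}")


def read_feature_table(
    path, label_column: str = "y", label_scheme: str = "raw"
) -> FeatureTable:
    """Read a UCI-layout CSV into a :class:`FeatureTable`.

    Raw labels are remapped according to ``label_scheme``; row order is
    preserved.  Raises :class:`ParseError` on empty files or non-numeric
    cells (naming the offending row and column) and :class:`LabelError` on
    inadmissible labels.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"{path} contains no data rows")
    if label_column not in df.columns:
        raise ParseError(f"label column {label_column!r} not found in {path}")
    feature_cols = [c for c in df.columns if c != label_column]
    if not feature_cols:
        raise ParseError(f"{path} has no feature columns")
    values = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.index[~np.isfinite(numeric.to_numpy(dtype=float))]
        if len(bad):
            raise ParseError(
                f"non-numeric or non-finite cell at row {bad[0]}, column {col!r}"
            )
        values[:, j] = numeric.to_numpy(dtype=float)
    raw = pd.to_numeric(df[label_column], errors="coerce")
    if raw.isna().any():
        row = int(raw.index[raw.isna()][0])
        raise ParseError(f"non-numeric label at row {row}, column {label_column!r}")
    labels = remap_labels(raw.to_numpy(dtype=int), label_scheme)
    return FeatureTable(values, labels, list(feature_cols), label_scheme)


def write_feature_table(table: FeatureTable, path, label_column: str = "y") -> None:
    """Write a table as CSV in the same dialect the reader expects."""
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df[label_column] = table.labels.astype(int)
    df.to_csv(path, index=False)


def fit_minmax(table: FeatureTable) -> NormalizationParams:
    """Column-wise extremes of the table (fit on training folds only)."""
    return NormalizationParams(table.values.min(axis=0), table.values.max(axis=0))


def apply_minmax(table: FeatureTable, params: NormalizationParams) -> FeatureTable:
    """Map each cell to (x - x_min) / (x_max - x_min).

    Constant columns (x_max == x_min) map to 0 everywhere, keeping the
    transform total.  Values outside the fitted range are not clipped, so
    test-fold cells may fall outside [0, 1].
    """
    if params.x_min.shape[0] != table.n_features:
        raise ValueError(
            f"params dimension {params.x_min.shape[0]} does not match "
            f"table dimension {table.n_features}"
        )
    span = params.x_max - params.x_min
    safe = np.where(span > 0, span, 1.0)
    z = (table.values - params.x_min) / safe
    z[:, span == 0] = 0.0
    return FeatureTable(z, table.labels, list(table.feature_names), table.label_scheme)


def invert_minmax(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Inverse map x_min + z * (x_max - x_min) (constant columns stay at x_min)."""
    return params.x_min + np.asarray(values, dtype=float) * (params.x_max - params.x_min)
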