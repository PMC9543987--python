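"""Core dataset container, CSV ingestion, imputation and encoding.

A multilabel cohort is a participant-level table of mixed numeric /
categorical predictors together with a block of binary condition columns
(the labels).  Predictors may contain missing values; labels may not —
participants without complete condition information are excluded when the
dataset is constructed (the analytic-sample rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ConfigError",
    "MultiLabelDataset",
    "PredictionMatrix",
    "Imputer",
    "FeatureEncoder",
    "load_dataset",
    "write_dataset",
]

#: values treated as missing when reading CSV files
NA_VALUES = ["", "NA"]


class DataError(ValueError):
    """Raised when input data violate a dataset invariant."""


class ConfigError(ValueError):
    """Raised when a configuration (column names, options) is invalid."""


class MultiLabelDataset:
    """Predictor table ``X`` plus binary label matrix ``Y``.

    Parameters
    ----------
    X : pandas.DataFrame
        Feature columns, numeric or categorical (``object``/``category``
        dtype).  Missing values are permitted.
    Y : pandas.DataFrame
        Binary label columns (strictly 0/1, no missing values).

    Invariants enforced at construction: at least one instance, at least
    two labels (override with ``allow_single_label`` for degenerate
    single-outcome uses), disjoint unique feature/label names, all label
    values in {0, 1}.
    """

    def __init__(self, X: pd.DataFrame, Y: pd.DataFrame, *, allow_single_label: bool = False):
        if len(X) != len(Y):
            raise DataError(f"feature table has {len(X)} rows but label table has {len(Y)}")
        if len(Y) < 1:
            raise DataError("dataset must contain at least one instance")
        min_labels = 1 if allow_single_label else 2
        if Y.shape[1] < min_labels:
            raise DataError(f"dataset must have at least {min_labels} label columns")
        if len(set(X.columns)) != X.shape[1] or len(set(Y.columns)) != Y.shape[1]:
            raise DataError("duplicate column names")
        overlap = set(X.columns) & set(Y.columns)
        if overlap:
            raise DataError(f"feature and label names overlap: {sorted(overlap)}")
        if Y.isna().any().any():
            bad = Y.columns[Y.isna().any()].tolist()
            raise DataError(f"missing values in label column(s) {bad}; drop incomplete rows first")
        vals = Y.to_numpy()
        ok = np.isin(vals, [0, 1]) | np.isin(vals, [0.0, 1.0])
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise DataError(
                f"non-binary label value {vals[i, j]!r} at row {i}, column {Y.columns[j]!r}"
            )
        self.X = X.reset_index(drop=True)
        self.Y = Y.reset_index(drop=True).astype(np.int8)

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        """Number of instances |D|."""
        return len(self.Y)

    @property
    def labels(self) -> list[str]:
        """Ordered label names L."""
        return list(self.Y.columns)

    @property
    def n_labels(self) -> int:
        return self.Y.shape[1]

    @property
    def features(self) -> list[str]:
        return list(self.X.columns)

    def label_matrix(self) -> np.ndarray:
        """Label values as an ``(n, |L|)`` int array."""
        return self.Y.to_numpy()

    # ------------------------------------------------------------------
    def subset(self, rows: Sequence[int]) -> "MultiLabelDataset":
        """Row subset by positional index; preserves row order given."""
        rows = np.asarray(rows)
        return MultiLabelDataset(
            self.X.iloc[rows].reset_index(drop=True),
            self.Y.iloc[rows].reset_index(drop=True),
            allow_single_label=self.n_labels == 1,
        )

    def select_features(self, names: Iterable[str]) -> "MultiLabelDataset":
        names = list(names)
        missing = [c for c in names if c not in self.X.columns]
        if missing:
            raise ConfigError(f"unknown feature(s): {missing}")
        return MultiLabelDataset(self.X[names].copy(), self.Y.copy(),
                                 allow_single_label=self.n_labels == 1)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"MultiLabelDataset(n={self.n}, features={len(self.features)}, "
                f"labels={self.n_labels})")


@dataclass
class PredictionMatrix:
    """Per-instance predicted label sets, optionally with probabilities.

    ``predicted`` is an ``(n, |L|)`` 0/1 matrix; when ``scores`` is present
    ``predicted == (scores >= threshold)`` (ties predict positive).
    """

    predicted: np.ndarray
    labels: list[str]
    scores: np.ndarray | None = None
    threshold: float = 0.5

    def __post_init__(self):
        self.predicted = np.asarray(self.predicted)
        if not np.isin(self.predicted, [0, 1]).all():
            raise DataError("predicted entries must be 0/1")
        self.predicted = self.predicted.astype(np.int8)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if self.scores.shape != self.predicted.shape:
                raise DataError("scores shape does not match predictions")
            if ((self.scores < 0) | (self.scores > 1)).any():
                raise DataError("scores must lie in [0, 1]")
            if not np.array_equal(self.predicted, (self.scores >= self.threshold).astype(np.int8)):
                raise DataError("predicted must equal scores >= threshold")

    @classmethod
    def from_scores(cls, scores: np.ndarray, labels: Sequence[str],
                    threshold: float = 0.5) -> "PredictionMatrix":
        scores = np.asarray(scores, dtype=float)
        return cls((scores >= threshold).astype(np.int8), list(labels), scores, threshold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.predicted, columns=self.labels)


# ----------------------------------------------------------------------
# CSV ingestion


def load_dataset(path, label_columns: Sequence[str]) -> MultiLabelDataset:
    """Read a cohort CSV and split it into features and labels.

    Rows with any missing label value are dropped (the analytic-sample
    rule); the number dropped is recorded on the returned dataset as
    ``dropped_label_rows`` and reported through a warning.

    Parameters
    ----------
    path : str or pathlib.Path
        CSV file with a header row; comma separated, UTF-8, with ``""`` or
        ``NA`` marking missing predictor cells.
    label_columns : sequence of str
        Names of the binary condition columns.
    """
    try:
        frame = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty CSV file: {path}") from exc
    missing = [c for c in label_columns if c not in frame.columns]
    if missing:
        raise ConfigError(f"label column(s) {missing} not present in {path}")
    label_columns = list(label_columns)
    Y = frame[label_columns]
    complete = ~Y.isna().any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"dropped {dropped} row(s) with incomplete label information")
        frame = frame.loc[complete].reset_index(drop=True)
        Y = frame[label_columns]
    Yv = Y.apply(pd.to_numeric, errors="coerce")
    bad = ~(Yv.isin([0, 1]) | Yv.isna()).to_numpy()
    if Yv.isna().any().any() or bad.any():
        mask = (Yv.isna() | ~Yv.isin([0, 1])).to_numpy()
        i, j = np.argwhere(mask)[0]
        raise DataError(
            f"non-binary label value {Y.iloc[i, j]!r} at row {i}, column {label_columns[j]!r}"
        )
    X = frame.drop(columns=label_columns)
    ds = MultiLabelDataset(X, Yv.astype(np.int8))
    ds.dropped_label_rows = dropped
    return ds


def write_dataset(dataset: MultiLabelDataset, path) -> None:
    """Write features + labels back to a single CSV (inverse of load)."""
    out = pd.concat([dataset.X, dataset.Y], axis=1)
    out.to_csv(path, index=False, na_rep="")


# ----------------------------------------------------------------------
# Imputation


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


@dataclass
class Imputer:
    """Median / mode imputer fitted on a reference row subset.

    Numeric features are filled with the median, categorical features with
    the mode, both computed on the fitting rows only.  A feature entirely
    missing among the fitting rows falls back to 0 (numeric) or the level
    ``"unknown"`` (categorical), with a warning.  Never touches labels.
    """

    fill: dict = field(default_factory=dict)

    def fit(self, dataset: MultiLabelDataset, rows: Sequence[int] | None = None) -> "Imputer":
        if rows is None:
            rows = np.arange(dataset.n)
        rows = np.asarray(rows)
        if rows.size == 0:
            raise ConfigError("cannot fit an imputer on an empty row subset")
        sub = dataset.X.iloc[rows]
        self.fill = {}
        for col in sub.columns:
            s = sub[col]
            if s.notna().sum() == 0:
                fallback = 0.0 if _is_numeric(s) else "unknown"
                warnings.warn(f"feature {col!r} entirely missing in fitting rows; "
                              f"falling back to {fallback!r}")
                self.fill[col] = fallback
            elif _is_numeric(s):
                self.fill[col] = float(s.median())
            else:
                # mode with deterministic tie-break (lexicographically first)
                self.fill[col] = sorted(s.dropna().mode())[0]
        return self

    def transform(self, dataset: MultiLabelDataset) -> MultiLabelDataset:
        if not self.fill:
            raise ConfigError("imputer has not been fitted")
        X = dataset.X.copy()
        for col, value in self.fill.items():
            if col in X.columns:
                X[col] = X[col].fillna(value)
        return MultiLabelDataset(X, dataset.Y.copy(),
                                 allow_single_label=dataset.n_labels == 1)

    def fit_transform(self, dataset: MultiLabelDataset,
                      rows: Sequence[int] | None = None) -> MultiLabelDataset:
        return self.fit(dataset, rows).transform(dataset)


# ----------------------------------------------------------------------
# Encoding


class FeatureEncoder:
    """One-hot or ordinal encoding of the predictor table.

    One-hot expands each categorical feature into indicator columns with
    the (lexicographically) first level dropped as reference; the column
    map supports aggregating encoded-column importances back to their
    source feature by summation.  Ordinal encoding maps levels to integer
    codes in sorted-level order.
    """

    def __init__(self, scheme: str = "onehot"):
        if scheme not in ("onehot", "ordinal"):
            raise ConfigError(f"unknown encoding scheme {scheme!r}")
        self.scheme = scheme
        self.categories_: dict[str, list] = {}
        self.columns_: list[str] | None = None
        self.column_map_: dict[str, str] = {}

    def fit(self, X: pd.DataFrame) -> "FeatureEncoder":
        self.categories_ = {}
        for col in X.columns:
            if not _is_numeric(X[col]):
                if self.scheme == "onehot" and X[col].isna().any():
                    raise DataError(f"feature {col!r} has missing values; impute before one-hot")
                self.categories_[col] = sorted(X[col].dropna().unique())
        self.columns_ = None
        self.column_map_ = {}
        # establish output columns from the fitted frame
        self.transform(X, _fitting=True)
        return self

    def transform(self, X: pd.DataFrame, _fitting: bool = False) -> pd.DataFrame:
        out = {}
        colmap = {}
        for col in X.columns:
            if col not in self.categories_:
                out[col] = pd.to_numeric(X[col])
                colmap[col] = col
                continue
            levels = self.categories_[col]
            if self.scheme == "ordinal":
                code = {lev: i for i, lev in enumerate(levels)}
                out[col] = X[col].map(code).astype(float)
                colmap[col] = col
            else:
                seen = set(X[col].dropna().unique())
                unseen = seen - set(levels)
                if unseen and not _fitting:
                    warnings.warn(f"unseen level(s) {sorted(unseen)} in feature {col!r}; "
                                  "encoded as all-zero indicators")
                for lev in levels[1:]:  # reference level dropped
                    name = f"{col}={lev}"
                    out[name] = (X[col] == lev).astype(float)
                    colmap[name] = col
        frame = pd.DataFrame(out, index=X.index)
        if self.columns_ is None:
            self.columns_ = list(frame.columns)
            self.column_map_ = colmap
        return frame[self.columns_]

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def aggregate_importance(self, importances: dict[str, float]) -> dict[str, float]:
        """Sum encoded-column importances back onto their source features."""
        agg: dict[str, float] = {}
        for col, value in importances.items():
            src = self.column_map_.get(col, col)
            agg[src] = agg.get(src, 0.0) + value
        return agg
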