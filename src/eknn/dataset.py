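"""Labeled tabular datasets: loading, writing and synthesis.

A :class:`LabeledDataset` is the single in-memory container consumed by all
other modules: an ``m x n`` float matrix of feature measurements plus a
length-``m`` integer label vector. Labels are encoded to dense integers in
*first-appearance order*; that order is also the deterministic tie-break
order for majority votes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "DatasetError",
    "SchemaError",
    "MissingValueError",
    "NonNumericError",
    "TooFewSamplesError",
    "load_table",
    "write_table",
    "simulate_uniform",
    "make_separable_fixture",
]


class DatasetError(ValueError):
    """Base class for dataset validation failures."""


class SchemaError(DatasetError):
    """A required column is absent or duplicated."""


class MissingValueError(DatasetError):
    """A feature or label cell is missing (NaN/empty)."""


class NonNumericError(DatasetError):
    """A feature cell cannot be interpreted as a number."""


class TooFewSamplesError(DatasetError):
    """Fewer than two samples were provided."""


@dataclass(frozen=True)
class LabeledDataset:
    """An ``m x n`` feature matrix with encoded class labels.

    Attributes
    ----------
    features : ndarray of shape (m, n)
        Real-valued measurements, no missing values.
    labels : ndarray of shape (m,)
        Dense integer class codes ``0..n_classes-1`` in first-appearance
        order of the original label values.
    label_names : tuple
        Original label values, indexed by code.
    feature_names : tuple of str
        Unique column identifiers, length ``n``.
    sample_ids : tuple of str
        Unique row identifiers, length ``m``.
    """

    features: np.ndarray
    labels: np.ndarray
    label_names: tuple = field(default=())
    feature_names: tuple = field(default=())
    sample_ids: tuple = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2:
            raise DatasetError("features must be a 2-D matrix")
        m, n = X.shape
        if m < 2:
            raise TooFewSamplesError(f"need at least 2 samples, got {m}")
        if n < 1:
            raise DatasetError("need at least one feature column")
        if y.shape != (m,):
            raise DatasetError("labels must be a length-m vector")
        if np.isnan(X).any():
            raise MissingValueError("features contain missing values")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y.astype(np.int64))
        if not self.label_names:
            codes = sorted(set(int(c) for c in y))
            object.__setattr__(self, "label_names", tuple(codes))
        if not self.feature_names:
            object.__setattr__(
                self, "feature_names", tuple(f"f{i}" for i in range(1, n + 1))
            )
        if not self.sample_ids:
            object.__setattr__(
                self, "sample_ids", tuple(f"s{i}" for i in range(1, m + 1))
            )
        if len(self.feature_names) != n or len(set(self.feature_names)) != n:
            raise SchemaError("feature_names must be unique, length n")
        if len(self.sample_ids) != m or len(set(self.sample_ids)) != m:
            raise SchemaError("sample_ids must be unique, length m")

    @property
    def m(self) -> int:
        return self.features.shape[0]

    @property
    def n(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.label_names)


def _encode_labels(raw) -> tuple[np.ndarray, tuple]:
    """Encode labels to dense integers in first-appearance order."""
    names: list = []
    seen: dict = {}
    codes = np.empty(len(raw), dtype=np.int64)
    for i, v in enumerate(raw):
        if v not in seen:
            seen[v] = len(names)
            names.append(v)
        codes[i] = seen[v]
    return codes, tuple(names)


def load_table(path, label_column: str, delimiter: str = ",") -> LabeledDataset:
    """Load a delimited text table into a :class:`LabeledDataset`.

    Parameters
    ----------
    path : str or PathLike
        Delimited text file with a header row; one row per sample.
    label_column : str
        Name of the class-label column; all other columns must be numeric
        feature columns.
    delimiter : str
        Field separator (default comma).
    """
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except FileNotFoundError:
        raise
    if label_column not in frame.columns:
        raise SchemaError(f"label column {label_column!r} not found")
    labels_raw = frame[label_column]
    if labels_raw.isna().any():
        raise MissingValueError("label column contains missing values")
    feats = frame.drop(columns=[label_column])
    if feats.shape[1] < 1:
        raise SchemaError("no feature columns present")
    if feats.isna().any().any():
        raise MissingValueError("feature columns contain missing values")
    for col in feats.columns:
        if not np.issubdtype(feats[col].dtype, np.number):
            raise NonNumericError(f"feature column {col!r} is not numeric")
    if len(frame) < 2:
        raise TooFewSamplesError(f"need at least 2 samples, got {len(frame)}")
    codes, names = _encode_labels(labels_raw.tolist())
    return LabeledDataset(
        features=feats.to_numpy(dtype=float),
        labels=codes,
        label_names=names,
        feature_names=tuple(str(c) for c in feats.columns),
        sample_ids=tuple(str(i) for i in frame.index),
    )


def write_table(data: LabeledDataset, path, delimiter: str = ",",
                label_column: str = "label") -> None:
    """Write a dataset to delimited text (header row, label column last)."""
    frame = pd.DataFrame(data.features, columns=list(data.feature_names))
    frame[label_column] = [data.label_names[c] for c in data.labels]
    frame.to_csv(path, sep=delimiter, index=False)


def simulate_uniform(m: int, n: int, n_classes: int = 2,
                     seed: int = 0) -> LabeledDataset:
    """Simulate an uninformative dataset: features i.i.d. U(0,1)^n.

    Labels are assigned round-robin (sample ``i`` gets class ``i mod
    n_classes``) and therefore carry no class information by construction —
    the setting used for runtime baselines where any classification signal
    would be an artifact.
    """
    if m < 2 or n < 1:
        raise DatasetError(f"invalid dimensions m={m}, n={n}")
    if not 1 <= n_classes <= m:
        raise DatasetError(f"n_classes={n_classes} outside [1, m]")
    rng = np.random.default_rng(seed)
    X = rng.random((m, n))
    y = np.arange(m, dtype=np.int64) % n_classes
    return LabeledDataset(
        features=X,
        labels=y,
        label_names=tuple(f"c{i}" for i in range(n_classes)),
    )


def make_separable_fixture(m: int, n: int, informative: int, gap: float,
                           seed: int = 0) -> LabeledDataset:
    """Two balanced classes separable on exactly one planted feature.

    The informative feature (1-based index) takes values in ``[0, 1)`` for
    class 0 and in ``[1 + gap, 2 + gap)`` for class 1, so its
    class-conditional supports are disjoint intervals separated by ``gap``.
    All other features are i.i.d. U(0,1) noise. Under the squared-difference
    metric the within-class distance on the planted feature is < 1 while the
    between-class distance is > gap**2, so for ``gap > 1`` a 1-NN restricted
    to that feature commits zero leave-one-out errors.
    """
    if m % 2 != 0:
        raise DatasetError("m must be even for balanced classes")
    if not 1 <= informative <= n:
        raise DatasetError(f"informative index {informative} outside [1, {n}]")
    if gap <= 0:
        raise DatasetError("gap must be positive")
    rng = np.random.default_rng(seed)
    X = rng.random((m, n))
    y = np.arange(m, dtype=np.int64) % 2
    col = informative - 1
    X[y == 1, col] = X[y == 1, col] + 1.0 + gap
    return LabeledDataset(features=X, labels=y, label_names=("c0", "c1"))
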