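"""Feature-wise distance matrices for decomposable (product) distances.

A distance is *decomposable* when the matrix over a feature subset is the
entrywise sum of per-feature matrices. Memoizing the ``n`` one-dimensional
matrices turns every subset's matrix into a chain of O(m^2) additions,
independent of the subset's dimensionality. The canonical example is the
squared Euclidean distance (no square root); rooted Minkowski distances are
not decomposable and cannot be registered.

The registry holds *per-feature* kernels ``d_i: R x R -> R>=0`` applied to
one column at a time; decomposability is therefore structural (sums of
per-feature matrices), never assumed of a black-box full-space distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .dataset import LabeledDataset
from .subsets import Signature, validate_signature

__all__ = [
    "DistanceMatrix",
    "FeaturewiseDistances",
    "EntryCounter",
    "register_metric",
    "featurewise_matrices",
    "denovo_matrix",
    "add_feature",
]


@dataclass
class EntryCounter:
    """Counts scalar distance-entry computations (m^2 per matrix op)."""

    entries: int = 0

    def add_matrices(self, count: int, m: int) -> None:
        self.entries += count * m * m


@dataclass(frozen=True)
class DistanceMatrix:
    """An m x m symmetric nonnegative matrix tied to a feature signature."""

    values: np.ndarray
    subset: Signature

    @property
    def m(self) -> int:
        return self.values.shape[0]


def _sq_diff(col: np.ndarray) -> np.ndarray:
    d = col[:, None] - col[None, :]
    return d * d


def _abs_diff(col: np.ndarray) -> np.ndarray:
    return np.abs(col[:, None] - col[None, :])


# name -> column kernel producing one m x m per-feature matrix
_METRICS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sqeuclidean": _sq_diff,
    "manhattan": _abs_diff,
}


def register_metric(name: str, column_kernel: Callable[[np.ndarray], np.ndarray]) -> None:
    """Register a per-feature distance kernel.

    ``column_kernel`` maps one feature column (length m) to its m x m
    per-feature distance matrix, which must be symmetric, zero-diagonal and
    nonnegative. Only per-feature kernels are accepted: this is what keeps
    every registered metric decomposable by construction.
    """
    _METRICS[name] = column_kernel


def _kernel(metric: str) -> Callable[[np.ndarray], np.ndarray]:
    try:
        return _METRICS[metric]
    except KeyError:
        raise KeyError(
            f"unregistered metric {metric!r}; known: {sorted(_METRICS)}"
        ) from None


class FeaturewiseDistances:
    """The n memoized one-dimensional distance matrices of a dataset.

    ``single(i)`` returns the m x m matrix for the 1-based feature ``i``.
    The stack of all matrices is held as one ``(n, m, m)`` array.
    """

    def __init__(self, matrices: np.ndarray, metric_name: str):
        self.matrices = matrices  # (n, m, m)
        self.metric_name = metric_name

    @property
    def n(self) -> int:
        return self.matrices.shape[0]

    @property
    def m(self) -> int:
        return self.matrices.shape[1]

    def single(self, i: int) -> np.ndarray:
        """Per-feature matrix for 1-based feature index ``i``."""
        if not 1 <= i <= self.n:
            raise ValueError(f"feature index {i} outside [1, {self.n}]")
        return self.matrices[i - 1]


def featurewise_matrices(data: LabeledDataset, metric: str = "sqeuclidean",
                         counter: Optional[EntryCounter] = None) -> FeaturewiseDistances:
    """Compute all n per-feature distance matrices of a dataset."""
    kern = _kernel(metric)
    m, n = data.m, data.n
    out = np.empty((n, m, m))
    for j in range(n):
        out[j] = kern(data.features[:, j])
    if counter is not None:
        counter.add_matrices(n, m)
    return FeaturewiseDistances(out, metric)


def denovo_matrix(data: LabeledDataset, s: Signature, metric: str = "sqeuclidean",
                  counter: Optional[EntryCounter] = None) -> DistanceMatrix:
    """Direct O(m^2 * |s|) distance matrix for one subset, no memoization.

    This is the baseline an incremental traversal is measured against, and
    the reference oracle its delivered matrices are compared to.
    """
    validate_signature(s, data.n)
    if not s:
        raise ValueError("the empty signature has no distance matrix")
    kern = _kernel(metric)
    m = data.m
    acc = np.zeros((m, m))
    for i in s:
        acc += kern(data.features[:, i - 1])
    if counter is not None:
        counter.add_matrices(len(s), m)
    return DistanceMatrix(values=acc, subset=tuple(s))


def add_feature(cumulative: DistanceMatrix, single: np.ndarray,
                i: int) -> DistanceMatrix:
    """Extend a cumulative matrix by one feature via a single addition.

    ``i`` must exceed every index already in ``cumulative.subset`` so that
    the resulting signature stays strictly increasing.
    """
    if cumulative.subset and i <= cumulative.subset[-1]:
        raise ValueError(
            f"feature {i} not greater than current maximum {cumulative.subset[-1]}"
        )
    return DistanceMatrix(values=cumulative.values + single,
                          subset=cumulative.subset + (i,))
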