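"""scikit-learn estimator interface to the exhaustive e-k-NN screen."""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .dataset import LabeledDataset, _encode_labels
from .landscape import exhaustive_screen, select_best, summarize_landscape
from .subsets import sig_from_id
from .traversal import IdRange


class ExhaustiveKnnSelector(SelectorMixin, BaseEstimator):
    """Feature selection by exhaustive k-NN cross-validation (e-k-NN).

    Fitting evaluates the internal r x f cross-validation error of a k-NN
    classifier on *every* non-empty subset of the input features — the full
    fitness landscape — using an incremental distance-matrix traversal
    (one O(m^2) matrix addition per subset) and lookup-accelerated CV. The
    selected subset is the arg-min of the CV error; ties prefer smaller
    subsets, then earlier enumeration positions.

    Parameters
    ----------
    n_neighbors : int, default=1
        Neighborhood size k of the internal k-NN.
    cv_runs : int, default=10
        Number r of independent CV repetitions.
    cv_folds : int, default=10
        Number f of folds per repetition.
    metric : str, default="sqeuclidean"
        Registered per-feature (decomposable) distance.
    random_state : int, default=0
        Seed of the fold plan; one plan is shared by all subsets.
    workers : int, default=1
        Parallel traversal chunks.
    id_range : tuple of (int, int), optional
        Restrict the screen to a contiguous range of subset ids
        (1-based enumeration positions); default screens all 2**p - 1
        non-empty subsets of the p input features.

    Attributes
    ----------
    landscape_ : Landscape
        The full census of subset CV errors.
    best_id_ : int
        Enumeration position of the selected subset.
    best_signature_ : tuple of int
        Selected features as 1-based column indices, strictly increasing.
    best_cv_error_ : float
        Internal CV error of the selected subset.
    support_ : ndarray of shape (n_features_in_,)
        Boolean mask of the selected features.

    Examples
    --------
    >>> import numpy as np
    >>> from eknn.selector import ExhaustiveKnnSelector
    >>> rng = np.random.default_rng(0)
    >>> X = rng.random((40, 5)); y = np.arange(40) % 2
    >>> X[y == 1, 2] += 3.0   # plant a separating feature
    >>> sel = ExhaustiveKnnSelector(n_neighbors=1, random_state=0).fit(X, y)
    >>> sel.best_signature_
    (3,)
    """

    def __init__(self, n_neighbors: int = 1, cv_runs: int = 10,
                 cv_folds: int = 10, metric: str = "sqeuclidean",
                 random_state: int = 0, workers: int = 1,
                 id_range: Optional[tuple[int, int]] = None):
        self.n_neighbors = n_neighbors
        self.cv_runs = cv_runs
        self.cv_folds = cv_folds
        self.metric = metric
        self.random_state = random_state
        self.workers = workers
        self.id_range = id_range

    def fit(self, X, y):
        """Screen all feature subsets of ``(X, y)`` and select the arg-min."""
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        codes, names = _encode_labels(list(y))
        data = LabeledDataset(features=np.asarray(X, dtype=float),
                              labels=codes, label_names=names)
        rng = None if self.id_range is None else IdRange(*self.id_range)
        self.landscape_ = exhaustive_screen(
            data, k=self.n_neighbors, r=self.cv_runs, f=self.cv_folds,
            seed=self.random_state, id_range=rng, workers=self.workers,
            metric=self.metric,
        )
        ranked = select_best(self.landscape_)
        self.best_id_ = ranked[0]
        self.best_signature_ = sig_from_id(self.best_id_, data.n)
        idx = self.landscape_.ids.searchsorted(self.best_id_)
        self.best_cv_error_ = float(self.landscape_.cv_errors[idx])
        mask = np.zeros(data.n, dtype=bool)
        mask[[i - 1 for i in self.best_signature_]] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_

    def summary(self, bin_width: float = 0.01):
        """Per-size accuracy census of the fitted landscape."""
        check_is_fitted(self)
        return summarize_landscape(self.landscape_, bin_width=bin_width)
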