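"""k-NN prediction and r x f cross-validation from precomputed distances.

Two CV engines are provided. ``cv_error_naive`` is the transparent
reference: every held-out sample is classified by scanning its distance row
against the current training folds. ``cv_error_fast`` replaces most scans
by a lookup into a table of each sample's k *global* nearest neighbors
(nearest among all other samples): whenever all k global neighbors of a
test sample lie in the training folds, the stored list IS its local
neighborhood and the prediction — which then equals the leave-one-out
prediction — is read off directly. The lookup is exact acceleration, never
approximation: both engines produce identical predictions.

Determinism rules, applied identically everywhere:
  * neighbor distance ties are broken by ascending sample index;
  * vote ties are won by the label earliest in encoding order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import DistanceMatrix

__all__ = [
    "FoldPlan",
    "NeighborTable",
    "CvResult",
    "knn_predict",
    "make_folds",
    "cv_error_naive",
    "build_neighbor_table",
    "cv_error_fast",
    "loo_error",
]


@dataclass
class FoldPlan:
    """Assignment of m samples to f folds for each of r runs.

    ``assignments[run, sample]`` is the 0-based fold of a sample. Within
    each run every sample appears in exactly one fold and fold sizes differ
    by at most one. Identical ``(m, r, f, seed)`` reproduce the plan.
    """

    assignments: np.ndarray  # (r, m) int
    r: int
    f: int
    seed: int
    _train_cache: dict = field(default_factory=dict, repr=False)

    @property
    def m(self) -> int:
        return self.assignments.shape[1]

    def train_indices(self, run: int, fold: int) -> np.ndarray:
        """Ascending indices of samples outside ``fold`` in ``run`` (cached)."""
        key = (run, fold)
        hit = self._train_cache.get(key)
        if hit is None:
            hit = np.flatnonzero(self.assignments[run] != fold)
            self._train_cache[key] = hit
        return hit


@dataclass(frozen=True)
class NeighborTable:
    """Per-sample global k nearest neighbors (self excluded).

    ``neighbors[s]`` lists the k nearest other samples of ``s`` in
    nondecreasing distance order (ties by ascending index); ``distances``
    holds the matching values.
    """

    neighbors: np.ndarray  # (m, k) int
    distances: np.ndarray  # (m, k) float

    @property
    def k(self) -> int:
        return self.neighbors.shape[1]


@dataclass(frozen=True)
class CvResult:
    """Mean misclassification rate of an r x f CV plus lookup accounting."""

    error: float
    per_run_errors: np.ndarray
    lookup_hits: int
    lookup_misses: int


def _vote(labels_k: np.ndarray, n_classes: int) -> int:
    # argmax returns the first maximum -> earliest-encoded label wins ties
    return int(np.argmax(np.bincount(labels_k, minlength=n_classes)))


def knn_predict(dists_to_training: np.ndarray, training_labels: np.ndarray,
                k: int, n_classes: int | None = None) -> int:
    """Majority vote among the k nearest training samples.

    Distance ties at the k-boundary are broken by position in the training
    vector (stable sort), i.e. by ascending sample index when the training
    vector is in ascending index order.
    """
    d = np.asarray(dists_to_training)
    y = np.asarray(training_labels)
    if k < 1 or k > d.shape[0]:
        raise ValueError(f"k={k} outside [1, {d.shape[0]}]")
    if n_classes is None:
        n_classes = int(y.max()) + 1
    nearest = np.argsort(d, kind="stable")[:k]
    return _vote(y[nearest], n_classes)


def make_folds(m: int, r: int, f: int, seed: int) -> FoldPlan:
    """Random fold plan: per run, a uniform permutation sliced into f folds.

    The first ``m % f`` folds receive the extra sample. Runs draw from
    independent child streams of one seed sequence, so plans are
    reproducible and runs are mutually independent.
    """
    if not 2 <= f <= m:
        raise ValueError(f"folds f={f} outside [2, m={m}]")
    if r < 1:
        raise ValueError("r must be >= 1")
    children = np.random.SeedSequence(seed).spawn(r)
    assignments = np.empty((r, m), dtype=np.int64)
    sizes = np.full(f, m // f)
    sizes[: m % f] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    for run in range(r):
        perm = np.random.default_rng(children[run]).permutation(m)
        for j in range(f):
            assignments[run, perm[bounds[j]:bounds[j + 1]]] = j
    return FoldPlan(assignments=assignments, r=r, f=f, seed=seed)


def _as_matrix(D) -> np.ndarray:
    return D.values if isinstance(D, DistanceMatrix) else np.asarray(D)


def _check_k(k: int, min_train: int) -> None:
    if k < 1 or k > min_train:
        raise ValueError(f"k={k} exceeds smallest training set size {min_train}")


def cv_error_naive(D, labels: np.ndarray, k: int, plan: FoldPlan,
                   out_predictions: np.ndarray | None = None) -> CvResult:
    """Reference r x f CV: full neighbor scan for every held-out sample.

    ``out_predictions``, if given, must be an ``(r, m)`` int array; it is
    filled with the prediction of each sample in the run it is held out.
    """
    Dm = _as_matrix(D)
    y = np.asarray(labels)
    m = Dm.shape[0]
    n_classes = int(y.max()) + 1
    fold_sizes = np.array([np.bincount(plan.assignments[run], minlength=plan.f)
                           for run in range(plan.r)])
    _check_k(k, int(m - fold_sizes.max()))
    per_run = np.empty(plan.r)
    for run in range(plan.r):
        wrong = 0
        for fold in range(plan.f):
            train = plan.train_indices(run, fold)
            for v in np.flatnonzero(plan.assignments[run] == fold):
                pred = knn_predict(Dm[v, train], y[train], k, n_classes)
                wrong += pred != y[v]
                if out_predictions is not None:
                    out_predictions[run, v] = pred
        per_run[run] = wrong / m
    return CvResult(error=float(per_run.mean()), per_run_errors=per_run,
                    lookup_hits=0, lookup_misses=plan.r * m)


def build_neighbor_table(D, k: int) -> NeighborTable:
    """Global k-nearest-neighbor table (self excluded) from a distance matrix."""
    Dm = _as_matrix(D)
    m = Dm.shape[0]
    if not 1 <= k <= m - 1:
        raise ValueError(f"k={k} outside [1, m-1={m - 1}]")
    work = Dm.copy()
    np.fill_diagonal(work, np.inf)
    if k == 1:
        nn = np.argmin(work, axis=1)[:, None]  # argmin takes first -> lowest index
    else:
        nn = np.argsort(work, axis=1, kind="stable")[:, :k]
    return NeighborTable(neighbors=nn, distances=np.take_along_axis(work, nn, axis=1))


def cv_error_fast(D, labels: np.ndarray, k: int, plan: FoldPlan,
                  table: NeighborTable,
                  out_predictions: np.ndarray | None = None) -> CvResult:
    """Lookup-accelerated r x f CV, prediction-identical to the naive engine.

    A test sample is answered by lookup iff *all* k of its global nearest
    neighbors lie in the current training folds; its local neighborhood then
    equals the stored global list and the prediction equals the
    leave-one-out prediction. Any partial hit falls back to a full scan,
    which is what keeps the acceleration exact.
    """
    Dm = _as_matrix(D)
    y = np.asarray(labels)
    m = Dm.shape[0]
    if table.k != k:
        raise ValueError(f"table built for k={table.k}, requested k={k}")
    n_classes = int(y.max()) + 1
    # leave-one-out predictions: what every successful lookup returns
    nb_labels = y[table.neighbors]  # (m, k)
    counts = (nb_labels[:, :, None] == np.arange(n_classes)).sum(axis=1)
    loo_preds = np.argmax(counts, axis=1)
    fold_sizes = np.array([np.bincount(plan.assignments[run], minlength=plan.f)
                           for run in range(plan.r)])
    _check_k(k, int(m - fold_sizes.max()))
    per_run = np.empty(plan.r)
    hits = 0
    for run in range(plan.r):
        fold_of = plan.assignments[run]
        # a miss: some global neighbor shares the test sample's fold
        miss = np.any(fold_of[table.neighbors] == fold_of[:, None], axis=1)
        preds = loo_preds.copy()
        for v in np.flatnonzero(miss):
            train = plan.train_indices(run, int(fold_of[v]))
            preds[v] = knn_predict(Dm[v, train], y[train], k, n_classes)
        hits += int(m - miss.sum())
        if out_predictions is not None:
            out_predictions[run] = preds
        per_run[run] = np.mean(preds != y)
    total = plan.r * m
    return CvResult(error=float(per_run.mean()), per_run_errors=per_run,
                    lookup_hits=hits, lookup_misses=total - hits)


def loo_error(D, labels: np.ndarray, k: int) -> float:
    """Leave-one-out error, read directly off the global neighbor table.

    Leave-one-out is the f = m special case in which every lookup succeeds,
    so no scan is ever needed.
    """
    y = np.asarray(labels)
    table = build_neighbor_table(D, k)
    n_classes = int(y.max()) + 1
    nb_labels = y[table.neighbors]
    counts = (nb_labels[:, :, None] == np.arange(n_classes)).sum(axis=1)
    preds = np.argmax(counts, axis=1)
    return float(np.mean(preds != y))
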