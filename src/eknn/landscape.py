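"""Exhaustive e-k-NN screening: fitness landscapes over all feature subsets.

``exhaustive_screen`` walks the full subset enumeration (or a contiguous id
range), obtains each subset's distance matrix from the incremental
traversal, cross-validates a k-NN on it with the lookup-accelerated engine,
and records one ``(id, size, cv_error)`` row per subset — the complete
fitness landscape of the dataset. A single fold plan, drawn once from the
screen's seed, is shared by every subset so that error differences reflect
the subsets alone and repeated screens are bit-identical.

Selection (``select_best``) is the arg-min of the CV error; among ties the
smallest subset wins, then the smallest id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from joblib import Parallel, delayed

from .dataset import LabeledDataset
from .distance import featurewise_matrices
from .knn import FoldPlan, build_neighbor_table, cv_error_fast, make_folds
from .subsets import Signature, format_signature, sig_from_id
from .traversal import IdRange, partition_ids, traverse

__all__ = ["Landscape", "LandscapeSummary", "exhaustive_screen",
           "select_best", "summarize_landscape", "write_landscape"]

# beyond this, 2**n in-memory records stop being reasonable; callers must
# restrict the id range (or stream chunks themselves)
MAX_IN_MEMORY_N = 30


@dataclass(frozen=True)
class Landscape:
    """One evaluated screen: parallel arrays of id, subset size, CV error."""

    ids: np.ndarray        # (e,) int64, strictly increasing
    sizes: np.ndarray      # (e,) int64
    cv_errors: np.ndarray  # (e,) float64
    n: int
    m: int
    k: int
    r: int
    f: int
    seed: int
    lookup_hits: int = 0
    lookup_misses: int = 0

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def accuracies(self) -> np.ndarray:
        return 1.0 - self.cv_errors

    def signature_of(self, id: int) -> Signature:
        return sig_from_id(int(id), self.n)


@dataclass(frozen=True)
class LandscapeSummary:
    """Per-size census of a landscape's accuracies.

    ``per_size[s]`` maps subset size ``s`` (1..n) to a dict with keys
    ``count``, ``min``, ``max``, ``median``, ``hist`` (mode-normalized bin
    heights), ``mode_bin`` (index of the fullest bin). ``better_or_equal``
    is the fraction of subsets whose accuracy is at least the full-set
    accuracy (None when the full set was not screened).
    """

    per_size: dict
    bin_width: float
    bin_edges: np.ndarray
    better_or_equal: Optional[float]


def _screen_chunk(fw, labels, k, plan: FoldPlan, id_range: IdRange):
    total = len(id_range)
    sizes = np.empty(total, dtype=np.int64)
    errors = np.empty(total, dtype=np.float64)
    hits = misses = 0
    pos = 0

    def visit(id: int, sig: Signature, matrix: np.ndarray) -> None:
        nonlocal pos, hits, misses
        table = build_neighbor_table(matrix, k)
        res = cv_error_fast(matrix, labels, k, plan, table)
        sizes[pos] = len(sig)
        errors[pos] = res.error
        hits += res.lookup_hits
        misses += res.lookup_misses
        pos += 1

    traverse(fw, id_range, visit)
    return sizes, errors, hits, misses


def exhaustive_screen(data: LabeledDataset, k: int = 1, r: int = 10,
                      f: int = 10, seed: int = 0,
                      id_range: Optional[IdRange] = None, workers: int = 1,
                      metric: str = "sqeuclidean") -> Landscape:
    """Evaluate the k-NN CV error of every subset in ``id_range``.

    The default range covers all ``2**n - 1`` non-empty subsets. With
    ``workers > 1`` the range is split into equal-length contiguous chunks,
    each processed by an independent traversal with its own cumulative
    stack; results are concatenated in id order, so the landscape is
    identical for any worker count.
    """
    n, m = data.n, data.m
    if id_range is None:
        if n > MAX_IN_MEMORY_N:
            raise ValueError(
                f"full screen at n={n} exceeds the in-memory guard "
                f"(n <= {MAX_IN_MEMORY_N}); pass an explicit id_range"
            )
        id_range = IdRange(2, 1 << n)
    if id_range.end > (1 << n):
        raise ValueError(f"id range end {id_range.end} exceeds 2^{n}")
    plan = make_folds(m, r, f, seed)
    fw = featurewise_matrices(data, metric)
    labels = data.labels

    total = len(id_range)
    chunk_count = max(1, min(workers, total))
    if chunk_count == 1:
        chunks = [id_range]
    else:
        base, rem = divmod(total, chunk_count)
        chunks, lo = [], id_range.start
        for c in range(chunk_count):
            size = base + (1 if c < rem else 0)
            chunks.append(IdRange(lo, lo + size - 1))
            lo += size
    if workers == 1:
        parts = [_screen_chunk(fw, labels, k, plan, ch) for ch in chunks]
    else:
        # threads: the feature-wise matrices are shared read-only; every
        # chunk owns its private cumulative stack and fold-index cache
        parts = Parallel(n_jobs=workers, prefer="threads")(
            delayed(_screen_chunk)(
                fw, labels, k,
                FoldPlan(plan.assignments, plan.r, plan.f, plan.seed), ch)
            for ch in chunks
        )
    sizes = np.concatenate([p[0] for p in parts])
    errors = np.concatenate([p[1] for p in parts])
    ids = np.arange(id_range.start, id_range.end + 1, dtype=np.int64)
    return Landscape(ids=ids, sizes=sizes, cv_errors=errors, n=n, m=m, k=k,
                     r=r, f=f, seed=seed,
                     lookup_hits=sum(p[2] for p in parts),
                     lookup_misses=sum(p[3] for p in parts))


def select_best(landscape: Landscape) -> list[int]:
    """All ids attaining the minimal CV error, smallest subsets first.

    Ties are ordered by (subset size ascending, id ascending); the first
    element is the selected signature's id.
    """
    if len(landscape) == 0:
        raise ValueError("empty landscape")
    best = landscape.cv_errors.min()
    mask = landscape.cv_errors == best
    ids = landscape.ids[mask]
    sizes = landscape.sizes[mask]
    order = np.lexsort((ids, sizes))
    return [int(i) for i in ids[order]]


def summarize_landscape(landscape: Landscape,
                        bin_width: float = 0.01) -> LandscapeSummary:
    """Per-size accuracy statistics and mode-normalized histograms."""
    if len(landscape) == 0:
        raise ValueError("empty landscape")
    if not 0.0 < bin_width <= 1.0:
        raise ValueError("bin_width must be in (0, 1]")
    acc = landscape.accuracies
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    edges[-1] = max(edges[-1], 1.0)  # ensure accuracy 1.0 falls in the last bin
    per_size: dict[int, dict] = {}
    for s in np.unique(landscape.sizes):
        a = acc[landscape.sizes == s]
        hist, _ = np.histogram(a, bins=edges)
        mode_bin = int(np.argmax(hist))
        mode = hist[mode_bin]
        per_size[int(s)] = {
            "count": int(a.size),
            "min": float(a.min()),
            "max": float(a.max()),
            "median": float(np.median(a)),
            "hist": (hist / mode).tolist() if mode else hist.tolist(),
            "mode_bin": mode_bin,
        }
    full_id = 1 + landscape.n  # id_from_sig((1..n)) = 1 + n
    where = np.flatnonzero(landscape.ids == full_id)
    better = None
    if where.size:
        full_acc = acc[where[0]]
        better = float(np.mean(acc >= full_acc))
    return LandscapeSummary(per_size=per_size, bin_width=bin_width,
                            bin_edges=edges, better_or_equal=better)


def write_landscape(landscape: Landscape, path) -> None:
    """Dump a landscape as tab-separated text sorted by id."""
    with open(path, "w") as fh:
        fh.write("id\tsignature\tsize\tcv_error\taccuracy\n")
        for i in range(len(landscape)):
            id = int(landscape.ids[i])
            sig = format_signature(sig_from_id(id, landscape.n))
            err = landscape.cv_errors[i]
            fh.write(f"{id}\t{sig}\t{int(landscape.sizes[i])}\t"
                     f"{err:.10g}\t{1.0 - err:.10g}\n")
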