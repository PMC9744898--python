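"""Incremental traversal of the subset enumeration.

Visiting signatures in prefix-first lexicographic order means every
signature appears immediately after a run of its ancestors, so its
cumulative distance matrix is always one matrix addition away from its
parent's (which is resident on a stack of at most ``n`` matrices). Together
with the ``n`` memoized feature-wise matrices, at most ``2n`` matrices are
ever resident, and a full enumeration of the ``2**n - 1`` non-empty subsets
costs one O(m^2) addition per subset — independent of subset size.

A traversal can start at any id: the stack is rebuilt along the parent path
of the starting signature with at most ``n`` additions, which is what makes
arbitrary contiguous id ranges (and hence parallel chunking) possible.

Stack slots are reused in place; the matrix handed to the visit callback is
a view into the stack, valid only for the duration of the callback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .distance import FeaturewiseDistances
from .subsets import Signature, sig_from_id

__all__ = ["IdRange", "TraversalState", "start_state", "traverse", "partition_ids"]

VisitFn = Callable[[int, Signature, np.ndarray], None]


@dataclass(frozen=True)
class IdRange:
    """Inclusive id range within [2, 2**n]; the empty set (id 1) is excluded."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 2 <= self.start <= self.end:
            raise ValueError(f"invalid id range [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1


class TraversalState:
    """Stack of cumulative matrices along the current parent path.

    ``stack_buf[d]`` holds the cumulative matrix of the length-(d+1) prefix
    of the current signature; slots above the current depth are stale and
    are overwritten without zeroing. ``additions`` counts matrix additions
    (a depth-0 copy counts as one); ``peak_depth`` tracks the deepest stack
    use, so peak resident matrices is ``fw.n + peak_depth <= 2n``.
    """

    def __init__(self, fw: FeaturewiseDistances):
        self.fw = fw
        self.stack_buf = np.empty((fw.n, fw.m, fw.m))
        self.sig: list[int] = []
        self.current_id = 1
        self.additions = 0
        self.peak_depth = 0

    @property
    def depth(self) -> int:
        return len(self.sig)

    @property
    def current(self) -> Signature:
        return tuple(self.sig)

    @property
    def top(self) -> np.ndarray:
        """Cumulative matrix of the current signature (in-place view)."""
        return self.stack_buf[self.depth - 1]

    @property
    def peak_resident(self) -> int:
        """Peak number of simultaneously resident matrices (stack + featurewise)."""
        return self.fw.n + self.peak_depth

    def _push(self, i: int) -> None:
        d = self.depth
        single = self.fw.single(i)
        if d == 0:
            np.copyto(self.stack_buf[0], single)
        else:
            np.add(self.stack_buf[d - 1], single, out=self.stack_buf[d])
        self.sig.append(i)
        self.additions += 1
        if self.depth > self.peak_depth:
            self.peak_depth = self.depth

    def advance(self) -> bool:
        """Step to the next signature; False once the enumeration ends.

        Append rule: last index below ``n`` -> push ``last+1`` (one
        addition). Otherwise pop the exhausted branch and replace the new
        last index by its increment (pop twice, push once).
        """
        n = self.fw.n
        last = self.sig[-1]
        if last < n:
            self._push(last + 1)
        else:
            self.sig.pop()
            if not self.sig:
                return False
            nxt = self.sig.pop() + 1
            self._push(nxt)
        self.current_id += 1
        return True


def start_state(start: int, fw: FeaturewiseDistances) -> TraversalState:
    """Position a fresh traversal state at an arbitrary id.

    The cumulative matrices of every prefix of ``sig_from_id(start)`` are
    built bottom-up with at most ``n`` additions.
    """
    n = fw.n
    if not 2 <= start <= (1 << n):
        raise ValueError(f"start id {start} outside [2, {1 << n}]")
    state = TraversalState(fw)
    for i in sig_from_id(start, n):
        state._push(i)
    state.current_id = start
    return state


def traverse(fw: FeaturewiseDistances, id_range: IdRange, visit: VisitFn,
             state: Optional[TraversalState] = None) -> int:
    """Visit every id in ``id_range`` in increasing order.

    ``visit(id, signature, matrix)`` receives the subset's cumulative
    distance matrix as a view that is reused in place; callbacks must copy
    it if they need to retain it. Returns the number of visits.
    """
    n = fw.n
    if id_range.end > (1 << n):
        raise ValueError(f"range end {id_range.end} exceeds 2^{n}")
    if state is None:
        state = start_state(id_range.start, fw)
    count = 0
    while state.current_id <= id_range.end:
        visit(state.current_id, state.current, state.top)
        count += 1
        if not state.advance():
            break
    return count


def partition_ids(n: int, chunks: int) -> list[IdRange]:
    """Split [2, 2**n] into contiguous ranges differing in length by <= 1."""
    if chunks < 1:
        raise ValueError("chunks must be >= 1")
    total = (1 << n) - 1
    chunks = min(chunks, total)
    base, rem = divmod(total, chunks)
    out = []
    lo = 2
    for c in range(chunks):
        size = base + (1 if c < rem else 0)
        out.append(IdRange(lo, lo + size - 1))
        lo += size
    return out
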