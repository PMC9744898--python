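"""Closed-form lookup probabilities and the LOO-based CV error bound.

For a uniformly random f-fold split of ``|S|`` samples, the probability
that all k global nearest neighbors of a held-out sample lie inside the
training folds is

    p_lo = prod_{i=|T|+1}^{|S|-1} (1 - k/i),     |T| = |S| (f-1)/f,

the hypergeometric probability of drawing all k neighbors among the |T|
training slots of the remaining |S|-1 samples. On that event the CV
prediction equals the leave-one-out prediction, which yields the two-sided
bound on the expected CV error under random splits:

    p_lo * R_lo  <=  E[R_cv]  <=  1 + p_lo * (R_lo - 1).

The interval has width 1 - p_lo and collapses to the exact R_lo at
leave-one-out (f = |S|, p_lo = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

__all__ = ["BoundResult", "p_lo", "p_lo_uneven", "expected_lookups",
           "cv_bound", "format_percent"]


@dataclass(frozen=True)
class BoundResult:
    """p_lo together with the induced interval around E[R_cv]."""

    p_lo: float
    lower: float
    upper: float
    r_lo: float


def _train_size(S_size: int, f: int) -> int:
    if not 2 <= f <= S_size:
        raise ValueError(f"folds f={f} outside [2, |S|={S_size}]")
    if S_size % f != 0:
        raise ValueError(
            f"|S|={S_size} not divisible by f={f}; use p_lo_uneven for "
            "uneven folds"
        )
    return S_size * (f - 1) // f


def p_lo(S_size: int, f: int, k: int) -> float:
    """Probability that all k global neighbors land in the training fold.

    Requires ``|S|`` divisible by ``f`` (equal folds, |T| = |S|(f-1)/f).
    Computed as a left-to-right product, which is numerically stable: every
    factor lies in (0, 1].
    """
    T = _train_size(S_size, f)
    if not 1 <= k <= T:
        raise ValueError(f"k={k} outside [1, |T|={T}]")
    prob = 1.0
    for i in range(T + 1, S_size):
        prob *= 1.0 - k / i
    return prob


def p_lo_uneven(fold_sizes: Sequence[int], k: int) -> float:
    """Conservative p_lo when fold sizes are unequal.

    Evaluates the product with each fold's actual training size
    ``|T| = |S| - |fold|`` and returns the minimum over folds — a safe
    lower bound that degrades gracefully when ``|S|`` is not divisible by
    ``f`` (the equal-fold formula is recovered exactly when sizes match).
    """
    sizes = list(fold_sizes)
    S = sum(sizes)
    best = 1.0
    for size in sizes:
        T = S - size
        if not 1 <= k <= T:
            raise ValueError(f"k={k} outside [1, |T|={T}]")
        prob = 1.0
        for i in range(T + 1, S):
            prob *= 1.0 - k / i
        best = min(best, prob)
    return best


def expected_lookups(S_size: int, f: int, k: int) -> float:
    """Expected successful lookups per test sample: k |T| / (|S| - 1).

    The successful-lookup count follows a hypergeometric
    HG(k, |S|-1, |T|); this is its mean.
    """
    T = _train_size(S_size, f)
    if not 1 <= k <= T:
        raise ValueError(f"k={k} outside [1, |T|={T}]")
    return k * T / (S_size - 1)


def cv_bound(r_lo: float, S_size: int, f: int, k: int) -> BoundResult:
    """Interval bound on E[R_cv] from the leave-one-out error ``r_lo``."""
    if not 0.0 <= r_lo <= 1.0:
        raise ValueError(f"r_lo={r_lo} outside [0, 1]")
    p = p_lo(S_size, f, k)
    return BoundResult(p_lo=p, lower=p * r_lo, upper=1.0 + p * (r_lo - 1.0),
                       r_lo=r_lo)


def format_percent(prob: float, decimals: int = 1) -> str:
    """Render a probability in percent, rounding half up (e.g. 0.9184 -> '91.8')."""
    q = Decimal(1).scaleb(-decimals)
    # go through the shortest decimal repr so 0.1205 scales to exactly 12.05
    scaled = Decimal(repr(float(prob))).scaleb(2)
    return str(scaled.quantize(q, rounding=ROUND_HALF_UP))
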