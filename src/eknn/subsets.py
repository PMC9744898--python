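"""Lexicographic subset codec.

The 2**n subsets of ``{1..n}`` are represented as *signatures*: strictly
increasing tuples of 1-based feature indices (the empty tuple is the empty
set). The total order used everywhere is the prefix-first lexicographic
order: a signature precedes every signature it is a proper prefix of, and
otherwise the first differing index decides. Under this order the *parent*
of a signature (drop its last, largest index) always precedes it, which is
what lets a traversal reuse the parent's cumulative distance matrix.

Positions in the enumeration are 1-based *ids*: id 1 is the empty set and
id 2**n is the singleton ``(n,)``. ``sig_from_id`` / ``id_from_sig`` form
the bijection between ids and signatures; both run in O(n).
"""

from __future__ import annotations

from typing import Optional

__all__ = [
    "MAX_FEATURES",
    "Signature",
    "validate_signature",
    "lex_precedes",
    "parent",
    "sig_from_id",
    "id_from_sig",
    "successor",
    "parse_signature",
    "format_signature",
]

# ids are kept in machine integers; 2**62 still fits a signed 64-bit value
MAX_FEATURES = 62

Signature = tuple[int, ...]


def _check_n(n: int) -> None:
    if not 1 <= n <= MAX_FEATURES:
        raise ValueError(f"feature count n={n} outside [1, {MAX_FEATURES}]")


def validate_signature(s: Signature, n: int) -> None:
    """Raise ValueError unless ``s`` is strictly increasing within [1, n]."""
    _check_n(n)
    prev = 0
    for i in s:
        if not prev < i <= n:
            raise ValueError(f"invalid signature {s!r} for n={n}")
        prev = i


def lex_precedes(a: Signature, b: Signature) -> bool:
    """True iff ``a`` strictly precedes ``b`` in the subset order.

    ``a`` precedes ``b`` when ``a`` is a proper prefix of ``b``, or when at
    the first position where they differ ``a`` holds the smaller index.
    """
    la, lb = len(a), len(b)
    for x, y in zip(a, b):
        if x != y:
            return x < y
    return la < lb


def parent(s: Signature) -> Signature:
    """Drop the last (largest) index; the parent in the enumeration tree."""
    if not s:
        raise ValueError("the empty signature has no parent")
    return s[:-1]


def sig_from_id(id: int, n: int) -> Signature:
    """Signature at 1-based position ``id`` in the lexicographic order.

    Iterative form of the stage-wise recursion: at stage ``i``, position 1
    is the current prefix itself (stop), the next ``2**(n-i)`` positions
    form the subtree of signatures whose next index is ``i``, and anything
    beyond skips that subtree (``id -= 2**(n-i)``) and retries with
    ``i+1``; inside the subtree, emit ``i``, step past the subtree root
    (``id -= 1``) and continue with ``i+1``.
    """
    _check_n(n)
    if not 1 <= id <= (1 << n):
        raise ValueError(f"id={id} outside [1, {1 << n}] for n={n}")
    out: list[int] = []
    i = 1
    while id > 1:
        span = 1 << (n - i)
        if id > span + 1:
            id -= span
        else:
            out.append(i)
            id -= 1
        i += 1
    return tuple(out)


def id_from_sig(s: Signature, n: int) -> int:
    """1-based position of ``s`` in the lexicographic order (inverse codec).

    Each entry ``i_p`` contributes 1 (the step into its subtree) plus the
    spans ``2**(n-i)`` of every skipped subtree ``i_{p-1} < i < i_p``.
    """
    validate_signature(s, n)
    pos = 1
    prev = 0
    for ip in s:
        pos += 1
        for i in range(prev + 1, ip):
            pos += 1 << (n - i)
        prev = ip
    return pos


def successor(s: Signature, n: int) -> Optional[Signature]:
    """Lexicographically next signature, or None after the last one.

    Rule: if the last index is below ``n``, append ``last+1``; otherwise
    drop the last index and increment the new last one. The empty signature
    is followed by ``(1,)``; the final signature ``(n,)`` has no successor.
    """
    validate_signature(s, n)
    if not s:
        return (1,)
    last = s[-1]
    if last < n:
        return s + (last + 1,)
    if len(s) == 1:
        return None
    return s[:-2] + (s[-2] + 1,)


def parse_signature(text: str) -> Signature:
    """Parse a comma-separated signature such as ``"2,3"`` ("" is empty)."""
    text = text.strip()
    if not text:
        return ()
    return tuple(int(tok) for tok in text.split(","))


def format_signature(s: Signature) -> str:
    return ",".join(str(i) for i in s)
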