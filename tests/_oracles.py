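"""Independent oracles used by the test suite.

These deliberately avoid the library's own dynamic-programming code
paths: alignment scores come either from explicit enumeration of every
alignment (scored directly from the built rows) or from a separate
last-operation-state recursion; translation expectations come from
expanding every concrete codon combination and translating each with
Biopython.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

GAP = "-"


def score_rows(row_a: str, row_b: str, match_score, go: int, ge: int) -> int:
    """Score a gapped row pair directly: substitution per residue column,
    open + L*extend per maximal gap run."""
    total = 0
    for ca, cb in zip(row_a, row_b):
        if ca != GAP and cb != GAP:
            total += match_score(ca, cb)
    for row in (row_a, row_b):
        run = False
        for ch in row:
            if ch == GAP:
                total += ge + (0 if run else go)
                run = True
            else:
                run = False
    return total


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as a row pair
    (no double-gap columns).  Exponential; keep inputs tiny."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, GAP + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield GAP + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def exhaustive_global_score(a: str, b: str, match_score, go: int, ge: int) -> int:
    """Maximum over explicitly enumerated global alignments."""
    return max(
        score_rows(ra, rb, match_score, go, ge)
        for ra, rb in enumerate_alignments(a, b)
    )


def dp_global_score(a: str, b: str, match_score, go: int, ge: int) -> int:
    """Second, independent affine-score implementation: top-down
    recursion over (i, j, previous op), charging the open on op change."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> int:
        if i == len(a) and j == len(b):
            return 0
        options = []
        if i < len(a) and j < len(b):
            options.append(match_score(a[i], b[j]) + best(i + 1, j + 1, "M"))
        if i < len(a):
            open_cost = 0 if prev == "D" else go
            options.append(open_cost + ge + best(i + 1, j, "D"))
        if j < len(b):
            open_cost = 0 if prev == "I" else go
            options.append(open_cost + ge + best(i, j + 1, "I"))
        return max(options)

    result = best(0, 0, "M")
    best.cache_clear()
    return result


def brute_local_score(a: str, b: str, match_score, go: int, ge: int) -> int:
    """Local score as the maximum over all substring pairs of the global
    affine score, floored at zero (the empty alignment)."""
    best = 0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            sub_a = a[i1:i2]
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = dp_global_score(sub_a, b[j1:j2], match_score, go, ge)
                    if s > best:
                        best = s
    return best


def anchored_bruteforce_score(
    a: str, b: str, anchors, match_score, go: int, ge: int
) -> int:
    """Best global score among alignments pairing a[i] with b[j] for
    every anchor (i, j), by filtering the full enumeration."""
    best = None
    for ra, rb in enumerate_alignments(a, b):
        cols = []
        ia = ib = 0
        for ca, cb in zip(ra, rb):
            cols.append((ia if ca != GAP else None, ib if cb != GAP else None))
            ia += ca != GAP
            ib += cb != GAP
        if all((i, j) in cols for i, j in anchors):
            s = score_rows(ra, rb, match_score, go, ge)
            if best is None or s > best:
                best = s
    return best


def expand_iupac(seq: str, ambiguity: dict[str, str]) -> list[str]:
    """All concrete sequences an IUPAC string denotes."""
    choices = [sorted(ambiguity.get(ch, ch)) for ch in seq]
    return ["".join(parts) for parts in itertools.product(*choices)]
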