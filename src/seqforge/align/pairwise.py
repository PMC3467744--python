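"""Pairwise alignment: global and local affine-gap DP, and a
linear-memory global aligner with optional anchors.

All three aligners share the affine gap model: a gap of length L
costs ``open + L·extend`` (both non-positive), the open charged once
per gap run.  End gaps are penalized in global alignment.  Traceback
is deterministic with tie-break order diagonal > up (gap in the
second sequence) > left.

``align_global`` is the quadratic Gotoh three-state recurrence with
full traceback matrices.  ``align_local`` is the affine-gap
Smith–Waterman variant.  ``align_global_linear`` computes the same
optimal global score using forward/backward passes that keep only two
rows (divide-and-conquer traceback in the style of Myers–Miller), and
accepts user anchors: residue pairs the alignment must align to each
other, which also split the problem into independent sub-alignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence as PySequence

from ..errors import AnchorError, ValidationError
from ..sequence import Sequence
from .matrices import SubstitutionMatrix

__all__ = [
    "GapPenalty",
    "Anchor",
    "PairwiseAlignment",
    "align_global",
    "align_local",
    "align_global_linear",
    "score_alignment",
]

GAP = "-"
_NEG = -(1 << 40)


@dataclass(frozen=True)
class GapPenalty:
    """Affine gap scores: ``open + L·extend`` for a run of length L."""

    open: int = -10
    extend: int = -1

    def __post_init__(self) -> None:
        if self.open > 0 or self.extend > 0:
            raise ValidationError("gap open and extend must be non-positive")


class Anchor(NamedTuple):
    """A residue pair (0-based) the alignment must pass through."""

    i: int
    j: int


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal length with their affine-gap score.

    For local alignments ``starts`` holds the 0-based offsets of the
    aligned substrings within the original sequences.
    """

    rows: tuple[str, str]
    score: int
    starts: tuple[int, int] = (0, 0)
    mode: str = "global"
    ids: tuple[str, str] = ("seq1", "seq2")

    def __post_init__(self) -> None:
        if len(self.rows[0]) != len(self.rows[1]):
            raise ValidationError("alignment rows differ in length")

    def __len__(self) -> int:
        return len(self.rows[0])

    def degap(self, k: int) -> str:
        """Row *k* with gap characters removed."""
        return self.rows[k].replace(GAP, "")

    def column_map(self, k: int) -> list[int | None]:
        """Original 0-based index per column of row *k* (``None`` at gaps)."""
        out: list[int | None] = []
        pos = self.starts[k]
        for ch in self.rows[k]:
            if ch == GAP:
                out.append(None)
            else:
                out.append(pos)
                pos += 1
        return out


def score_alignment(
    row_a: str, row_b: str, matrix: SubstitutionMatrix, gap: GapPenalty
) -> int:
    """Recompute the affine score of a gapped row pair from scratch.

    Substitution scores over residue–residue columns plus
    ``open + L·extend`` per maximal gap run in either row.  Double-gap
    columns are illegal in a pairwise alignment.
    """
    score = 0
    for ca, cb in zip(row_a, row_b):
        if ca == GAP and cb == GAP:
            raise ValidationError("pairwise alignment contains a double-gap column")
        if ca != GAP and cb != GAP:
            score += matrix.score(ca, cb)
    for row in (row_a, row_b):
        in_gap = False
        for ch in row:
            if ch == GAP:
                score += gap.extend + (0 if in_gap else gap.open)
                in_gap = True
            else:
                in_gap = False
    return score


def _check_symbols(a: str, b: str, matrix: SubstitutionMatrix) -> None:
    for ch in set(a) | set(b):
        matrix.score(ch, ch)  # raises ScoringError naming the symbol


def _rows_from_ops(a: str, b: str, ops: PySequence[str]) -> tuple[str, str]:
    ra, rb = [], []
    i = j = 0
    for op in ops:
        if op == "M":
            ra.append(a[i]); rb.append(b[j]); i += 1; j += 1
        elif op == "D":  # consume a, gap in b
            ra.append(a[i]); rb.append(GAP); i += 1
        else:  # "I": gap in a, consume b
            ra.append(GAP); rb.append(b[j]); j += 1
    if i != len(a) or j != len(b):
        raise AssertionError("alignment ops do not cover the inputs")
    return "".join(ra), "".join(rb)


def _gotoh_ops(a, b, sub, go, ge, tb, te):
    """Quadratic three-state DP returning (score, edit ops).

    ``tb``/``te`` replace the gap-open for a vertical run (gap in
    ``b``) starting at the top-left or ending at the bottom-right
    corner — the hook that lets the divide-and-conquer caller represent
    gaps continuing past a subproblem boundary.
    """
    M, N = len(a), len(b)
    if M == 0:
        return (go + N * ge if N else 0), ["I"] * N
    if N == 0:
        return max(tb, te) + M * ge, ["D"] * M

    S = [[_NEG] * (N + 1) for _ in range(M + 1)]
    X = [[_NEG] * (N + 1) for _ in range(M + 1)]
    Y = [[_NEG] * (N + 1) for _ in range(M + 1)]
    Sp = [[""] * (N + 1) for _ in range(M + 1)]
    Xp = [[""] * (N + 1) for _ in range(M + 1)]
    Yp = [[""] * (N + 1) for _ in range(M + 1)]
    S[0][0] = 0
    for i in range(1, M + 1):
        X[i][0] = tb + i * ge
        Xp[i][0] = "S" if i == 1 else "X"
    for j in range(1, N + 1):
        Y[0][j] = go + j * ge
        Yp[0][j] = "S" if j == 1 else "Y"

    for i in range(1, M + 1):
        ai = a[i - 1]
        Si_1, Xi_1, Yi_1 = S[i - 1], X[i - 1], Y[i - 1]
        Si, Xi, Yi = S[i], X[i], Y[i]
        for j in range(1, N + 1):
            best, st = Si_1[j - 1], "S"
            if Xi_1[j - 1] > best:
                best, st = Xi_1[j - 1], "X"
            if Yi_1[j - 1] > best:
                best, st = Yi_1[j - 1], "Y"
            Si[j] = best + sub(ai, b[j - 1])
            Sp[i][j] = st

            best, st = Si_1[j] + go, "S"
            if Xi_1[j] > best:
                best, st = Xi_1[j], "X"
            if Yi_1[j] + go > best:
                best, st = Yi_1[j] + go, "Y"
            Xi[j] = best + ge
            Xp[i][j] = st

            best, st = Si[j - 1] + go, "S"
            if Xi[j - 1] + go > best:
                best, st = Xi[j - 1] + go, "X"
            if Yi[j - 1] > best:
                best, st = Yi[j - 1], "Y"
            Yi[j] = best + ge
            Yp[i][j] = st

    # A vertical run ending exactly at (M, N) opened with `go`; swap in `te`.
    end_candidates = (
        (S[M][N], "S"),
        (X[M][N] + (te - go), "X"),
        (Y[M][N], "Y"),
    )
    score, state = end_candidates[0]
    for val, st in end_candidates[1:]:
        if val > score:
            score, state = val, st

    ops: list[str] = []
    i, j = M, N
    while i > 0 or j > 0:
        if state == "S":
            ops.append("M")
            state = Sp[i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            ops.append("D")
            state = Xp[i][j]
            i -= 1
        else:
            ops.append("I")
            state = Yp[i][j]
            j -= 1
    ops.reverse()
    return score, ops


def align_global(
    s1: Sequence | str,
    s2: Sequence | str,
    matrix: SubstitutionMatrix,
    gap: GapPenalty,
) -> PairwiseAlignment:
    """Optimal global affine-gap alignment (Needleman–Wunsch/Gotoh).

    End gaps are penalized; traceback ties resolve diagonal > up >
    left.  Symbols missing from the matrix raise
    :class:`~seqforge.errors.ScoringError`.
    """
    a, b = str(s1), str(s2)
    _check_symbols(a, b, matrix)
    score, ops = _gotoh_ops(a, b, matrix.score, gap.open, gap.extend, gap.open, gap.open)
    rows = _rows_from_ops(a, b, ops)
    return PairwiseAlignment(rows, score, (0, 0), "global", _ids(s1, s2))


def _ids(s1, s2) -> tuple[str, str]:
    n1 = getattr(s1, "identifier", "") or "seq1"
    n2 = getattr(s2, "identifier", "") or "seq2"
    return (n1, n2)


def align_local(
    s1: Sequence | str,
    s2: Sequence | str,
    matrix: SubstitutionMatrix,
    gap: GapPenalty,
) -> PairwiseAlignment:
    """Optimal local affine-gap alignment (Smith–Waterman).

    Returns the empty alignment with score 0 when no substring pair
    scores positively.  ``starts`` identifies the matched substrings.
    """
    a, b = str(s1), str(s2)
    _check_symbols(a, b, matrix)
    go, ge = gap.open, gap.extend
    M, N = len(a), len(b)
    H = [[0] * (N + 1) for _ in range(M + 1)]
    X = [[_NEG] * (N + 1) for _ in range(M + 1)]
    Y = [[_NEG] * (N + 1) for _ in range(M + 1)]
    Hp = [[""] * (N + 1) for _ in range(M + 1)]
    Xp = [[""] * (N + 1) for _ in range(M + 1)]
    Yp = [[""] * (N + 1) for _ in range(M + 1)]

    best_score, best_pos = 0, None
    for i in range(1, M + 1):
        ai = a[i - 1]
        for j in range(1, N + 1):
            prev, st = H[i - 1][j - 1], "H"
            if X[i - 1][j - 1] > prev:
                prev, st = X[i - 1][j - 1], "X"
            if Y[i - 1][j - 1] > prev:
                prev, st = Y[i - 1][j - 1], "Y"
            val = prev + matrix.score(ai, b[j - 1])
            if val > 0:
                # a zero-score H predecessor is an empty alignment:
                # starting fresh here is equivalent and ends traceback
                if st == "H" and H[i - 1][j - 1] == 0:
                    st = "0"
                H[i][j], Hp[i][j] = val, st
            else:
                H[i][j], Hp[i][j] = 0, "0"

            bestx, st = H[i - 1][j] + go, "H"
            if X[i - 1][j] > bestx:
                bestx, st = X[i - 1][j], "X"
            if Y[i - 1][j] + go > bestx:
                bestx, st = Y[i - 1][j] + go, "Y"
            X[i][j], Xp[i][j] = bestx + ge, st

            besty, st = H[i][j - 1] + go, "H"
            if X[i][j - 1] + go > besty:
                besty, st = X[i][j - 1] + go, "X"
            if Y[i][j - 1] > besty:
                besty, st = Y[i][j - 1], "Y"
            Y[i][j], Yp[i][j] = besty + ge, st

            if H[i][j] > best_score:
                best_score, best_pos = H[i][j], (i, j)

    if best_pos is None:
        return PairwiseAlignment(("", ""), 0, (0, 0), "local", _ids(s1, s2))

    ops: list[str] = []
    i, j = best_pos
    state = "H"
    while True:
        if state == "H":
            pred = Hp[i][j]
            ops.append("M")
            i, j = i - 1, j - 1
            if pred == "0":
                break
            state = pred
        elif state == "X":
            pred = Xp[i][j]
            ops.append("D")
            i -= 1
            state = pred
        else:
            pred = Yp[i][j]
            ops.append("I")
            j -= 1
            state = pred
    ops.reverse()
    rows = _rows_from_ops(a[i : best_pos[0]], b[j : best_pos[1]], ops)
    return PairwiseAlignment(rows, best_score, (i, j), "local", _ids(s1, s2))


def _linear_pass(a, b, sub, go, ge, tb):
    """Forward Gotoh over ``a`` keeping one row: returns (CC, DD) where
    CC[j] is the best any-state score of aligning ``a`` with ``b[:j]``
    and DD[j] the best ending in a vertical-gap (gap-in-``b``) state."""
    N = len(b)
    S = [_NEG] * (N + 1)
    X = [_NEG] * (N + 1)
    Y = [_NEG] * (N + 1)
    S[0] = 0
    for j in range(1, N + 1):
        Y[j] = go + j * ge
    for i in range(1, len(a) + 1):
        ai = a[i - 1]
        diagS, diagX, diagY = S[0], X[0], Y[0]
        S[0], X[0], Y[0] = _NEG, tb + i * ge, _NEG
        for j in range(1, N + 1):
            curS = sub(ai, b[j - 1]) + max(diagS, diagX, diagY)
            curX = ge + max(S[j] + go, X[j], Y[j] + go)
            curY = ge + max(S[j - 1] + go, X[j - 1] + go, Y[j - 1])
            diagS, diagX, diagY = S[j], X[j], Y[j]
            S[j], X[j], Y[j] = curS, curX, curY
    CC = [max(S[j], X[j], Y[j]) for j in range(N + 1)]
    return CC, X[:]


# Sub-problems at or below this area are solved by the quadratic DP.
_BLOCK = 1024


def _mm_ops(a, b, sub, go, ge, tb, te):
    """Divide-and-conquer optimal global path in linear memory.

    Splits at the middle row of ``a``; the crossing is either at a
    node (type 1) or inside a vertical gap run spanning the split
    (type 2, which adds back the doubly-charged gap open).
    """
    M, N = len(a), len(b)
    if M == 0:
        return ["I"] * N
    if N == 0:
        return ["D"] * M
    if M <= 2 or N <= 2 or M * N <= _BLOCK:
        return _gotoh_ops(a, b, sub, go, ge, tb, te)[1]

    imid = M // 2
    CC, DD = _linear_pass(a[:imid], b, sub, go, ge, tb)
    CC2, DD2 = _linear_pass(a[imid:][::-1], b[::-1], sub, go, ge, te)
    RR = CC2[::-1]
    SS = DD2[::-1]

    best_val, best_j, best_type = None, 0, 1
    for j in range(N + 1):
        t1 = CC[j] + RR[j]
        if best_val is None or t1 > best_val:
            best_val, best_j, best_type = t1, j, 1
        t2 = DD[j] + SS[j] - go
        if t2 > best_val:
            best_val, best_j, best_type = t2, j, 2

    if best_type == 1:
        return (
            _mm_ops(a[:imid], b[:best_j], sub, go, ge, tb, go)
            + _mm_ops(a[imid:], b[best_j:], sub, go, ge, go, te)
        )
    # type 2: the vertical run covers rows imid-1 and imid at least;
    # neighbouring sub-paths may extend it without re-opening (flag 0).
    return (
        _mm_ops(a[: imid - 1], b[:best_j], sub, go, ge, tb, 0)
        + ["D", "D"]
        + _mm_ops(a[imid + 1 :], b[best_j:], sub, go, ge, 0, te)
    )


def linear_global_score(
    s1: Sequence | str,
    s2: Sequence | str,
    matrix: SubstitutionMatrix,
    gap: GapPenalty,
) -> int:
    """Global affine score in memory linear in the second sequence."""
    a, b = str(s1), str(s2)
    _check_symbols(a, b, matrix)
    if len(a) == 0:
        return gap.open + len(b) * gap.extend if b else 0
    if len(b) == 0:
        return gap.open + len(a) * gap.extend
    CC, _ = _linear_pass(a, b, matrix.score, gap.open, gap.extend, gap.open)
    return CC[len(b)]


def _validate_anchors(anchors, M: int, N: int) -> list[Anchor]:
    out: list[Anchor] = []
    prev = Anchor(-1, -1)
    for raw in anchors:
        anc = Anchor(*raw)
        if not (0 <= anc.i < M and 0 <= anc.j < N):
            raise AnchorError(
                f"anchor {tuple(anc)} out of range for lengths ({M}, {N})"
            )
        if anc.i <= prev.i or anc.j <= prev.j:
            raise AnchorError(
                f"anchors must be strictly increasing in both coordinates; "
                f"{tuple(prev)} then {tuple(anc)}"
            )
        out.append(anc)
        prev = anc
    return out


def align_global_linear(
    s1: Sequence | str,
    s2: Sequence | str,
    matrix: SubstitutionMatrix,
    gap: GapPenalty,
    anchors: PySequence[tuple[int, int]] = (),
) -> PairwiseAlignment:
    """Linear-memory global alignment, optionally through anchors.

    Without anchors the score is identical to :func:`align_global`.
    Each anchor ``(i, j)`` forces ``s1[i]`` to align against ``s2[j]``;
    anchors partition the problem into independently solved segments
    (exact, since an anchored column interrupts any gap run).  The
    result is optimal among alignments through every anchor, hence its
    score never exceeds the unanchored optimum.
    """
    a, b = str(s1), str(s2)
    _check_symbols(a, b, matrix)
    ancs = _validate_anchors(anchors, len(a), len(b))
    sub, go, ge = matrix.score, gap.open, gap.extend
    ops: list[str] = []
    pi = pj = 0
    for anc in ancs:
        ops += _mm_ops(a[pi : anc.i], b[pj : anc.j], sub, go, ge, go, go)
        ops.append("M")
        pi, pj = anc.i + 1, anc.j + 1
    ops += _mm_ops(a[pi:], b[pj:], sub, go, ge, go, go)
    rows = _rows_from_ops(a, b, ops)
    score = score_alignment(rows[0], rows[1], matrix, gap) if rows[0] or rows[1] else 0
    return PairwiseAlignment(rows, score, (0, 0), "global", _ids(s1, s2))
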