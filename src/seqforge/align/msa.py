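"""Progressive multiple sequence alignment.

The classic recipe: all-against-all global alignments give fractional
identities, ``d = 1 − identity`` gives a distance matrix, UPGMA gives
a rooted guide tree, and profiles are merged up the tree by
profile–profile affine-gap DP with sum-of-pairs column scoring.  Gaps
inserted into a profile are propagated, never removed ("once a gap,
always a gap").

The stored MSA score is the sum-of-pairs score recomputed from the
emitted rows: for every unordered row pair the pairwise projection
(double-gap columns dropped) is scored with the substitution matrix
and the affine model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence as PySequence

import numpy as np

from ..errors import ValidationError
from ..sequence import Sequence
from .matrices import SubstitutionMatrix
from .pairwise import GAP, GapPenalty, align_global, score_alignment

__all__ = [
    "GuideTreeNode",
    "Msa",
    "distance_matrix",
    "build_guide_tree",
    "progressive_msa",
    "sp_score",
]


@dataclass(frozen=True)
class GuideTreeNode:
    """Node of a rooted UPGMA tree; leaves carry the input index."""

    height: float
    index: int | None = None
    left: "GuideTreeNode | None" = None
    right: "GuideTreeNode | None" = None
    leaves: tuple[int, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return self.index is not None

    def newick(self, names: PySequence[str] | None = None) -> str:
        def render(node: GuideTreeNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                label = names[node.index] if names else f"seq{node.index}"
                return f"{label}:{length:g}"
            inner = ",".join(render(c, node.height) for c in (node.left, node.right))
            return f"({inner}):{length:g}"

        if self.is_leaf:
            return f"{(names[self.index] if names else f'seq{self.index}')};"
        inner = ",".join(render(c, self.height) for c in (self.left, self.right))
        return f"({inner});"


@dataclass(frozen=True)
class Msa:
    """Gapped rows (one per input, input order), guide tree and score."""

    rows: tuple[str, ...]
    ids: tuple[str, ...]
    score: int
    tree: GuideTreeNode | None = None

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValidationError("MSA rows differ in length")

    def __len__(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degap(self, k: int) -> str:
        return self.rows[k].replace(GAP, "")


def distance_matrix(
    seqs: PySequence[Sequence | str],
    matrix: SubstitutionMatrix,
    gap: GapPenalty,
) -> np.ndarray:
    """Pairwise distances ``1 − fractional identity`` from global
    alignments; symmetric with a zero diagonal."""
    n = len(seqs)
    if n < 2:
        raise ValidationError("need at least 2 sequences")
    d = np.zeros((n, n), dtype=float)
    for i, j in combinations(range(n), 2):
        aln = align_global(seqs[i], seqs[j], matrix, gap)
        cols = len(aln)
        same = sum(
            1
            for ca, cb in zip(aln.rows[0], aln.rows[1])
            if ca != GAP and cb != GAP and ca == cb
        )
        d[i, j] = d[j, i] = 1.0 - same / cols if cols else 0.0
    return d


def build_guide_tree(d: np.ndarray) -> GuideTreeNode:
    """UPGMA (average linkage) agglomeration of a distance matrix.

    Deterministic: ties pick the lowest cluster-index pair (clusters
    numbered in creation order, leaves first), and the child holding
    the smallest input index becomes the left child.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    n = d.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 leaves")

    nodes: dict[int, GuideTreeNode] = {
        i: GuideTreeNode(0.0, index=i, leaves=(i,)) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    active = sorted(nodes)
    while len(active) > 1:
        best = min(dist[(i, j)] for i, j in combinations(active, 2))
        i, j = next(
            (i, j) for i, j in combinations(active, 2) if dist[(i, j)] == best
        )
        left, right = nodes[i], nodes[j]
        if min(right.leaves) < min(left.leaves):
            left, right = right, left
        node = GuideTreeNode(
            best / 2.0,
            left=left,
            right=right,
            leaves=left.leaves + right.leaves,
        )
        nodes[next_id] = node
        sizes[next_id] = sizes[i] + sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(k, next_id)] = (sizes[i] * dik + sizes[j] * djk) / (
                sizes[i] + sizes[j]
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        active.sort()
        next_id += 1
    return nodes[active[0]]


def _profile_columns(rows: list[str]) -> list[dict[str, int]]:
    cols = []
    for k in range(len(rows[0])):
        counts: dict[str, int] = {}
        for row in rows:
            ch = row[k]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        cols.append(counts)
    return cols


def _profile_align(
    rows_a: list[str],
    rows_b: list[str],
    matrix: SubstitutionMatrix,
    gap: GapPenalty,
) -> tuple[list[str], list[str]]:
    """Affine profile–profile DP; sum-of-pairs column scores, gap
    penalties scaled by the number of row pairs affected."""
    cols_a = _profile_columns(rows_a)
    cols_b = _profile_columns(rows_b)
    na, nb = len(rows_a), len(rows_b)
    mult = na * nb
    go, ge = gap.open * mult, gap.extend * mult
    score = matrix.score

    def sub(ca: dict[str, int], cb: dict[str, int]) -> int:
        total = 0
        for sa, na_ in ca.items():
            for sb, nb_ in cb.items():
                total += na_ * nb_ * score(sa, sb)
        return total

    from .pairwise import _gotoh_ops  # same recurrence, column-valued

    _, ops = _gotoh_ops(cols_a, cols_b, sub, go, ge, go, go)

    out_a = [[] for _ in range(na)]
    out_b = [[] for _ in range(nb)]
    i = j = 0
    for op in ops:
        if op in ("M", "D"):
            for k in range(na):
                out_a[k].append(rows_a[k][i])
            i += 1
        else:
            for k in range(na):
                out_a[k].append(GAP)
        if op in ("M", "I"):
            for k in range(nb):
                out_b[k].append(rows_b[k][j])
            j += 1
        else:
            for k in range(nb):
                out_b[k].append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def sp_score(
    rows: PySequence[str], matrix: SubstitutionMatrix, gap: GapPenalty
) -> int:
    """Sum-of-pairs score of MSA rows under the affine model.

    Each unordered row pair is projected (double-gap columns dropped)
    and scored like a pairwise alignment.
    """
    total = 0
    for ra, rb in combinations(rows, 2):
        pa, pb = [], []
        for ca, cb in zip(ra, rb):
            if ca == GAP and cb == GAP:
                continue
            pa.append(ca)
            pb.append(cb)
        if pa:
            total += score_alignment("".join(pa), "".join(pb), matrix, gap)
    return total


def progressive_msa(
    seqs: PySequence[Sequence | str],
    matrix: SubstitutionMatrix,
    gap: GapPenalty,
) -> Msa:
    """Align ≥2 sequences progressively up a UPGMA guide tree.

    With exactly two sequences the result is the optimal pairwise
    global alignment.  Rows are returned in input order; the stored
    score is :func:`sp_score` of the rows.
    """
    n = len(seqs)
    if n < 2:
        raise ValidationError("need at least 2 sequences")
    ids = tuple(
        (getattr(s, "identifier", "") or f"seq{i + 1}") for i, s in enumerate(seqs)
    )
    texts = [str(s) for s in seqs]

    d = distance_matrix(seqs, matrix, gap)
    tree = build_guide_tree(d)

    if n == 2:
        aln = align_global(seqs[0], seqs[1], matrix, gap)
        return Msa(aln.rows, ids, aln.score, tree)

    def merge(node: GuideTreeNode) -> tuple[list[str], list[int]]:
        if node.is_leaf:
            return [texts[node.index]], [node.index]
        rows_a, idx_a = merge(node.left)
        rows_b, idx_b = merge(node.right)
        new_a, new_b = _profile_align(rows_a, rows_b, matrix, gap)
        return new_a + new_b, idx_a + idx_b

    rows, order = merge(tree)
    width = len(rows[0])
    keep = [k for k in range(width) if any(r[k] != GAP for r in rows)]
    if len(keep) != width:  # defensive: no merge step should create these
        rows = ["".join(r[k] for k in keep) for r in rows]
    by_input = [rows[order.index(i)] for i in range(n)]
    return Msa(tuple(by_input), ids, sp_score(by_input, matrix, gap), tree)
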