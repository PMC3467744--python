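"""Substitution matrices in NCBI text format.

BLOSUM62 (protein, half-bit scores) and NUC.4.4 (IUPAC nucleotides,
+5/−4 with ambiguity-averaged entries) ship as package data; any
matrix in the same layout — ``#`` comments, a header row of symbols,
one labelled row per symbol — can be read with
:func:`read_substitution_matrix`.  Matrices must be symmetric and
total over their symbol set.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from os import PathLike
from typing import Iterable

from ..errors import FormatError, ScoringError

__all__ = ["SubstitutionMatrix", "read_substitution_matrix", "load_matrix"]

_BUNDLED = {"blosum62": "BLOSUM62.txt", "nuc.4.4": "NUC.4.4.txt", "nuc44": "NUC.4.4.txt"}


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric integer scoring matrix over a symbol set."""

    name: str
    symbols: tuple[str, ...]
    scores: dict[tuple[str, str], int]

    def score(self, a: str, b: str) -> int:
        try:
            return self.scores[(a, b)]
        except KeyError:
            missing = a if (a, a) not in self.scores else b
            raise ScoringError(
                f"symbol {missing!r} has no entry in matrix {self.name!r}"
            ) from None

    @classmethod
    def match_mismatch(
        cls,
        match: int,
        mismatch: int,
        symbols: Iterable[str] = "ACGT",
        name: str | None = None,
    ) -> "SubstitutionMatrix":
        """Uniform match/mismatch matrix, handy for nucleotide work."""
        syms = tuple(symbols)
        scores = {
            (a, b): (match if a == b else mismatch) for a in syms for b in syms
        }
        return cls(name or f"match{match}/mismatch{mismatch}", syms, scores)


def read_substitution_matrix(source, name: str = "") -> SubstitutionMatrix:
    """Parse an NCBI-format matrix; rejects missing cells and asymmetry."""
    if isinstance(source, (str, PathLike)):
        with open(source, "r", encoding="ascii") as fh:
            text = fh.read()
        name = name or str(source)
    else:
        text = source.read()
    lines = [
        ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise FormatError("empty substitution matrix")
    header = tuple(lines[0].split())
    if len(lines) - 1 != len(header):
        raise FormatError(
            f"matrix has {len(header)} header symbols but {len(lines) - 1} rows"
        )
    scores: dict[tuple[str, str], int] = {}
    for row_no, line in enumerate(lines[1:]):
        fields = line.split()
        if len(fields) != len(header) + 1:
            raise FormatError(
                f"row {fields[0] if fields else '?'}: expected "
                f"{len(header) + 1} fields, found {len(fields)}"
            )
        row_sym = fields[0]
        if row_sym != header[row_no]:
            raise FormatError(
                f"row label {row_sym!r} does not match header symbol "
                f"{header[row_no]!r}"
            )
        for col_sym, cell in zip(header, fields[1:]):
            try:
                scores[(row_sym, col_sym)] = int(cell)
            except ValueError:
                raise FormatError(
                    f"non-integer score {cell!r} at ({row_sym}, {col_sym})"
                ) from None
    for a in header:
        for b in header:
            if scores[(a, b)] != scores[(b, a)]:
                raise FormatError(
                    f"asymmetric entries: ({a},{b})={scores[(a, b)]} but "
                    f"({b},{a})={scores[(b, a)]}"
                )
    return SubstitutionMatrix(name or "matrix", header, scores)


def load_matrix(name: str) -> SubstitutionMatrix:
    """Load a bundled matrix by name (``blosum62`` or ``nuc.4.4``)."""
    key = name.lower()
    if key not in _BUNDLED:
        raise ScoringError(
            f"no bundled matrix {name!r}; available: blosum62, nuc.4.4"
        )
    text = resources.files("seqforge.align.data").joinpath(_BUNDLED[key]).read_text()
    return read_substitution_matrix(io.StringIO(text), name=name.upper())
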