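"""Alignment output: aligned FASTA and CLUSTAL.

Aligned FASTA writes one gapped record per row and round-trips through
:func:`read_alignment_fasta`.  CLUSTAL output is interleaved in
60-column blocks.  Duplicate row names are disambiguated with a
numeric suffix (a warning is logged) since CLUSTAL identifies rows by
name.
"""

from __future__ import annotations

import io
import logging
from os import PathLike

from .msa import Msa
from .pairwise import PairwiseAlignment

__all__ = ["write_alignment", "read_alignment_fasta"]

logger = logging.getLogger(__name__)

_WIDTH = 60


def _rows_and_names(aln) -> tuple[list[str], list[str]]:
    if isinstance(aln, (PairwiseAlignment, Msa)):
        rows = list(aln.rows)
        names = list(aln.ids)
    else:
        raise TypeError(f"cannot write alignment of type {type(aln).__name__}")
    seen: dict[str, int] = {}
    unique = []
    for name in names:
        if name in seen:
            seen[name] += 1
            new = f"{name}_{seen[name]}"
            logger.warning("duplicate row name %r renamed to %r", name, new)
            unique.append(new)
        else:
            seen[name] = 1
            unique.append(name)
    return rows, unique


def write_alignment(aln, format: str = "fasta", dest=None) -> str | None:
    """Serialise a pairwise alignment or MSA as ``fasta`` or ``clustal``."""
    rows, names = _rows_and_names(aln)
    buf = io.StringIO()
    if format == "fasta":
        for name, row in zip(names, rows):
            buf.write(f">{name}\n")
            for k in range(0, len(row), _WIDTH):
                buf.write(row[k : k + _WIDTH] + "\n")
    elif format == "clustal":
        buf.write("CLUSTAL multiple sequence alignment\n\n")
        pad = max((len(n) for n in names), default=0) + 3
        width = len(rows[0]) if rows else 0
        for start in range(0, width, _WIDTH):
            for name, row in zip(names, rows):
                buf.write(f"{name:<{pad}}{row[start:start + _WIDTH]}\n")
            buf.write("\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    out = buf.getvalue()
    if dest is None:
        return out
    if isinstance(dest, (str, PathLike)):
        with open(dest, "w", encoding="ascii") as fh:
            fh.write(out)
    else:
        dest.write(out)
    return None


def read_alignment_fasta(source) -> list[tuple[str, str]]:
    """Read aligned FASTA back as ``(name, gapped_row)`` pairs."""
    if isinstance(source, (str, PathLike)):
        with open(source, "r", encoding="ascii") as fh:
            text = fh.read()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = source
    out: list[tuple[str, str]] = []
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                out.append((name, "".join(chunks)))
            name = line[1:].split()[0] if line[1:].strip() else ""
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        out.append((name, "".join(chunks)))
    return out
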