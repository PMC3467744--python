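"""FASTA reading and writing, eager and indexed-lazy.

:func:`read_fasta` loads records into memory.  :func:`open_fasta_lazy`
scans the file once to build a byte-offset index and returns sequences
whose symbols are read from disk on demand — the file-backed
implementation of the proxy-storage contract.  Both expose identical
observable behaviour; the lazy path validates symbols on first access
instead of up front.
"""

from __future__ import annotations

import io
from bisect import bisect_right
from os import PathLike
from typing import Iterable, TextIO

from ..alphabet import DNA, PROTEIN, RNA, Alphabet
from ..errors import FormatError, ValidationError
from ..sequence import Sequence, make_sequence

__all__ = ["read_fasta", "write_fasta", "open_fasta_lazy", "guess_alphabet"]


def guess_alphabet(symbols: str) -> Alphabet:
    """Smallest standard alphabet containing the symbols (DNA → RNA → protein)."""
    seen = set(symbols.upper())
    for alphabet in (DNA, RNA, PROTEIN):
        if seen <= alphabet.symbols:
            return alphabet
    bad = sorted(seen - PROTEIN.symbols)
    raise ValidationError(f"symbols {bad} fit no standard alphabet")


def _as_text_stream(source) -> TextIO:
    if isinstance(source, (str, PathLike)):
        return open(source, "r", encoding="ascii")
    return source


def read_fasta(source, alphabet: Alphabet | None = None) -> list[Sequence]:
    """Parse FASTA records eagerly, preserving order.

    The identifier is the header token up to the first whitespace; the
    remainder is the description.  Wrapped sequence lines are
    concatenated.  When *alphabet* is ``None`` each record's alphabet
    is guessed (DNA, then RNA, then protein).
    """
    stream = _as_text_stream(source)
    records: list[tuple[str, str, list[str], int]] = []
    current: tuple[str, str, list[str], int] | None = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith(">"):
            header = line[1:].strip()
            ident, _, desc = header.partition(" ")
            current = (ident, desc.strip(), [], lineno)
            records.append(current)
        else:
            if current is None:
                raise FormatError(
                    "expected FASTA header ('>') before sequence data",
                    line=lineno,
                )
            current[2].append(line.strip())
    out = []
    for ident, desc, chunks, _ in records:
        symbols = "".join(chunks)
        ab = alphabet or guess_alphabet(symbols)
        out.append(make_sequence(symbols, ab, ident, desc))
    return out


def write_fasta(records: Iterable[Sequence], dest=None, width: int = 60) -> str | None:
    """Write records as FASTA, wrapping sequence lines at *width* columns.

    With ``dest=None`` the text is returned; otherwise it is written to
    the given path or stream.
    """
    buf = io.StringIO()
    for rec in records:
        header = rec.identifier or "sequence"
        if rec.description:
            header += f" {rec.description}"
        buf.write(f">{header}\n")
        text = str(rec)
        for i in range(0, len(text), width):
            buf.write(text[i : i + width] + "\n")
        if not text:
            pass  # header-only record: no body lines
    out = buf.getvalue()
    if dest is None:
        return out
    if isinstance(dest, (str, PathLike)):
        with open(dest, "w", encoding="ascii") as fh:
            fh.write(out)
    else:
        dest.write(out)
    return None


class _IndexedFastaStorage:
    """File-backed storage for one FASTA record.

    Holds a per-line index ``(sequence_start, byte_offset, length)``;
    symbol reads seek into the file and validate lazily against the
    alphabet.  Reads are deterministic and never load more than the
    requested window.
    """

    def __init__(self, path, lines: list[tuple[int, int, int]], length: int, alphabet: Alphabet):
        self._path = path
        self._lines = lines
        self._length = length
        self._alphabet = alphabet
        self._starts = [ln[0] for ln in lines]
        self._handle = None

    def _file(self):
        if self._handle is None:
            self._handle = open(self._path, "r", encoding="ascii")
        return self._handle

    def __len__(self) -> int:
        return self._length

    def slice(self, start: int, end: int) -> str:
        if not (0 <= start <= end <= self._length):
            raise IndexError(
                f"slice [{start}, {end}) out of range for length {self._length}"
            )
        if start == end:
            return ""
        fh = self._file()
        parts: list[str] = []
        idx = bisect_right(self._starts, start) - 1
        pos = start
        while pos < end:
            seq_start, offset, length = self._lines[idx]
            take_from = pos - seq_start
            take_to = min(length, end - seq_start)
            fh.seek(offset + take_from)
            parts.append(fh.read(take_to - take_from))
            pos = seq_start + take_to
            idx += 1
        text = "".join(parts).upper()
        for k, ch in enumerate(text):
            if ch not in self._alphabet:
                raise ValidationError(
                    f"symbol {ch!r} at position {start + k} is not in "
                    f"alphabet {self._alphabet.name!r}"
                )
        return text

    def symbol_at(self, index: int) -> str:
        return self.slice(index, index + 1)


def open_fasta_lazy(path, alphabet: Alphabet = DNA) -> list[Sequence]:
    """Index a FASTA file and return lazily file-backed sequences.

    One pass over the file records byte offsets; no sequence data is
    retained.  Symbols are read (and validated) only when accessed, so
    opening a large file costs only the index.  Format errors are
    raised during indexing, matching :func:`read_fasta`.
    """
    records: list[Sequence] = []
    ident = desc = ""
    lines: list[tuple[int, int, int]] = []
    seq_len = 0
    in_record = False

    def finish():
        nonlocal lines, seq_len
        storage = _IndexedFastaStorage(path, lines, seq_len, alphabet)
        records.append(Sequence(storage, alphabet, ident, desc))
        lines, seq_len = [], 0

    with open(path, "r", encoding="ascii") as fh:
        lineno = 0
        while True:
            offset = fh.tell()
            raw = fh.readline()
            if not raw:
                break
            lineno += 1
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(">"):
                if in_record:
                    finish()
                header = line[1:].strip()
                ident, _, desc = header.partition(" ")
                desc = desc.strip()
                in_record = True
            else:
                if not in_record:
                    raise FormatError(
                        "expected FASTA header ('>') before sequence data",
                        line=lineno,
                    )
                stripped = line.strip()
                lead = line.index(stripped[0]) if stripped else 0
                lines.append((seq_len, offset + lead, len(stripped)))
                seq_len += len(stripped)
        if in_record:
            finish()
    return records
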