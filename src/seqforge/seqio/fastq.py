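"""Streaming FASTQ I/O for the three historical quality encodings.

Variants
--------
``sanger``
    Phred qualities, ASCII offset 33, legal range 0–93.
``solexa``
    Solexa odds-based qualities, offset 64, range −5–62.
``illumina13``
    Phred qualities as produced by Illumina pipeline 1.3+, offset 64,
    range 0–62.

The variant is always explicit — offset ranges overlap, so guessing
silently corrupts qualities.  Conversion between Phred and Solexa
scales uses the exact logistic relations

    Q_phred  = 10·log10(10^(Q_solexa/10) + 1)
    Q_solexa = 10·log10(10^(Q_phred/10) − 1)   (Q_phred = 0 → −5)

with rounding to the nearest integer (ties away from zero) and
clamping to the target range.  Sanger ↔ Illumina-1.3 conversion is a
pure offset re-encoding of identical Phred values.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Iterator

from ..alphabet import DNA
from ..errors import FormatError, ValidationError
from ..sequence import Sequence, make_sequence

__all__ = ["FastqVariant", "VARIANTS", "FastqRecord", "read_fastq", "write_fastq", "convert_fastq"]


@dataclass(frozen=True)
class FastqVariant:
    name: str
    offset: int
    qmin: int
    qmax: int
    solexa_scale: bool


VARIANTS: dict[str, FastqVariant] = {
    "sanger": FastqVariant("sanger", 33, 0, 93, False),
    "solexa": FastqVariant("solexa", 64, -5, 62, True),
    "illumina13": FastqVariant("illumina13", 64, 0, 62, False),
}


def _variant(tag: str | FastqVariant) -> FastqVariant:
    if isinstance(tag, FastqVariant):
        return tag
    try:
        return VARIANTS[tag]
    except KeyError:
        raise ValidationError(
            f"unknown FASTQ variant {tag!r}; known: {sorted(VARIANTS)}"
        ) from None


@dataclass(frozen=True)
class FastqRecord:
    """One read: identifier, DNA sequence and per-base quality integers
    on the scale of *variant*."""

    identifier: str
    sequence: Sequence
    qualities: tuple[int, ...]
    variant: str = "sanger"
    description: str = ""

    def __post_init__(self) -> None:
        v = _variant(self.variant)
        if len(self.qualities) != len(self.sequence):
            raise ValidationError(
                f"record {self.identifier!r}: {len(self.qualities)} qualities "
                f"for {len(self.sequence)} bases"
            )
        for pos, q in enumerate(self.qualities):
            if not v.qmin <= q <= v.qmax:
                raise ValidationError(
                    f"record {self.identifier!r}: quality {q} at position "
                    f"{pos} outside {v.name} range [{v.qmin}, {v.qmax}]"
                )


def read_fastq(source, variant: str | FastqVariant = "sanger") -> Iterator[FastqRecord]:
    """Stream records from 4-line FASTQ; constant memory in record count.

    Decodes qualities as ``ord(char) − offset`` for the given variant
    and rejects values outside its legal range, truncated records, and
    sequence/quality length mismatches.
    """
    v = _variant(variant)
    own = isinstance(source, (str, PathLike))
    stream = open(source, "r", encoding="ascii") if own else source
    try:
        lineno = 0
        while True:
            head = stream.readline()
            if not head:
                return
            lineno += 1
            head = head.rstrip("\n").rstrip("\r")
            if not head.strip():
                continue
            if not head.startswith("@"):
                raise FormatError("expected '@' record header", line=lineno)
            ident, _, desc = head[1:].partition(" ")
            seq_raw = stream.readline()
            plus_raw = stream.readline()
            qual_raw = stream.readline()
            if not plus_raw or not qual_raw:
                raise FormatError(f"truncated record {ident!r}", line=lineno)
            seq_line = seq_raw.rstrip("\n").rstrip("\r")
            plus = plus_raw.rstrip("\n").rstrip("\r")
            qual_line = qual_raw.rstrip("\n").rstrip("\r")
            lineno += 3
            if not plus.startswith("+"):
                raise FormatError(
                    f"record {ident!r}: expected '+' separator", line=lineno - 1
                )
            if len(plus) > 1 and plus[1:] != head[1:]:
                raise FormatError(
                    f"record {ident!r}: '+' line repeats a different id",
                    line=lineno - 1,
                )
            if len(qual_line) != len(seq_line):
                raise FormatError(
                    f"record {ident!r}: sequence length {len(seq_line)} != "
                    f"quality length {len(qual_line)}",
                    line=lineno,
                )
            quals = []
            for pos, ch in enumerate(qual_line):
                q = ord(ch) - v.offset
                if not v.qmin <= q <= v.qmax:
                    raise FormatError(
                        f"record {ident!r}: quality character {ch!r} at "
                        f"position {pos} outside {v.name} range",
                        line=lineno,
                    )
                quals.append(q)
            yield FastqRecord(
                ident,
                make_sequence(seq_line, DNA, ident, desc),
                tuple(quals),
                v.name,
                desc,
            )
    finally:
        if own:
            stream.close()


def write_fastq(
    records: Iterable[FastqRecord], variant: str | FastqVariant = "sanger", dest=None
) -> str | None:
    """Encode records in the given variant; same-variant round trips are
    byte-exact.  Records on a different scale must be converted first."""
    v = _variant(variant)
    buf = io.StringIO()
    for rec in records:
        if rec.variant != v.name:
            raise ValidationError(
                f"record {rec.identifier!r} carries {rec.variant} qualities; "
                f"convert_fastq to {v.name} before writing"
            )
        for pos, q in enumerate(rec.qualities):
            if not v.qmin <= q <= v.qmax:
                raise ValidationError(
                    f"record {rec.identifier!r}: quality {q} at position {pos} "
                    f"out of range for {v.name}"
                )
        head = rec.identifier + (f" {rec.description}" if rec.description else "")
        buf.write(f"@{head}\n{rec.sequence}\n+\n")
        buf.write("".join(chr(q + v.offset) for q in rec.qualities) + "\n")
    out = buf.getvalue()
    if dest is None:
        return out
    if isinstance(dest, (str, PathLike)):
        with open(dest, "w", encoding="ascii") as fh:
            fh.write(out)
    else:
        dest.write(out)
    return None


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def solexa_to_phred(q: float) -> float:
    """Exact Solexa(odds) → Phred(probability) quality mapping."""
    return 10.0 * math.log10(10.0 ** (q / 10.0) + 1.0)


def phred_to_solexa(q: float) -> float:
    """Exact Phred → Solexa mapping; Q_phred = 0 maps to the Solexa floor −5."""
    if q <= 0:
        return -5.0
    return 10.0 * math.log10(10.0 ** (q / 10.0) - 1.0)


def convert_fastq(record: FastqRecord, target: str | FastqVariant) -> FastqRecord:
    """Re-encode a record's qualities on another variant's scale.

    Phred-scaled variants interconvert by offset only; Solexa
    conversions go through the exact logistic mapping.  Results are
    rounded to the nearest integer (ties away from zero) and clamped
    to the target's legal range.
    """
    src = _variant(record.variant)
    tgt = _variant(target)
    if src.name == tgt.name:
        return record
    out = []
    for q in record.qualities:
        val = float(q)
        if src.solexa_scale:
            val = solexa_to_phred(val)
        if tgt.solexa_scale:
            val = phred_to_solexa(val)
        v = _round_half_away(val)
        out.append(min(tgt.qmax, max(tgt.qmin, v)))
    return FastqRecord(
        record.identifier, record.sequence, tuple(out), tgt.name, record.description
    )
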