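"""GFF3 / GTF / GFF2 feature parsing, GFF3 writing and spliced-sequence
extraction.

Features keep the 1-based inclusive coordinates of the file format;
conversion to the toolkit's internal 0-based half-open convention
happens only where sequence is actually extracted
(:func:`extract_spliced`).

GFF3 ``ID``/``Parent`` attributes are resolved into object links after
parsing; GTF and GFF2 attribute syntax (``key "value";``) is parsed
into the same attribute map, with unknown constructs preserved as raw
text values.  GFF3 is the only dialect written.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable

from ..errors import ConsistencyError, FormatError, ValidationError
from ..sequence import Sequence, reverse_complement, subsequence

__all__ = ["Feature", "read_gff", "write_gff3", "extract_spliced"]

_DIALECTS = ("gff3", "gtf", "gff2")
# GFF3 reserved characters that must be percent-escaped in attribute values.
_ESCAPE = {";", "=", "&", ",", "%", "\t", "\n", "\r"}


@dataclass
class Feature:
    """One GFF line: a located, typed annotation with attributes.

    ``start``/``end`` are 1-based inclusive (``start <= end`` on both
    strands, per the GFF3 rule).  ``attributes`` maps each key to the
    list of its values in file order; ``parents`` holds resolved links
    for GFF3 ``Parent`` references.
    """

    seqid: str
    source: str
    type: str
    start: int
    end: int
    score: float | None = None
    strand: str = "."
    phase: int | None = None
    attributes: dict[str, list[str]] = field(default_factory=dict)
    parents: list["Feature"] = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"feature {self.type} has start {self.start} > end {self.end}"
            )
        if self.strand not in "+-.?":
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def id(self) -> str | None:
        values = self.attributes.get("ID")
        return values[0] if values else None


def _unescape(text: str) -> str:
    def sub(m: re.Match) -> str:
        return chr(int(m.group(1), 16))

    return re.sub(r"%([0-9A-Fa-f]{2})", sub, text)


def _escape(text: str) -> str:
    return "".join(
        f"%{ord(c):02X}" if c in _ESCAPE or ord(c) < 0x20 else c for c in text
    )


def _parse_attributes_gff3(text: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, eq, value = chunk.partition("=")
        if not eq:  # malformed pair: keep raw
            attrs.setdefault(chunk, [])
            continue
        values = [_unescape(v) for v in value.split(",")]
        attrs.setdefault(key.strip(), []).extend(values)
    return attrs


_GTF_PAIR = re.compile(r'^\s*(\S+)\s+"([^"]*)"\s*$')


def _parse_attributes_gtf(text: str) -> dict[str, list[str]]:
    attrs: dict[str, list[str]] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = _GTF_PAIR.match(chunk)
        if m:
            attrs.setdefault(m.group(1), []).append(m.group(2))
            continue
        key, _, value = chunk.partition(" ")
        # unknown construct: preserved as raw attribute text
        attrs.setdefault(key, []).append(value.strip().strip('"'))
    return attrs


def read_gff(source, dialect: str = "gff3") -> list[Feature]:
    """Parse features from a GFF3, GTF or GFF2 stream or path.

    Comment lines (``#``) are skipped; an embedded ``##FASTA`` section
    ends parsing.  Wrong column counts raise
    :class:`~seqforge.errors.FormatError` with the line number.  For
    GFF3, ``Parent`` references are resolved into ``Feature.parents``.
    """
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; known: {_DIALECTS}")
    own = isinstance(source, (str, PathLike))
    stream = open(source, "r", encoding="utf-8") if own else source
    features: list[Feature] = []
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("##FASTA"):
                    break
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(
                    f"expected 9 tab-separated columns, found {len(cols)}",
                    line=lineno,
                )
            seqid, src, ftype, start, end, score, strand, phase, attr_text = cols
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise FormatError(
                    f"non-integer coordinates {start!r}/{end!r}", line=lineno
                ) from None
            if start_i > end_i:
                raise FormatError(
                    f"start {start_i} > end {end_i}", line=lineno
                )
            score_v = None if score == "." else float(score)
            phase_v = None if phase == "." else int(phase)
            if dialect == "gff3":
                attrs = _parse_attributes_gff3(attr_text)
            else:
                attrs = _parse_attributes_gtf(attr_text)
            features.append(
                Feature(seqid, src, ftype, start_i, end_i, score_v, strand, phase_v, attrs)
            )
    finally:
        if own:
            stream.close()

    if dialect == "gff3":
        by_id: dict[str, Feature] = {}
        for f in features:
            if f.id is not None:
                by_id.setdefault(f.id, f)
        for f in features:
            for pid in f.attributes.get("Parent", []):
                parent = by_id.get(pid)
                if parent is not None:
                    f.parents.append(parent)
    return features


def write_gff3(features: Iterable[Feature], dest=None) -> str | None:
    """Serialise features as GFF3 (the only write dialect).

    Emits the ``##gff-version 3`` header and percent-escapes reserved
    characters in attribute values.  A ``CDS`` feature without a phase
    is rejected, as GFF3 requires phase on CDS lines.
    """
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for f in features:
        if f.type == "CDS" and f.phase is None:
            raise ValidationError(
                f"CDS feature at {f.seqid}:{f.start}-{f.end} requires a phase"
            )
        score = "." if f.score is None else format(f.score, "g")
        phase = "." if f.phase is None else str(f.phase)
        attrs = ";".join(
            f"{key}={','.join(_escape(v) for v in values)}" if values else key
            for key, values in f.attributes.items()
        )
        buf.write(
            "\t".join(
                (
                    f.seqid,
                    f.source,
                    f.type,
                    str(f.start),
                    str(f.end),
                    score,
                    f.strand,
                    phase,
                    attrs,
                )
            )
            + "\n"
        )
    out = buf.getvalue()
    if dest is None:
        return out
    if isinstance(dest, (str, PathLike)):
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(out)
    else:
        dest.write(out)
    return None


def extract_spliced(features: Iterable[Feature], genome: Sequence) -> Sequence:
    """Concatenate exon/CDS segments into the spliced sequence.

    All features must share one seqid and one definite strand and must
    not overlap.  Segments are sorted by start, converted to 0-based
    half-open, concatenated, and reverse-complemented for the minus
    strand.
    """
    feats = sorted(features, key=lambda f: f.start)
    if not feats:
        raise ConsistencyError("no features to splice")
    seqids = {f.seqid for f in feats}
    strands = {f.strand for f in feats}
    if len(seqids) > 1:
        raise ConsistencyError(f"features span multiple seqids: {sorted(seqids)}")
    if len(strands) > 1 or not strands <= {"+", "-"}:
        raise ConsistencyError(
            f"features must share one definite strand, got {sorted(strands)}"
        )
    for prev, nxt in zip(feats, feats[1:]):
        if nxt.start <= prev.end:
            raise ConsistencyError(
                f"overlapping segments {prev.start}-{prev.end} and "
                f"{nxt.start}-{nxt.end}"
            )
    if feats[-1].end > len(genome):
        raise ConsistencyError(
            f"segment end {feats[-1].end} beyond genome length {len(genome)}"
        )
    spliced = "".join(
        str(subsequence(genome, f.start - 1, f.end)) for f in feats
    )
    from ..sequence import make_sequence

    joined = make_sequence(spliced, genome.alphabet)
    if feats[0].strand == "-":
        joined = reverse_complement(joined)
    return joined
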