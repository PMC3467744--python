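"""The translation engine: transcription, codon-table translation with
reading frames, start-codon conversion, stop trimming and IUPAC
ambiguity handling.

Codon tables follow the NCBI genetic-code numbering; tables 1
(standard), 2 (vertebrate mitochondrial) and 11 (bacterial/archaeal/
plant plastid) ship built in, and any table can be constructed from a
codon→amino-acid map.  Internally every sequence is normalised to RNA
codons before lookup, so DNA and RNA inputs translate identically.

A codon containing degeneracy codes is expanded over all concrete
codons it denotes: if every expansion encodes the same amino acid that
amino acid is emitted (``CGN`` → ``R``); if the expansions disagree an
``X`` is emitted; a codon whose expansions are all stops is a stop.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .alphabet import DNA, PROTEIN, RNA
from .errors import ValidationError
from .sequence import Sequence, StringStorage, make_sequence

__all__ = [
    "CodonTable",
    "TranslationOptions",
    "get_table",
    "transcribe",
    "back_transcribe",
    "translate",
    "six_frame_translate",
    "FRAMES",
]

STOP = "*"
_BASES = "UCAG"
#: The six reading frames: sign selects the strand, magnitude the offset.
FRAMES = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class CodonTable:
    """An NCBI-style genetic code: 64 codon→amino-acid rules plus starts.

    ``forward`` maps every concrete RNA codon to an amino-acid symbol or
    ``'*'``; ``starts`` is the set of initiation codons (each of which
    must itself encode an amino acid).
    """

    id: int
    name: str
    forward: dict[str, str]
    starts: frozenset[str]

    def __post_init__(self) -> None:
        expected = {a + b + c for a in _BASES for b in _BASES for c in _BASES}
        if set(self.forward) != expected:
            raise ValidationError(
                f"codon table {self.id}: forward map must cover exactly the "
                "64 concrete RNA codons"
            )
        if not self.starts:
            raise ValidationError(f"codon table {self.id}: empty start-codon set")
        for codon in self.starts:
            if self.forward.get(codon, STOP) == STOP:
                raise ValidationError(
                    f"codon table {self.id}: start codon {codon} does not "
                    "encode an amino acid"
                )


def _table(tid: int, name: str, aa64: str, starts_dna: tuple[str, ...]) -> CodonTable:
    codons = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
    forward = dict(zip(codons, aa64))
    starts = frozenset(s.replace("T", "U") for s in starts_dna)
    return CodonTable(tid, name, forward, starts)


# Amino-acid strings in TCAG codon order (base1 slowest), per the NCBI
# genetic-code tables.
_STANDARD_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_VERT_MITO_AA = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"

TABLES: dict[int, CodonTable] = {
    1: _table(1, "Standard", _STANDARD_AA, ("TTG", "CTG", "ATG")),
    2: _table(
        2,
        "Vertebrate Mitochondrial",
        _VERT_MITO_AA,
        ("ATT", "ATC", "ATA", "ATG", "GTG"),
    ),
    11: _table(
        11,
        "Bacterial, Archaeal and Plant Plastid",
        _STANDARD_AA,
        ("TTG", "CTG", "ATT", "ATC", "ATA", "ATG", "GTG"),
    ),
}


def get_table(table: int | CodonTable) -> CodonTable:
    """Resolve a table id (or pass a table through)."""
    if isinstance(table, CodonTable):
        return table
    try:
        return TABLES[table]
    except KeyError:
        raise ValidationError(
            f"unknown codon table id {table}; built-in tables: "
            f"{sorted(TABLES)}"
        ) from None


@dataclass(frozen=True)
class TranslationOptions:
    """Knobs of the translation engine.

    frame: one of ±1, ±2, ±3 — sign selects the strand, magnitude the
    0/1/2 offset.  ``init_met`` rewrites the first codon of the frame to
    methionine when it is an initiation codon of the table.
    ``trim_stop`` truncates the product at the first stop; otherwise
    stops appear as ``'*'``.  Incomplete trailing codons are dropped.
    """

    table: int | CodonTable = 1
    frame: int = 1
    init_met: bool = False
    trim_stop: bool = False

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValidationError(f"frame must be one of {FRAMES}, got {self.frame}")


def transcribe(s: Sequence) -> Sequence:
    """DNA → RNA on the coding strand: replace T with U."""
    if s.alphabet is not DNA and s.alphabet != DNA:
        raise ValidationError("transcribe expects a DNA sequence")
    rna = str(s).replace("T", "U")
    return Sequence(StringStorage(rna, RNA), RNA, s.identifier, s.description)


def back_transcribe(s: Sequence) -> Sequence:
    """RNA → DNA: replace U with T; exact inverse of :func:`transcribe`."""
    if s.alphabet is not RNA and s.alphabet != RNA:
        raise ValidationError("back_transcribe expects an RNA sequence")
    dna = str(s).replace("U", "T")
    return Sequence(StringStorage(dna, DNA), DNA, s.identifier, s.description)


def _codon_product(codon: str, alphabet) -> list[str]:
    sets = [sorted(alphabet.expand(ch)) for ch in codon]
    return ["".join(bases) for bases in itertools.product(*sets)]


def _translate_codon(codon: str, table: CodonTable) -> str:
    aa = table.forward.get(codon)
    if aa is not None:
        return aa
    seen = {table.forward[c] for c in _codon_product(codon, RNA)}
    if len(seen) == 1:
        return seen.pop()
    return "X"


def translate(
    s: Sequence,
    options: TranslationOptions | None = None,
    *,
    table: int | CodonTable = 1,
    frame: int = 1,
    init_met: bool = False,
    trim_stop: bool = False,
) -> Sequence:
    """Translate a DNA or RNA sequence to protein.

    Either pass a :class:`TranslationOptions` or the individual keyword
    arguments.  Negative frames translate the reverse complement.
    Short or empty input yields the empty protein.
    """
    opts = options or TranslationOptions(
        table=table, frame=frame, init_met=init_met, trim_stop=trim_stop
    )
    tab = get_table(opts.table)

    if s.alphabet == DNA:
        rna = str(s).replace("T", "U")
    elif s.alphabet == RNA:
        rna = str(s)
    else:
        raise ValidationError("translate expects a DNA or RNA sequence")

    if opts.frame < 0:
        rna = "".join(RNA.complement_symbol(ch) for ch in reversed(rna))
    offset = abs(opts.frame) - 1

    aas: list[str] = []
    first = True
    for i in range(offset, len(rna) - 2, 3):
        codon = rna[i : i + 3]
        if first and opts.init_met and codon in tab.starts:
            aas.append("M")
        else:
            aas.append(_translate_codon(codon, tab))
        first = False

    protein = "".join(aas)
    if opts.trim_stop:
        stop_at = protein.find(STOP)
        if stop_at >= 0:
            protein = protein[:stop_at]
    return make_sequence(protein, PROTEIN, s.identifier, s.description)


def six_frame_translate(
    s: Sequence, table: int | CodonTable = 1
) -> dict[int, Sequence]:
    """Translate all six reading frames; keys are +1, +2, +3, -1, -2, -3.

    Frame −k equals translating the reverse complement at offset k−1.
    """
    return {
        f: translate(s, TranslationOptions(table=table, frame=f)) for f in FRAMES
    }
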