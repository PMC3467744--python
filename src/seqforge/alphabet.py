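"""Alphabets: named, finite symbol sets with complement and ambiguity rules.

An :class:`Alphabet` knows three things about its symbols:

* membership — which single upper-case characters are legal;
* complementation — a partial, involutive symbol map (defined for
  nucleotide alphabets, absent for amino acids);
* ambiguity — the expansion of each IUPAC degeneracy code into the set
  of concrete symbols it stands for (``R`` → ``{A, G}``, ``N`` → all
  four bases).  Concrete symbols expand to themselves.

The three standard alphabets (:data:`DNA`, :data:`RNA`, :data:`PROTEIN`)
are module-level singletons; user-defined alphabets are ordinary
instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnsupportedOperationError, ValidationError

__all__ = ["Alphabet", "DNA", "RNA", "PROTEIN"]


@dataclass(frozen=True)
class Alphabet:
    """A named set of single-character symbols with optional structure.

    Parameters
    ----------
    name:
        Human-readable identifier (``"dna"``, ``"protein"`` ...).
    symbols:
        The full legal symbol set, upper case.
    complement:
        Partial map symbol → complementary symbol.  Must be an
        involution where defined.
    ambiguity:
        Map symbol → non-empty frozenset of *concrete* symbols.
        Symbols absent from the map are concrete (expand to themselves).
    """

    name: str
    symbols: frozenset[str]
    complement: dict[str, str] = field(default_factory=dict)
    ambiguity: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.symbols:
            if len(s) != 1 or s != s.upper():
                raise ValidationError(
                    f"alphabet {self.name!r}: symbol {s!r} is not a single "
                    "upper-case character"
                )
        for a, b in self.complement.items():
            if self.complement.get(b) != a:
                raise ValidationError(
                    f"alphabet {self.name!r}: complement is not an involution "
                    f"at {a!r}→{b!r}"
                )
        concrete = self.concrete_symbols()
        for a, expansion in self.ambiguity.items():
            if not expansion or not expansion <= concrete:
                raise ValidationError(
                    f"alphabet {self.name!r}: ambiguity expansion of {a!r} "
                    "is empty or not a subset of the concrete symbols"
                )

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def concrete_symbols(self) -> frozenset[str]:
        """Symbols that are not degeneracy codes."""
        return frozenset(s for s in self.symbols if s not in self.ambiguity)

    def expand(self, symbol: str) -> frozenset[str]:
        """Concrete symbols a (possibly ambiguous) symbol stands for."""
        if symbol not in self.symbols:
            raise ValidationError(
                f"symbol {symbol!r} not in alphabet {self.name!r}"
            )
        return self.ambiguity.get(symbol, frozenset((symbol,)))

    def complement_symbol(self, symbol: str) -> str:
        if not self.complement:
            raise UnsupportedOperationError(
                f"alphabet {self.name!r} has no complement rules"
            )
        try:
            return self.complement[symbol]
        except KeyError:
            raise ValidationError(
                f"no complement defined for symbol {symbol!r} in alphabet "
                f"{self.name!r}"
            ) from None

    def has_complement(self) -> bool:
        return bool(self.complement)


def _nucleotide_tables(t: str) -> tuple[dict[str, str], dict[str, frozenset[str]]]:
    # IUPAC nucleotide degeneracy codes; `t` is "T" for DNA, "U" for RNA.
    comp = {
        "A": t, t: "A", "C": "G", "G": "C",
        "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
        "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    }
    amb = {
        "R": frozenset("AG"), "Y": frozenset({"C", t}),
        "S": frozenset("CG"), "W": frozenset({"A", t}),
        "K": frozenset({"G", t}), "M": frozenset("AC"),
        "B": frozenset({"C", "G", t}), "D": frozenset({"A", "G", t}),
        "H": frozenset({"A", "C", t}), "V": frozenset("ACG"),
        "N": frozenset({"A", "C", "G", t}),
    }
    return comp, amb


_DNA_COMP, _DNA_AMB = _nucleotide_tables("T")
_RNA_COMP, _RNA_AMB = _nucleotide_tables("U")

#: IUPAC DNA alphabet (4 bases + 11 degeneracy codes).
DNA = Alphabet("dna", frozenset("ACGTRYSWKMBDHVN"), _DNA_COMP, _DNA_AMB)

#: IUPAC RNA alphabet.
RNA = Alphabet("rna", frozenset("ACGURYSWKMBDHVN"), _RNA_COMP, _RNA_AMB)

_AA20 = "ARNDCQEGHILKMFPSTWYV"

#: Amino-acid alphabet: the 20 standard residues, selenocysteine (U),
#: pyrrolysine (O), the ambiguity codes B/Z/J/X and the stop symbol '*'.
PROTEIN = Alphabet(
    "protein",
    frozenset(_AA20 + "UOBZJX*"),
    {},
    {
        "B": frozenset("DN"),
        "Z": frozenset("EQ"),
        "J": frozenset("IL"),
        "X": frozenset(_AA20),
    },
)
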