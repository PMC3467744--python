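"""The sequence data model: immutable symbol strings over an alphabet,
backed by a pluggable storage provider.

A :class:`Sequence` never owns its characters directly; it reads them
through a :class:`StorageProvider`.  The provider shipped here for
in-memory data is :class:`StringStorage`; ``seqforge.seqio.fasta``
provides a file-backed provider that defers reading until a symbol is
actually accessed (the "proxy" storage concept).  Two sequences over
the same alphabet compare equal whenever their symbol strings are
equal, regardless of backend.

Coordinates are 0-based and half-open throughout.
"""

from __future__ import annotations

from collections import Counter
from typing import Protocol, runtime_checkable

from .alphabet import Alphabet
from .errors import ValidationError

__all__ = [
    "StorageProvider",
    "StringStorage",
    "SliceStorage",
    "Sequence",
    "make_sequence",
    "reverse_complement",
    "subsequence",
    "composition",
]


@runtime_checkable
class StorageProvider(Protocol):
    """Contract for sequence backends.

    Implementations must be deterministic: repeated reads of the same
    index return the same symbol, and ``slice(i, j)`` equals the
    concatenation of ``symbol_at(i) .. symbol_at(j-1)``.
    """

    def __len__(self) -> int: ...

    def symbol_at(self, index: int) -> str: ...

    def slice(self, start: int, end: int) -> str: ...


class StringStorage:
    """Eager in-memory backend; validates against the alphabet up front."""

    def __init__(self, symbols: str, alphabet: Alphabet):
        symbols = symbols.upper()
        for pos, ch in enumerate(symbols):
            if ch not in alphabet:
                raise ValidationError(
                    f"symbol {ch!r} at position {pos} is not in alphabet "
                    f"{alphabet.name!r}"
                )
        self._symbols = symbols

    def __len__(self) -> int:
        return len(self._symbols)

    def symbol_at(self, index: int) -> str:
        return self._symbols[index]

    def slice(self, start: int, end: int) -> str:
        return self._symbols[start:end]


class SliceStorage:
    """Zero-copy view of a window of another provider.

    Used by :func:`subsequence` so that slicing a lazy file-backed
    sequence stays lazy.
    """

    def __init__(self, parent: StorageProvider, start: int, end: int):
        if not (0 <= start <= end <= len(parent)):
            raise IndexError(
                f"slice [{start}, {end}) out of range for length {len(parent)}"
            )
        self._parent = parent
        self._start = start
        self._length = end - start

    def __len__(self) -> int:
        return self._length

    def symbol_at(self, index: int) -> str:
        return self._parent.symbol_at(self._start + index)

    def slice(self, start: int, end: int) -> str:
        return self._parent.slice(self._start + start, self._start + end)


class Sequence:
    """An immutable symbol string over an :class:`Alphabet`.

    Equality is value-based: equal symbols and equal alphabet, whatever
    the storage backend.
    """

    __slots__ = ("alphabet", "storage", "identifier", "description")

    def __init__(
        self,
        storage: StorageProvider,
        alphabet: Alphabet,
        identifier: str = "",
        description: str = "",
    ):
        self.storage = storage
        self.alphabet = alphabet
        self.identifier = identifier
        self.description = description

    def __len__(self) -> int:
        return len(self.storage)

    def __iter__(self):
        return iter(str(self))

    def __getitem__(self, key):
        if isinstance(key, slice):
            start, stop, step = key.indices(len(self))
            if step != 1:
                raise ValidationError("sequences do not support strided slicing")
            return subsequence(self, start, stop)
        n = len(self)
        if key < 0:
            key += n
        if not 0 <= key < n:
            raise IndexError(f"index {key} out of range for length {n}")
        return self.storage.symbol_at(key)

    def __str__(self) -> str:
        return self.storage.slice(0, len(self))

    def __repr__(self) -> str:
        s = str(self)
        shown = s if len(s) <= 40 else s[:37] + "..."
        ident = f" id={self.identifier!r}" if self.identifier else ""
        return f"<Sequence {self.alphabet.name}{ident} {shown!r} len={len(s)}>"

    def __eq__(self, other) -> bool:
        if not isinstance(other, Sequence):
            return NotImplemented
        return self.alphabet == other.alphabet and str(self) == str(other)

    def __hash__(self) -> int:
        return hash((self.alphabet.name, str(self)))

    def with_identifier(self, identifier: str, description: str = "") -> "Sequence":
        return Sequence(self.storage, self.alphabet, identifier, description)


def make_sequence(
    symbols: str,
    alphabet: Alphabet,
    identifier: str = "",
    description: str = "",
) -> Sequence:
    """Build an eager in-memory sequence, validating every symbol.

    Input is case-insensitive; storage is upper-case canonical.  An
    unknown character raises :class:`~seqforge.errors.ValidationError`
    naming the symbol and its 0-based position.
    """
    return Sequence(StringStorage(symbols, alphabet), alphabet, identifier, description)


def reverse_complement(s: Sequence) -> Sequence:
    """Reverse-complement a nucleotide sequence.

    Defined for any alphabet with complement rules (all IUPAC DNA/RNA
    codes complement); applying it twice returns the original value.
    Raises :class:`~seqforge.errors.UnsupportedOperationError` for
    alphabets without complements (e.g. protein).
    """
    comp = s.alphabet.complement_symbol
    flipped = "".join(comp(ch) for ch in reversed(str(s)))
    return Sequence(
        StringStorage(flipped, s.alphabet), s.alphabet, s.identifier, s.description
    )


def subsequence(s: Sequence, start: int, end: int) -> Sequence:
    """View of ``s[start:end)`` sharing the parent's storage.

    Works identically on eager and file-backed sequences; raises
    ``IndexError`` if ``0 <= start <= end <= len(s)`` does not hold.
    """
    if not (0 <= start <= end <= len(s)):
        raise IndexError(
            f"subsequence [{start}, {end}) out of range for length {len(s)}"
        )
    return Sequence(SliceStorage(s.storage, start, end), s.alphabet, s.identifier)


def composition(s: Sequence) -> dict[str, float]:
    """Fraction of each observed symbol; empty map for the empty sequence."""
    text = str(s)
    if not text:
        return {}
    n = len(text)
    return {sym: count / n for sym, count in sorted(Counter(text).items())}
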