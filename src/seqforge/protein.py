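"""Peptide physicochemical property calculators.

Seven properties: molecular weight (average or monoisotopic, with
user-configurable residue-mass overrides for isotope labels and PTMs),
extinction coefficient at 280 nm, instability index, aliphatic index,
GRAVY, isoelectric point (with the underlying net-charge model) and
amino-acid composition.

Constant tables
---------------
Residue masses follow the Expasy/ProtParam residue-mass convention
(peptide mass = Σ residue masses + one water).  Hydropathy is the
Kyte–Doolittle scale.  The instability index uses the Guruprasad
dipeptide weights (:mod:`seqforge._diwv`).  The extinction
coefficients are the Gill–von Hippel values (Trp 5500, Tyr 1490,
cystine 125 M⁻¹cm⁻¹).  Ionisable-group pKas default to the
Bjellqvist-style set used by common pI calculators; the whole pKa set
is swappable data, not code, because published sets disagree and pI
shifts with them.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from xml.etree import ElementTree

from ._diwv import DIWV
from .alphabet import PROTEIN
from .errors import ConfigError, ValidationError
from .sequence import Sequence, composition, make_sequence

__all__ = [
    "PkaSet",
    "PropertyTables",
    "ResidueOverride",
    "DEFAULT_TABLES",
    "EMBOSS_PKA",
    "molecular_weight",
    "extinction_coefficient",
    "instability_index",
    "is_stable",
    "aliphatic_index",
    "gravy",
    "net_charge",
    "isoelectric_point",
    "aa_composition",
    "load_residue_overrides",
]

logger = logging.getLogger(__name__)

_STANDARD = "ARNDCQEGHILKMFPSTWYV"
_AMBIGUOUS = set("BZJX")

# Expasy residue masses, Daltons: (average, monoisotopic).
_RESIDUE_MASSES: dict[str, tuple[float, float]] = {
    "A": (71.0788, 71.03711),
    "R": (156.1875, 156.10111),
    "N": (114.1038, 114.04293),
    "D": (115.0886, 115.02694),
    "C": (103.1388, 103.00919),
    "E": (129.1155, 129.04259),
    "Q": (128.1307, 128.05858),
    "G": (57.0519, 57.02146),
    "H": (137.1411, 137.05891),
    "I": (113.1594, 113.08406),
    "L": (113.1594, 113.08406),
    "K": (128.1741, 128.09496),
    "M": (131.1926, 131.04049),
    "F": (147.1766, 147.06841),
    "P": (97.1167, 97.05276),
    "S": (87.0782, 87.03203),
    "T": (101.1051, 101.04768),
    "W": (186.2132, 186.07931),
    "Y": (163.1760, 163.06333),
    "V": (99.1326, 99.06841),
    # selenocysteine and pyrrolysine
    "U": (150.0379, 150.95364),
    "O": (237.2981, 237.14773),
}

_WATER = (18.0153, 18.010565)

# Kyte & Doolittle (1982) hydropathy.
_KD: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass(frozen=True)
class PkaSet:
    """pKa values of the ionisable groups; signs: N-term/H/K/R basic,
    C-term/D/E/C/Y acidic."""

    name: str
    nterm: float
    cterm: float
    side_chains: dict[str, float]  # keys among D, E, C, Y, H, K, R

    @property
    def positive(self) -> dict[str, float]:
        return {k: v for k, v in self.side_chains.items() if k in "HKR"}

    @property
    def negative(self) -> dict[str, float]:
        return {k: v for k, v in self.side_chains.items() if k in "DECY"}


#: Bjellqvist-style set (as used by common pI calculators); the default.
BJELLQVIST_PKA = PkaSet(
    "bjellqvist",
    nterm=7.5,
    cterm=3.55,
    side_chains={"K": 10.0, "R": 12.0, "H": 5.98, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
)

#: EMBOSS iep defaults, provided as an alternative.
EMBOSS_PKA = PkaSet(
    "emboss",
    nterm=8.6,
    cterm=3.6,
    side_chains={"K": 10.8, "R": 12.5, "H": 6.5, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
)

# Gill & von Hippel (1989) molar extinction coefficients at 280 nm.
_EXTINCTION = {"W": 5500, "Y": 1490, "cystine": 125}


@dataclass(frozen=True)
class PropertyTables:
    """The bundle of per-residue constants the calculators read."""

    residue_masses: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_RESIDUE_MASSES)
    )
    water: tuple[float, float] = _WATER
    hydropathy: dict[str, float] = field(default_factory=lambda: dict(_KD))
    diwv: dict[str, dict[str, float]] = field(default_factory=lambda: DIWV)
    pka: PkaSet = BJELLQVIST_PKA
    extinction: dict[str, int] = field(default_factory=lambda: dict(_EXTINCTION))

    def with_pka(self, pka: PkaSet) -> "PropertyTables":
        return replace(self, pka=pka)


DEFAULT_TABLES = PropertyTables()


@dataclass(frozen=True)
class ResidueOverride:
    """Replacement masses for every occurrence of a residue symbol.

    Used for isotope labels (e.g. SILAC heavy lysine) and
    post-translational modifications; affects mass calculations only.
    """

    target: str
    average: float
    monoisotopic: float
    label: str = ""


def _as_text(p: Sequence | str) -> str:
    return str(p).upper()


def molecular_weight(
    p: Sequence | str,
    scale: str = "average",
    overrides: list[ResidueOverride] = (),
    tables: PropertyTables = DEFAULT_TABLES,
) -> float:
    """Peptide mass in Daltons: Σ residue masses + one water.

    ``scale`` is ``"average"`` or ``"monoisotopic"``.  Overrides
    replace the table mass for every occurrence of their target symbol
    (later overrides win).  Symbols without a mass — ambiguity codes
    and anything not covered by the tables or an override — are
    errors: a silently wrong mass is worse than a failure.
    """
    text = _as_text(p)
    if not text:
        raise ValidationError("molecular weight of an empty peptide is undefined")
    if scale not in ("average", "monoisotopic"):
        raise ValidationError(f"unknown mass scale {scale!r}")
    col = 0 if scale == "average" else 1
    masses = {sym: pair[col] for sym, pair in tables.residue_masses.items()}
    for ov in overrides:
        masses[ov.target.upper()] = ov.average if col == 0 else ov.monoisotopic
    total = tables.water[col]
    for ch in text:
        try:
            total += masses[ch]
        except KeyError:
            raise ValidationError(f"no mass defined for residue {ch!r}") from None
    return total


def extinction_coefficient(
    p: Sequence | str,
    cystines_formed: bool = False,
    tables: PropertyTables = DEFAULT_TABLES,
) -> int:
    """Molar extinction coefficient at 280 nm (M⁻¹cm⁻¹).

    ε = nTrp·5500 + nTyr·1490, plus 125 per cystine (⌊nCys/2⌋ pairs)
    when ``cystines_formed``.
    """
    text = _as_text(p)
    eps = text.count("W") * tables.extinction["W"]
    eps += text.count("Y") * tables.extinction["Y"]
    if cystines_formed:
        eps += (text.count("C") // 2) * tables.extinction["cystine"]
    return eps


def instability_index(
    p: Sequence | str, tables: PropertyTables = DEFAULT_TABLES
) -> float:
    """Guruprasad instability index: (10/L)·Σ DIWV over adjacent pairs.

    Defined for length ≥ 2 over standard residues; a value below 40
    conventionally classifies the protein as stable.
    """
    text = _as_text(p)
    if len(text) < 2:
        raise ValidationError("instability index requires length >= 2")
    total = 0.0
    for x, y in zip(text, text[1:]):
        try:
            total += tables.diwv[x][y]
        except KeyError:
            bad = x if x not in tables.diwv else y
            raise ValidationError(
                f"no instability weight for residue {bad!r}"
            ) from None
    return 10.0 / len(text) * total


def is_stable(p: Sequence | str, tables: PropertyTables = DEFAULT_TABLES) -> bool:
    """Companion classification: stable iff instability index < 40."""
    return instability_index(p, tables) < 40.0


def aliphatic_index(p: Sequence | str) -> float:
    """Ikai aliphatic index: X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu),
    with X in mole percent of the full sequence length.

    Ambiguity codes are skipped with a logged warning (they still
    count toward the length).
    """
    text = _as_text(p)
    if not text:
        raise ValidationError("aliphatic index of an empty peptide is undefined")
    skipped = sorted({ch for ch in text if ch in _AMBIGUOUS})
    if skipped:
        logger.warning("aliphatic index: ignoring ambiguous residues %s", skipped)
    n = len(text)
    mole = {ch: 100.0 * text.count(ch) / n for ch in "AVIL"}
    return mole["A"] + 2.9 * mole["V"] + 3.9 * (mole["I"] + mole["L"])


def gravy(p: Sequence | str, tables: PropertyTables = DEFAULT_TABLES) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value."""
    text = _as_text(p)
    if not text:
        raise ValidationError("GRAVY of an empty peptide is undefined")
    total = 0.0
    for ch in text:
        try:
            total += tables.hydropathy[ch]
        except KeyError:
            raise ValidationError(f"no hydropathy value for residue {ch!r}") from None
    return total / len(text)


def net_charge(
    p: Sequence | str, pH: float, tables: PropertyTables = DEFAULT_TABLES
) -> float:
    """Henderson–Hasselbalch net charge at a given pH.

    Each basic group contributes ``1/(1+10^(pH−pKa))``, each acidic
    group ``−1/(1+10^(pKa−pH))``; the termini count once, side chains
    per occurrence.  Strictly decreasing in pH.
    """
    text = _as_text(p)
    pka = tables.pka
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka.nterm))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.cterm - pH))
    for sym, value in pka.positive.items():
        charge += text.count(sym) / (1.0 + 10.0 ** (pH - value))
    for sym, value in pka.negative.items():
        charge -= text.count(sym) / (1.0 + 10.0 ** (value - pH))
    return charge


def isoelectric_point(
    p: Sequence | str, tables: PropertyTables = DEFAULT_TABLES
) -> float:
    """The pH in [0, 14] where the net charge crosses zero.

    Found by bisection (the termini guarantee one basic and one acidic
    group, and monotonicity guarantees a unique root); converges to
    |net charge| < 1e−4 and pH within 1e−6.
    """
    text = _as_text(p)
    if not text:
        raise ValidationError("isoelectric point of an empty peptide is undefined")
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        c = net_charge(text, mid, tables)
        if abs(c) < 1e-4 and hi - lo < 1e-6:
            break
        if c > 0:
            lo = mid
        else:
            hi = mid
    return mid


def aa_composition(p: Sequence | str) -> dict[str, float]:
    """Fraction of each residue; empty map for the empty peptide."""
    if isinstance(p, Sequence):
        return composition(p)
    return composition(make_sequence(str(p), PROTEIN))


def load_residue_overrides(source) -> list[ResidueOverride]:
    """Parse residue-mass overrides from an XML document.

    Schema: any root; one child element per modification carrying
    ``name``, ``target``, ``average`` and ``monoisotopic`` as
    attributes (or child elements of those names).  Missing fields
    raise :class:`~seqforge.errors.ConfigError` naming the element;
    duplicate targets are allowed — the last one wins, with a logged
    warning.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and source.lstrip().startswith("<"):
        text = source  # raw XML text
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    try:
        root = ElementTree.parse(io.StringIO(text)).getroot()
    except ElementTree.ParseError as exc:
        raise ConfigError(f"invalid override XML: {exc}") from None

    def get_field(elem, key: str) -> str | None:
        if key in elem.attrib:
            return elem.attrib[key]
        child = elem.find(key)
        if child is not None and child.text:
            return child.text.strip()
        return None

    overrides: list[ResidueOverride] = []
    seen: dict[str, str] = {}
    for elem in root:
        name = get_field(elem, "name") or ""
        values = {}
        for key in ("target", "average", "monoisotopic"):
            raw = get_field(elem, key)
            if raw is None:
                raise ConfigError(
                    f"override element {name or elem.tag!r} is missing "
                    f"mandatory field {key!r}"
                )
            values[key] = raw
        try:
            avg = float(values["average"])
            mono = float(values["monoisotopic"])
        except ValueError:
            raise ConfigError(
                f"override element {name or elem.tag!r} has non-numeric mass"
            ) from None
        target = values["target"].upper()
        if target in seen:
            logger.warning(
                "duplicate override for residue %r: %r replaces %r",
                target, name, seen[target],
            )
        seen[target] = name
        overrides.append(ResidueOverride(target, avg, mono, name))
    return overrides
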