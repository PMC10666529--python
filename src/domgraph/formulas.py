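"""Molecular formulas: parsing, Hill notation, monoisotopic masses, descriptors.

Molecular formulas (MF) are the identity level of the whole model: direct
infusion ultrahigh-resolution mass spectrometry resolves exact masses and
hence elemental compositions, but no isomers.  A formula is represented as a
signed integer vector over a fixed element set (C, H, N, O, S and optionally
P, the standard assignment space for dissolved organic matter), with Hill
notation as the canonical text form.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ELEMENTS",
    "MONOISOTOPIC_MASS",
    "ElementVector",
    "MolecularFormula",
    "DescriptorSet",
    "FormulaError",
    "parse_formula",
    "hill_notation",
    "monoisotopic_mass",
    "descriptors",
]

#: Element order used everywhere in the package (also the Hill order after C, H).
ELEMENTS = ("C", "H", "N", "O", "S", "P")

#: Monoisotopic masses of the most abundant isotopes in Da (IUPAC/CODATA).
#: A single table so that every mass in the package derives from one source.
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid element vectors."""


@dataclass(frozen=True, order=True)
class ElementVector:
    """Signed per-element counts.

    Nonnegative vectors represent molecules; signed vectors represent
    elemental differences (transformation units).
    """

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self):
        for sym in ("c", "h", "n", "o", "s", "p"):
            v = getattr(self, sym)
            if not isinstance(v, int) or isinstance(v, bool):
                raise FormulaError(f"element count {sym.upper()}={v!r} is not an integer")

    def count(self, symbol: str) -> int:
        return getattr(self, symbol.lower())

    def as_dict(self) -> dict[str, int]:
        return {sym: self.count(sym) for sym in ELEMENTS}

    def __add__(self, other: "ElementVector") -> "ElementVector":
        return ElementVector(*(a + b for a, b in zip(self._tuple(), other._tuple())))

    def __sub__(self, other: "ElementVector") -> "ElementVector":
        return ElementVector(*(a - b for a, b in zip(self._tuple(), other._tuple())))

    def __neg__(self) -> "ElementVector":
        return ElementVector(*(-a for a in self._tuple()))

    def _tuple(self) -> tuple[int, ...]:
        return (self.c, self.h, self.n, self.o, self.s, self.p)

    @property
    def is_zero(self) -> bool:
        return all(v == 0 for v in self._tuple())

    @property
    def is_molecule(self) -> bool:
        """True for a physically meaningful molecule vector (all counts >= 0,
        at least one atom)."""
        return all(v >= 0 for v in self._tuple()) and not self.is_zero

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "ElementVector":
        unknown = set(k.upper() for k in counts) - set(ELEMENTS)
        if unknown:
            raise FormulaError(f"unknown element symbol(s): {sorted(unknown)}")
        return cls(**{k.lower(): int(v) for k, v in counts.items()})


def monoisotopic_mass(ev: ElementVector) -> float:
    """Monoisotopic mass in Da; linear in the counts, so signed difference
    vectors yield (possibly negative) mass differences."""
    return sum(ev.count(sym) * MONOISOTOPIC_MASS[sym] for sym in ELEMENTS)


def hill_notation(ev: ElementVector) -> str:
    """Hill-order string: C first, H second, remaining elements alphabetical.
    Counts of 1 are omitted; zero-count elements do not appear."""
    if not ev.is_molecule:
        raise FormulaError(f"not a molecule vector: {ev}")
    order = ("C", "H") + tuple(sorted(set(ELEMENTS) - {"C", "H"}))
    parts = []
    for sym in order:
        cnt = ev.count(sym)
        if cnt == 1:
            parts.append(sym)
        elif cnt > 1:
            parts.append(f"{sym}{cnt}")
    return "".join(parts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_counts(text: str) -> ElementVector:
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        sym, num = m.group(1), m.group(2)
        if sym not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        cnt = int(num) if num else 1
        if cnt <= 0:
            raise FormulaError(f"nonpositive count for {sym} in {text!r}")
        counts[sym] = counts.get(sym, 0) + cnt
        pos = m.end()
    return ElementVector.from_dict(counts)


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """A molecule identified by its elemental composition.

    ``canonical`` is the Hill-notation string and round-trips through
    :func:`parse_formula`; equality and hashing use the element vector.
    """

    elements: ElementVector
    canonical: str
    mass: float

    @classmethod
    def from_elements(cls, ev: ElementVector) -> "MolecularFormula":
        if not ev.is_molecule:
            raise FormulaError(f"negative or empty element vector: {ev}")
        if ev.c < 1:
            raise FormulaError("molecular formulas must contain carbon (C >= 1)")
        return cls(elements=ev, canonical=hill_notation(ev), mass=monoisotopic_mass(ev))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical


def parse_formula(text: str) -> MolecularFormula:
    """Parse a formula string such as ``"C10H12O5"``.

    Bare element symbols count as 1; symbols outside the configured element
    set raise :class:`FormulaError` naming the offending token.
    """
    return MolecularFormula.from_elements(_parse_counts(text))


@dataclass(frozen=True)
class DescriptorSet:
    """Formula-derived chemical descriptors used to characterize molecules
    and clusters in van Krevelen (H/C vs O/C) space."""

    hc: float  #: H/C ratio
    oc: float  #: O/C ratio
    mw: float  #: monoisotopic mass, Da
    dbe: float  #: double-bond equivalents
    ai: float  #: aromaticity index (modified variant by default)
    nosc: float  #: nominal oxidation state of carbon
    element_class: str  #: CHO / CHNO / CHOS / CHNOS / other


def _element_class(ev: ElementVector) -> str:
    if ev.c < 1 or ev.h < 1 or ev.o < 1 or ev.p > 0:
        return "other"
    key = "CH" + ("N" if ev.n > 0 else "") + "O" + ("S" if ev.s > 0 else "")
    return key if key in {"CHO", "CHNO", "CHOS", "CHNOS"} else "other"


def descriptors(mf: MolecularFormula, aromaticity: str = "mod") -> DescriptorSet:
    """Compute the descriptor set for a molecule.

    Parameters
    ----------
    mf:
        A valid molecular formula (C >= 1 enforced at construction).
    aromaticity:
        ``"mod"`` (default) uses the modified aromaticity index AImod, which
        counts only half the oxygen as carbonyl-like; ``"plain"`` uses the
        original AI with full oxygen weight.  A nonpositive denominator maps
        to 0 so descriptor tables never contain undefined entries.
    """
    ev = mf.elements
    if ev.c < 1:
        raise FormulaError("descriptors require C >= 1")
    c, h, n, o, s, p = ev.c, ev.h, ev.n, ev.o, ev.s, ev.p
    hc = h / c
    oc = o / c
    dbe = 1 + c - h / 2 + n / 2
    if aromaticity == "mod":
        num = 1 + c - 0.5 * o - s - 0.5 * h
        den = c - 0.5 * o - n - s - p
    elif aromaticity == "plain":
        num = 1 + c - o - s - 0.5 * h
        den = c - o - n - s - p
    else:
        raise ValueError(f"unknown aromaticity variant {aromaticity!r}")
    ai = num / den if den > 0 else 0.0
    ai = max(ai, 0.0)
    nosc = 4 - (4 * c + h - 3 * n - 2 * o - 2 * s) / c
    return DescriptorSet(
        hc=hc, oc=oc, mw=mf.mass, dbe=dbe, ai=ai, nosc=nosc,
        element_class=_element_class(ev),
    )
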