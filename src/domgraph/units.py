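"""Transformation units: named signed elemental differences.

A transformation unit is the net molecular-formula change of a chemical
reaction, e.g. ``-CO2`` for decarboxylation or ``+O`` for oxidation.  Units
are matched by *exact* integer element arithmetic, never by mass tolerance:
upstream formula assignment is assumed to have resolved masses to formulas
already.  Units with a positive mass difference form the *photo addition*
group (product heavier than educt), negative ones *photo elimination*.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd

from .formulas import ElementVector, FormulaError, MolecularFormula, monoisotopic_mass

__all__ = [
    "PHOTO_ADDITION",
    "PHOTO_ELIMINATION",
    "TransformationUnit",
    "UnitTable",
    "UnitTableError",
    "load_units",
    "default_units",
    "apply_unit",
    "match_delta",
]

PHOTO_ADDITION = "photo_addition"
PHOTO_ELIMINATION = "photo_elimination"

#: Location of the packaged default unit table.
DEFAULT_UNITS_RESOURCE = "data/transformation_units.csv"


class UnitTableError(ValueError):
    """Raised when a unit table violates its invariants."""


@dataclass(frozen=True, order=True)
class TransformationUnit:
    """A named signed elemental delta with its mass change and group."""

    name: str
    delta: ElementVector
    mass_delta: float
    group: str

    @classmethod
    def from_delta(cls, name: str, delta: ElementVector) -> "TransformationUnit":
        if delta.is_zero:
            raise UnitTableError(f"unit {name!r} has an all-zero delta")
        mass = monoisotopic_mass(delta)
        if mass == 0.0:
            raise UnitTableError(f"unit {name!r} has zero mass delta")
        group = PHOTO_ADDITION if mass > 0 else PHOTO_ELIMINATION
        return cls(name=name, delta=delta, mass_delta=mass, group=group)


@dataclass(frozen=True)
class UnitTable:
    """Ordered, name-unique collection of transformation units.

    Delta vectors are unique across the table, so reverse reactions must be
    listed as their own units (``-H2O`` and ``+H2O`` are distinct entries).
    """

    units: tuple[TransformationUnit, ...]
    provenance: str = ""
    _by_name: dict = field(default_factory=dict, repr=False, compare=False)
    _by_delta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        names = [u.name for u in self.units]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise UnitTableError(f"duplicate unit name(s): {dupes}")
        deltas = [u.delta for u in self.units]
        if len(set(deltas)) != len(deltas):
            raise UnitTableError("two units share an identical delta vector")
        object.__setattr__(self, "_by_name", {u.name: u for u in self.units})
        object.__setattr__(self, "_by_delta", {u.delta: u for u in self.units})

    def __iter__(self) -> Iterator[TransformationUnit]:
        return iter(self.units)

    def __len__(self) -> int:
        return len(self.units)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> TransformationUnit:
        return self._by_name[name]

    def names(self) -> list[str]:
        return [u.name for u in self.units]

    def by_delta(self, delta: ElementVector) -> Optional[TransformationUnit]:
        return self._by_delta.get(delta)

    def subset(self, names: Iterable[str]) -> "UnitTable":
        missing = [n for n in names if n not in self._by_name]
        if missing:
            raise KeyError(f"unknown unit name(s): {missing}")
        return UnitTable(
            units=tuple(self._by_name[n] for n in names),
            provenance=self.provenance + " (subset)",
        )

    def checksum(self) -> str:
        """Stable sha256 over names and deltas, recorded in run reports."""
        h = hashlib.sha256()
        for u in self.units:
            h.update(f"{u.name}:{u.delta._tuple()}\n".encode())
        return h.hexdigest()


_DELTA_COLS = ("dC", "dH", "dN", "dO", "dS", "dP")


def _table_from_frame(df: pd.DataFrame, provenance: str) -> UnitTable:
    if "name" not in df.columns:
        raise UnitTableError("unit table must have a 'name' column")
    delta_cols = [c for c in _DELTA_COLS if c in df.columns]
    if not set(delta_cols) >= {"dC", "dH", "dO"}:
        raise UnitTableError(f"unit table needs at least dC,dH,dO columns, got {list(df.columns)}")
    units = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = row._asdict()
        counts = {}
        for col in delta_cols:
            val = row_d[col]
            if pd.isna(val) or float(val) != int(val):
                raise UnitTableError(f"row {i}: non-integer delta in column {col}: {val!r}")
            counts[col[1:]] = int(val)
        try:
            delta = ElementVector.from_dict(counts)
            units.append(TransformationUnit.from_delta(str(row_d["name"]).strip(), delta))
        except (FormulaError, UnitTableError) as exc:
            raise UnitTableError(f"row {i}: {exc}") from exc
    return UnitTable(units=tuple(units), provenance=provenance)


def load_units(path: Union[str, Path]) -> UnitTable:
    """Load a unit table from delimited text (columns name,dC,dH,dN,dO,dS[,dP]).

    Lines starting with ``#`` are comments.  Errors carry the 1-based data row
    number of the offending entry.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    return _table_from_frame(df, provenance=str(path))


def default_units() -> UnitTable:
    """The packaged default table of 22 photochemical transformation units."""
    ref = resources.files("domgraph").joinpath(DEFAULT_UNITS_RESOURCE)
    with resources.as_file(ref) as path:
        table = load_units(path)
    return UnitTable(units=table.units, provenance="builtin:transformation_units.csv")


def apply_unit(mf: MolecularFormula, unit: TransformationUnit) -> Optional[MolecularFormula]:
    """Apply a unit to a formula; ``None`` means chemically infeasible
    (a count would go negative, or carbon would vanish)."""
    ev = mf.elements + unit.delta
    if not ev.is_molecule or ev.c < 1:
        return None
    return MolecularFormula.from_elements(ev)


def match_delta(
    educt: MolecularFormula, product: MolecularFormula, units: UnitTable
) -> list[TransformationUnit]:
    """All units whose delta maps educt exactly onto product.

    Deltas are unique within a table so the result has length 0 or 1, but the
    list interface leaves room for tables that relax that invariant.
    """
    unit = units.by_delta(product.elements - educt.elements)
    return [unit] if unit is not None else []
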