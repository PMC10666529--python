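"""Shared fixtures: toy worlds, random snapshot series, brute-force oracles.

The random peak-table generator seeds a small formula pool and extends it by
applying transformation units, so that potential edges actually occur; the
brute-force oracles enumerate all (educt, product, unit) combinations
directly from the tables, independently of the graph machinery they check.
"""
from __future__ import annotations

import numpy as np
import pytest

from domgraph import (
    ElementVector,
    MolecularFormula,
    build_graph,
    default_units,
    parse_formula,
)
from domgraph.prediction import TrendClass, classify_trend
from domgraph.units import UnitTable, apply_unit


@pytest.fixture(scope="session")
def units() -> UnitTable:
    return default_units()


@pytest.fixture()
def toy_tables() -> dict[int, dict[str, float]]:
    """The decarboxylation toy: A loses 20% while B gains 80% via -CO2."""
    return {
        1: {"C10H12O5": 0.50, "C9H12O3": 0.10},
        2: {"C10H12O5": 0.40, "C9H12O3": 0.18},
    }


def random_formula(rng: np.random.Generator) -> MolecularFormula:
    c = int(rng.integers(6, 25))
    h = max(1, round(c * rng.uniform(0.6, 1.8)))
    o = max(1, round(c * rng.uniform(0.2, 0.8)))
    n = int(rng.integers(0, 3)) if rng.random() < 0.3 else 0
    s = 1 if rng.random() < 0.2 else 0
    return MolecularFormula.from_elements(ElementVector(c=c, h=h, n=n, o=o, s=s))


def random_peak_tables(
    seed: int,
    n_snapshots: int = 4,
    n_seed_formulas: int = 6,
    present_p: float = 0.75,
    units: UnitTable | None = None,
) -> dict[int, dict[str, float]]:
    """Small random snapshot series (<= ~50 nodes) whose formula pool is
    closed enough under the unit table that potential edges exist."""
    units = units or default_units()
    rng = np.random.default_rng(seed)
    pool: dict[str, MolecularFormula] = {}
    while len(pool) < n_seed_formulas:
        mf = random_formula(rng)
        pool[mf.canonical] = mf
    # extend the pool along random units so deltas actually match
    for mf in list(pool.values()):
        for _ in range(2):
            unit = units.units[rng.integers(0, len(units))]
            prod = apply_unit(mf, unit)
            if prod is not None and len(pool) < 12:
                pool[prod.canonical] = prod
    tables: dict[int, dict[str, float]] = {}
    for t in range(1, n_snapshots + 1):
        table = {}
        for f in pool:
            if rng.random() < present_p:
                table[f] = float(rng.uniform(0.01, 1.0))
        tables[t] = table
    # every snapshot needs at least one formula for a well-formed world
    for t in tables:
        if not tables[t]:
            f = next(iter(pool))
            tables[t][f] = 0.5
    return tables


def brute_force_potential(tables, units) -> set[tuple[str, str, int, str]]:
    """All-pairs x all-units enumeration of potential transformations."""
    parsed = {}
    for table in tables.values():
        for f in table:
            parsed.setdefault(f, parse_formula(f))
    n = len(tables)
    out = set()
    for t in range(1, n):
        for a, ia in tables[t].items():
            if ia <= 0:
                continue
            for b, ib in tables[t + 1].items():
                if ib <= 0 or a == b:
                    continue
                delta = parsed[b].elements - parsed[a].elements
                for u in units:
                    if u.delta == delta:
                        out.add((a, b, t, u.name))
    return out


def brute_force_predicted(tables, units, margin=0.05, policy="strict"):
    """Filter the brute-force potential set by the two trend conditions,
    straight from the tables (no graph involved)."""

    def trend_class(f, t, end):
        before = tables[t].get(f, 0.0)
        after = tables[t + 1].get(f, 0.0)
        if before > 0 and after > 0:
            return classify_trend(after / before, margin)
        if policy == "strict":
            return None
        if end == "educt" and before > 0 and after == 0:
            return TrendClass.DECREASING
        if end == "product" and after > 0 and before == 0:
            return TrendClass.INCREASING
        return None

    out = set()
    for a, b, t, uname in brute_force_potential(tables, units):
        if trend_class(a, t, "educt") is TrendClass.DECREASING and \
           trend_class(b, t, "product") is TrendClass.INCREASING:
            out.add((a, b, t, uname))
    return out


@pytest.fixture()
def built_toy(toy_tables, units):
    return build_graph(toy_tables, units)
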