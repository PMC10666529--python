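"""Snapshot-based temporal graph of molecules.

Each detected molecular formula at each sampling time point is one
``Molecule`` node, uniquely identified by ``(formula, snapshot)``.  Three
directed edge kinds connect *consecutive* snapshots only:

* ``SAME_AS`` — the same formula at t and t+1, carrying the intensity trend
  I(t+1)/I(t);
* ``POTENTIAL_TRANSFORMATION`` — formula arithmetic allows a transformation
  unit to map the educt at t onto a product present at t+1;
* ``PREDICTED_TRANSFORMATION`` — the subset of potential edges consistent
  with educt intensity loss and product gain (see :mod:`domgraph.prediction`).

No edge ever connects two nodes within one snapshot, and isolated nodes
(without any potential edge) are pruned after potential-edge computation.

The graph is backed by a :class:`networkx.MultiDiGraph`; node keys are
``(canonical_formula, snapshot)`` tuples and every edge has a ``kind``
attribute (``"same_as"``, ``"potential"``, ``"predicted"``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from .formulas import MolecularFormula, parse_formula
from .units import TransformationUnit, UnitTable, apply_unit

__all__ = [
    "SAME_AS",
    "POTENTIAL",
    "PREDICTED",
    "GraphBuildError",
    "TemporalGraph",
    "validate_peak_tables",
    "compute_same_as",
    "compute_potential",
    "build_graph",
]

SAME_AS = "same_as"
POTENTIAL = "potential"
PREDICTED = "predicted"

PeakTables = Mapping[int, Mapping[str, float]]


class GraphBuildError(ValueError):
    """Raised for structurally invalid inputs to the graph builder."""


def validate_peak_tables(peak_tables: PeakTables) -> dict[int, dict[str, float]]:
    """Check snapshot indexing and intensities; drop zero-intensity rows.

    Snapshots must be consecutive integers starting at 1 (at least two).
    Zero intensity means "not detected" and the row is dropped; negative
    intensities are a hard error.
    """
    snaps = sorted(peak_tables)
    if len(snaps) < 2:
        raise GraphBuildError(f"need at least 2 snapshots, got {len(snaps)}")
    if snaps != list(range(1, len(snaps) + 1)):
        raise GraphBuildError(f"snapshot indices must be consecutive from 1, got {snaps}")
    clean: dict[int, dict[str, float]] = {}
    for t in snaps:
        table = {}
        for formula, inten in peak_tables[t].items():
            if inten < 0:
                raise GraphBuildError(
                    f"negative intensity {inten} for {formula} at snapshot {t}"
                )
            if inten > 0:
                table[formula] = float(inten)
        clean[t] = table
    return clean


@dataclass
class TemporalGraph:
    """Thin typed wrapper around the backing multigraph.

    ``series`` keeps the detected intensity series of *every* formula,
    including nodes later pruned for lacking potential edges: intensity
    trends are measured data, so the TPA predicate and the edge weights read
    them from the series rather than from surviving SAME_AS edges.  Pruning
    stays a pure graph-hygiene step and does not erase measurements.
    """

    graph: nx.MultiDiGraph
    n_snapshots: int
    metadata: dict = field(default_factory=dict)
    omitted_fraction: float = 0.0
    #: formula -> {snapshot: intensity} over all detected rows
    series: dict = field(default_factory=dict)

    # -- structure -----------------------------------------------------------
    @property
    def transitions(self) -> list[int]:
        """Transition t covers snapshot t -> t+1; n snapshots yield n-1."""
        return list(range(1, self.n_snapshots))

    def nodes_at(self, snapshot: int) -> list[tuple[str, int]]:
        return [v for v in self.graph.nodes if v[1] == snapshot]

    def formulas_at(self, snapshot: int) -> set[str]:
        return {v[0] for v in self.graph.nodes if v[1] == snapshot}

    def intensity(self, formula: str, snapshot: int) -> Optional[float]:
        data = self.graph.nodes.get((formula, snapshot))
        return None if data is None else data["intensity"]

    def formula_obj(self, formula: str, snapshot: int) -> MolecularFormula:
        return self.graph.nodes[(formula, snapshot)]["formula"]

    # -- edge accessors ------------------------------------------------------
    def _edges_of_kind(self, kind: str, transition: Optional[int] = None):
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            if d["kind"] != kind:
                continue
            if transition is not None and u[1] != transition:
                continue
            yield u, v, k, d

    def edges_by_transition(self, kind: str) -> dict[int, list]:
        """All edges of one kind grouped by transition, in a single pass
        (preferred over repeated per-transition scans on large graphs)."""
        out: dict[int, list] = {t: [] for t in self.transitions}
        for u, v, k, d in self.graph.edges(keys=True, data=True):
            if d["kind"] == kind:
                out[u[1]].append((u, v, k, d))
        return out

    def same_as_edges(self, transition: Optional[int] = None):
        return list(self._edges_of_kind(SAME_AS, transition))

    def potential_edges(self, transition: Optional[int] = None):
        return list(self._edges_of_kind(POTENTIAL, transition))

    def predicted_edges(self, transition: Optional[int] = None):
        return list(self._edges_of_kind(PREDICTED, transition))

    def detected_formulas_at(self, snapshot: int) -> set[str]:
        """Formulas detected at a snapshot (pre-pruning detection record)."""
        return {f for f, s in self.series.items() if snapshot in s}

    def series_trends(self, transition: int) -> dict[str, float]:
        """Intensity trends of all formulas detected at both ends of the
        transition — the measured SAME_AS relation, independent of pruning."""
        out = {}
        for f, s in self.series.items():
            if transition in s and transition + 1 in s:
                out[f] = s[transition + 1] / s[transition]
        return out

    def detected_intensity(self, formula: str, snapshot: int) -> Optional[float]:
        """Measured intensity from the detection series (None if absent),
        independent of whether the node survived pruning."""
        return self.series.get(formula, {}).get(snapshot)

    def trend(self, formula: str, transition: int) -> Optional[float]:
        """Intensity trend I(t+1)/I(t) of a formula over transition t -> t+1
        from the detection series, or None when absent at either end."""
        before = self.detected_intensity(formula, transition)
        after = self.detected_intensity(formula, transition + 1)
        if before is None or after is None:
            return None
        return after / before

    # -- equality (structural) ----------------------------------------------
    def _signature(self):
        nodes = frozenset(
            (v[0], v[1], round(d["intensity"], 12)) for v, d in self.graph.nodes(data=True)
        )
        edges = []
        for u, v, d in self.graph.edges(data=True):
            attrs = {k: d[k] for k in ("kind", "unit", "trend", "weight") if k in d}
            if "trend" in attrs:
                attrs["trend"] = round(attrs["trend"], 12)
            if attrs.get("weight") is not None:
                attrs["weight"] = round(attrs["weight"], 12)
            edges.append((u, v, tuple(sorted(attrs.items(), key=lambda kv: kv[0]))))
        return self.n_snapshots, nodes, frozenset((e, edges.count(e)) for e in edges)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TemporalGraph):
            return NotImplemented
        return self._signature() == other._signature()


def compute_same_as(peak_tables: PeakTables) -> list[tuple[str, int, float]]:
    """SAME_AS edges as (formula, from_snapshot, trend) triples: one per
    formula detected (intensity > 0) at both ends of a transition."""
    tables = validate_peak_tables(peak_tables)
    edges = []
    for t in range(1, len(tables)):
        for formula, inten in tables[t].items():
            later = tables[t + 1].get(formula)
            if later is not None:
                edges.append((formula, t, later / inten))
    return edges


def compute_potential(
    peak_tables: PeakTables, units: UnitTable
) -> list[tuple[str, str, int, str]]:
    """Potential-transformation edges as (educt, product, from_snapshot,
    unit_name) tuples.

    For every transition and every educt at t, each unit whose application is
    feasible and lands on a formula detected at t+1 yields one edge; several
    units linking the same node pair yield parallel edges.
    """
    tables = validate_peak_tables(peak_tables)
    # products are transition-independent: apply every unit to every unique
    # formula once, then per transition only check presence at t+1
    candidates: dict[str, list[tuple[str, str]]] = {}
    for table in tables.values():
        for f in table:
            if f in candidates:
                continue
            mf = parse_formula(f)
            cands = []
            for unit in units:
                prod = apply_unit(mf, unit)
                if prod is not None and prod.canonical != f:
                    cands.append((unit.name, prod.canonical))
            candidates[f] = cands
    edges = []
    for t in range(1, len(tables)):
        later = tables[t + 1]
        for formula in tables[t]:
            for unit_name, prod in candidates[formula]:
                if prod in later:
                    edges.append((formula, prod, t, unit_name))
    return edges


def build_graph(
    peak_tables: PeakTables,
    units: UnitTable,
    metadata: Optional[dict] = None,
    prune: bool = True,
) -> TemporalGraph:
    """Assemble the temporal graph from per-snapshot peak tables.

    Nodes are created for every detected formula, SAME_AS and potential
    edges computed, and (by default) nodes without any potential edge are
    pruned together with their SAME_AS edges; the omitted fraction is
    recorded on the returned graph.
    """
    tables = validate_peak_tables(peak_tables)
    n = len(tables)
    g = nx.MultiDiGraph()
    parsed: dict[str, MolecularFormula] = {}
    for t, table in tables.items():
        for formula, inten in table.items():
            if formula not in parsed:
                parsed[formula] = parse_formula(formula)
            if parsed[formula].canonical != formula:
                raise GraphBuildError(
                    f"formula {formula!r} is not in canonical Hill notation "
                    f"(expected {parsed[formula].canonical!r})"
                )
            g.add_node((formula, t), formula=parsed[formula], snapshot=t, intensity=inten)

    for formula, t, trend in compute_same_as(tables):
        g.add_edge((formula, t), (formula, t + 1), kind=SAME_AS, trend=trend)

    for educt, product, t, unit_name in compute_potential(tables, units):
        g.add_edge(
            (educt, t), (product, t + 1), kind=POTENTIAL, unit=unit_name
        )

    total = g.number_of_nodes()
    omitted = 0.0
    if prune and total:
        keep = set()
        for u, v, d in g.edges(data=True):
            if d["kind"] == POTENTIAL:
                keep.add(u)
                keep.add(v)
        drop = [v for v in g.nodes if v not in keep]
        g.remove_nodes_from(drop)
        omitted = len(drop) / total

    series: dict[str, dict[int, float]] = {}
    for t, table in tables.items():
        for formula, inten in table.items():
            series.setdefault(formula, {})[t] = inten

    return TemporalGraph(
        graph=g, n_snapshots=n, metadata=dict(metadata or {}),
        omitted_fraction=omitted, series=series,
    )
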