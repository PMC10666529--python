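"""Light temporal graph: one node per unique formula, and weighted label
propagation clustering on it.

The light representation folds the snapshot dimension into node and edge
properties: a node stores the formula's full intensity series, and a single
``CHEMICAL_TRANSFORMATION`` edge per ordered formula pair aggregates every
potential/predicted record across transitions.  The conversion is lossless in
both directions, which makes static-graph algorithms (community detection)
applicable without discarding temporal information.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .temporal import (
    PREDICTED,
    POTENTIAL,
    SAME_AS,
    GraphBuildError,
    TemporalGraph,
)
from .formulas import parse_formula

__all__ = [
    "TransformationRecord",
    "LightGraph",
    "ClusterAssignment",
    "to_light",
    "from_light",
    "clustering_weights",
    "label_propagation",
]


@dataclass(frozen=True, order=True)
class TransformationRecord:
    """One potential transformation on one transition, with its prediction
    status and (optional) TPA weight."""

    transition: int
    unit: str
    predicted: bool = False
    weight: Optional[float] = None


@dataclass
class LightGraph:
    """Aggregated temporal graph: formula-level nodes and edges."""

    #: formula -> {snapshot: intensity}; absent snapshots omitted
    nodes: dict[str, dict[int, float]]
    #: (educt, product) -> records, at most one per (transition, unit)
    edges: dict[tuple[str, str], list[TransformationRecord]]
    n_snapshots: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for pair, records in self.edges.items():
            keys = [(r.transition, r.unit) for r in records]
            if len(set(keys)) != len(keys):
                raise GraphBuildError(f"duplicate (transition, unit) record on edge {pair}")
            if not records:
                raise GraphBuildError(f"edge {pair} has no records")

    def predicted_record_count(self, a: str, b: str) -> int:
        """Number of predicted records between two formulas, both directions."""
        n = 0
        for pair in ((a, b), (b, a)):
            n += sum(1 for r in self.edges.get(pair, ()) if r.predicted)
        return n

    def __eq__(self, other) -> bool:
        if not isinstance(other, LightGraph):
            return NotImplemented
        def canon(lg: "LightGraph"):
            nodes = {
                f: {t: round(i, 12) for t, i in series.items()}
                for f, series in lg.nodes.items()
            }
            edges = {
                pair: sorted(
                    (r.transition, r.unit, r.predicted,
                     None if r.weight is None else round(r.weight, 12))
                    for r in records
                )
                for pair, records in lg.edges.items()
            }
            return lg.n_snapshots, nodes, edges
        return canon(self) == canon(other)


def to_light(g: TemporalGraph) -> LightGraph:
    """Aggregate a built temporal graph into its light representation."""
    nodes: dict[str, dict[int, float]] = {}
    for (formula, t), d in g.graph.nodes(data=True):
        nodes.setdefault(formula, {})[t] = d["intensity"]

    records: dict[tuple[str, str], dict[tuple[int, str], TransformationRecord]] = {}
    for u, v, _, d in g.graph.edges(keys=True, data=True):
        if d["kind"] == SAME_AS:
            continue  # recomputable from the series
        pair = (u[0], v[0])
        key = (u[1], d["unit"])
        slot = records.setdefault(pair, {})
        if d["kind"] == POTENTIAL:
            if key not in slot:
                slot[key] = TransformationRecord(transition=u[1], unit=d["unit"])
        else:  # predicted parallels its potential edge
            slot[key] = TransformationRecord(
                transition=u[1], unit=d["unit"], predicted=True, weight=d.get("weight")
            )
    edges = {pair: sorted(slot.values()) for pair, slot in records.items()}
    return LightGraph(
        nodes=nodes, edges=edges, n_snapshots=g.n_snapshots, metadata=dict(g.metadata)
    )


def from_light(lg: LightGraph) -> TemporalGraph:
    """Reconstruct the full temporal graph from a light graph.

    SAME_AS edges are recomputed from the intensity series; potential and
    predicted edges come from the records.  A record on a transition where
    either endpoint series has no value is a consistency error.
    """
    g = nx.MultiDiGraph()
    for formula, series in lg.nodes.items():
        mf = parse_formula(formula)
        for t, inten in series.items():
            if not 1 <= t <= lg.n_snapshots:
                raise GraphBuildError(f"snapshot {t} out of range for {formula}")
            g.add_node((formula, t), formula=mf, snapshot=t, intensity=inten)

    for formula, series in lg.nodes.items():
        for t in sorted(series):
            if t + 1 in series:
                g.add_edge(
                    (formula, t), (formula, t + 1),
                    kind=SAME_AS, trend=series[t + 1] / series[t],
                )

    for (educt, product), recs in lg.edges.items():
        for r in recs:
            u, v = (educt, r.transition), (product, r.transition + 1)
            if not g.has_node(u) or not g.has_node(v):
                raise GraphBuildError(
                    f"record {r} on edge {educt}->{product} references a snapshot "
                    "absent from the endpoint series"
                )
            g.add_edge(u, v, kind=POTENTIAL, unit=r.unit)
            if r.predicted:
                g.add_edge(u, v, kind=PREDICTED, unit=r.unit, weight=r.weight)

    # The detection series of formulas whose nodes were pruned before the
    # light conversion is not stored in the light graph; after a round trip
    # the series covers exactly the surviving nodes.
    series = {f: dict(s) for f, s in lg.nodes.items()}
    return TemporalGraph(
        graph=g, n_snapshots=lg.n_snapshots, metadata=dict(lg.metadata), series=series
    )


@dataclass
class ClusterAssignment:
    """Result of label propagation: a partition of the light-graph nodes."""

    labels: dict[str, int]
    n_iter: int
    seed: int
    converged: bool

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for f, lab in self.labels.items():
            out.setdefault(lab, []).append(f)
        return {lab: sorted(members) for lab, members in out.items()}


def clustering_weights(
    lg: LightGraph, directed: bool = False
) -> dict[tuple[str, str], int]:
    """Pairwise clustering weights: the number of predicted transformation
    records between two formulas.  With ``directed=False`` (default) the two
    directions are summed and each unordered pair appears once (sorted)."""
    weights: dict[tuple[str, str], int] = {}
    for (a, b), records in lg.edges.items():
        n = sum(1 for r in records if r.predicted)
        if n == 0:
            continue
        key = (a, b) if directed else tuple(sorted((a, b)))
        weights[key] = weights.get(key, 0) + n
    return weights


def label_propagation(
    lg: LightGraph,
    max_iter: int = 100,
    seed: int = 0,
    directed: bool = False,
    allow_zero_weight: bool = False,
    init_labels: Optional[dict[str, int]] = None,
) -> ClusterAssignment:
    """Asynchronous weighted label propagation on the light graph.

    Every node starts with a unique label.  In each sweep the nodes are
    visited in a seed-shuffled order and each adopts the neighboring label
    with the largest summed incident weight (the count of predicted records
    between the pair), ties broken by the smallest label.  The algorithm
    stops when a sweep changes nothing, or after ``max_iter`` sweeps (then
    the current assignment is returned with ``converged=False``).

    Nodes whose incident edges carry zero predicted records keep their own
    label and end as singletons unless ``allow_zero_weight`` is set.
    A converged assignment passed back via ``init_labels`` is a fixed point.
    """
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    formulas = sorted(lg.nodes)
    if init_labels is None:
        labels = {f: i for i, f in enumerate(formulas)}
    else:
        missing = set(formulas) - set(init_labels)
        if missing:
            raise ValueError(f"init_labels misses formula(s): {sorted(missing)[:5]}")
        labels = {f: init_labels[f] for f in formulas}

    pair_w = clustering_weights(lg, directed=False)
    if allow_zero_weight:
        for a, b in lg.edges:
            key = tuple(sorted((a, b)))
            pair_w.setdefault(key, 0)
    neighbors: dict[str, dict[str, int]] = {f: {} for f in formulas}
    for (a, b), w in pair_w.items():
        neighbors[a][b] = neighbors[a].get(b, 0) + w
        neighbors[b][a] = neighbors[b].get(a, 0) + w

    rng = random.Random(seed)
    converged = False
    sweeps = 0
    for sweeps in range(1, max_iter + 1):
        order = formulas[:]
        rng.shuffle(order)
        changed = False
        for f in order:
            nbrs = neighbors[f]
            if not nbrs:
                continue
            scores: dict[int, float] = {}
            for nbr, w in nbrs.items():
                if w == 0 and not allow_zero_weight:
                    continue
                lab = labels[nbr]
                scores[lab] = scores.get(lab, 0) + w
            if not scores:
                continue
            best_score = max(scores.values())
            if best_score <= 0 and not allow_zero_weight:
                continue
            best = min(lab for lab, s in scores.items() if s == best_score)
            if best != labels[f]:
                labels[f] = best
                changed = True
        if not changed:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(
            f"label propagation did not converge within {max_iter} sweeps",
            stacklevel=2,
        )
    return ClusterAssignment(labels=dict(labels), n_iter=sweeps, seed=seed,
                             converged=converged)
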