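"""Quantitative summaries of the temporal graph.

Everything here is reporting: per-transition structural metrics, the share
and importance of each transformation unit, intensity-weighted molecular
descriptors per snapshot, and the characterization of label-propagation
clusters.  All results are plain pandas objects so they serialize to
delimited tables directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .formulas import descriptors
from .light import ClusterAssignment, LightGraph
from .prediction import TrendClass, classify_trend
from .temporal import POTENTIAL, PREDICTED, TemporalGraph
from .units import PHOTO_ADDITION, PHOTO_ELIMINATION, UnitTable

__all__ = [
    "transition_stats",
    "out_degree_histogram",
    "ShareMatrix",
    "unit_shares",
    "group_shares",
    "unit_importance",
    "weighted_descriptors",
    "ClusterReport",
    "cluster_report",
]


def transition_stats(g: TemporalGraph, margin: float = 0.05) -> pd.DataFrame:
    """Per-transition structural metrics.

    Columns: detected-molecule counts at both ends, SAME_AS count and its
    partition into increasing/decreasing/consistent trends at the given
    margin, potential and predicted edge counts, and mean predicted edges per
    molecule at t.  Counts describe the detection record (the intensity
    series), so a molecule pruned from the graph for lacking potential edges
    still counts as detected.  A graph without predictions reports zeros.
    """
    potential = g.edges_by_transition(POTENTIAL)
    predicted = g.edges_by_transition(PREDICTED)
    rows = []
    for t in g.transitions:
        trends = g.series_trends(t)
        counts = {c: 0 for c in TrendClass}
        for trend in trends.values():
            counts[classify_trend(trend, margin)] += 1
        n_from = len(g.detected_formulas_at(t))
        n_pred = len(predicted[t])
        rows.append(
            {
                "transition": t,
                "nodes_from": n_from,
                "nodes_to": len(g.detected_formulas_at(t + 1)),
                "same_as": len(trends),
                "increasing": counts[TrendClass.INCREASING],
                "decreasing": counts[TrendClass.DECREASING],
                "consistent": counts[TrendClass.CONSISTENT],
                "potential": len(potential[t]),
                "predicted": n_pred,
                "mean_predicted_per_molecule": n_pred / n_from if n_from else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("transition")


def out_degree_histogram(g: TemporalGraph) -> pd.DataFrame:
    """Distribution of outgoing predicted edges per node, by transition.

    Includes degree 0, so counts sum to the detected-molecule count at t.
    Scale-free behavior shows up as many degree-0/1 nodes and a long tail.
    """
    predicted = g.edges_by_transition(PREDICTED)
    rows = []
    for t in g.transitions:
        deg: dict[str, int] = {f: 0 for f in g.detected_formulas_at(t)}
        for u, _, _, _ in predicted[t]:
            deg[u[0]] += 1
        hist: dict[int, int] = {}
        for d in deg.values():
            hist[d] = hist.get(d, 0) + 1
        for d in sorted(hist):
            rows.append({"transition": t, "out_degree": d, "count": hist[d]})
    return pd.DataFrame(rows, columns=["transition", "out_degree", "count"])


@dataclass
class ShareMatrix:
    """Unit shares of predicted transformations.

    ``per_transition`` tabulates share(t, u) over the full unit set (zeros
    included); transitions without any prediction are all-NaN rows and are
    excluded from the averages.  ``relative_change`` is the percent change of
    each unit's share from the first to the last transition; units absent in
    the first transition are NaN there and listed in ``undefined_change``.
    """

    per_transition: pd.DataFrame
    unit_avg: pd.Series
    grand_mean: float
    relative_change: pd.Series
    undefined_change: list[str] = field(default_factory=list)


def _predicted_unit_counts(g: TemporalGraph, units: UnitTable) -> pd.DataFrame:
    names = units.names()
    counts = {t: dict.fromkeys(names, 0.0) for t in g.transitions}
    for t, edges in g.edges_by_transition(PREDICTED).items():
        for _, _, _, d in edges:
            counts[t][d["unit"]] += 1
    data = pd.DataFrame.from_dict(counts, orient="index", dtype=float)[names]
    data.index.name = "transition"
    return data


def unit_shares(g: TemporalGraph, units: UnitTable) -> ShareMatrix:
    """Share of each transformation unit among the predicted edges.

    share(t, u) = predicted edges with unit u on transition t divided by all
    predicted edges on t; the unit average is the mean across transitions
    with predictions, and the grand mean averages those unit averages (equal
    to 1/K for a full K-unit tabulation, since shares sum to 1 per
    transition).
    """
    counts = _predicted_unit_counts(g, units)
    totals = counts.sum(axis=1)
    if totals.sum() == 0:
        raise ValueError("no predicted edges in any transition; run the TPA first")
    shares = counts.div(totals, axis=0)  # all-NaN rows where total == 0
    unit_avg = shares.mean(axis=0, skipna=True)
    grand_mean = float(unit_avg.mean())

    first, last = g.transitions[0], g.transitions[-1]
    first_s, last_s = shares.loc[first], shares.loc[last]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (last_s - first_s) / first_s * 100.0
    rel = rel.replace([np.inf, -np.inf], np.nan)
    undefined = sorted(first_s.index[(first_s == 0) | first_s.isna()])
    rel[undefined] = np.nan
    return ShareMatrix(
        per_transition=shares,
        unit_avg=unit_avg,
        grand_mean=grand_mean,
        relative_change=rel,
        undefined_change=list(undefined),
    )


def group_shares(shares: ShareMatrix, units: UnitTable) -> pd.DataFrame:
    """Roll the share matrix up into photo addition vs photo elimination."""
    groups = {u.name: u.group for u in units}
    cols = shares.per_transition.columns
    add = [c for c in cols if groups.get(c) == PHOTO_ADDITION]
    elim = [c for c in cols if groups.get(c) == PHOTO_ELIMINATION]
    return pd.DataFrame(
        {
            PHOTO_ADDITION: shares.per_transition[add].sum(axis=1, min_count=1),
            PHOTO_ELIMINATION: shares.per_transition[elim].sum(axis=1, min_count=1),
        }
    )


def unit_importance(g: TemporalGraph, units: UnitTable) -> pd.DataFrame:
    """Weight-based relative importance of each unit per transition.

    importance(t, u) = summed TPA weights of unit-u predicted edges on t,
    normalized by the summed weights of all predicted edges on t.  A
    transition with zero total weight reports all zeros.
    """
    names = units.names()
    sums = {t: dict.fromkeys(names, 0.0) for t in g.transitions}
    for t, edges in g.edges_by_transition(PREDICTED).items():
        for _, _, _, d in edges:
            w = d.get("weight")
            if w is None:
                raise ValueError("predicted edges have no weights; run compute_edge_weights")
            sums[t][d["unit"]] += w
    data = pd.DataFrame.from_dict(sums, orient="index")[names]
    data.index.name = "transition"
    totals = data.sum(axis=1)
    out = data.div(totals.where(totals != 0), axis=0).fillna(0.0)
    return out


def weighted_descriptors(
    g: TemporalGraph, fields: tuple[str, ...] = ("mw", "hc", "oc", "dbe", "ai", "nosc")
) -> pd.DataFrame:
    """Intensity-weighted mean molecular descriptors per snapshot, over all
    detected molecules (bulk sample metrics, so pruning does not apply)."""
    from .formulas import parse_formula

    cache: dict[str, object] = {}
    rows = []
    for t in range(1, g.n_snapshots + 1):
        formulas = sorted(g.detected_formulas_at(t))
        if not formulas:
            raise ValueError(f"snapshot {t} has no detected molecules")
        weights = np.array([g.detected_intensity(f, t) for f in formulas])
        descs = []
        for f in formulas:
            if f not in cache:
                cache[f] = descriptors(parse_formula(f))
            descs.append(cache[f])
        row = {"snapshot": t}
        for name in fields:
            vals = np.array([getattr(d, name) for d in descs])
            row[name] = float(np.average(vals, weights=weights))
        rows.append(row)
    return pd.DataFrame(rows).set_index("snapshot")


@dataclass
class ClusterReport:
    """Per-cluster characterization of a label-propagation partition."""

    #: size, element-class composition, descriptor means, mean intensity trend
    summary: pd.DataFrame
    #: cluster label -> share of each unit among internal predicted records
    unit_shares: dict[int, pd.Series]
    #: clusters with no internal predicted records
    empty_unit_shares: list[int]
    #: count of predicted records crossing cluster boundaries
    boundary_records: int


def cluster_report(
    assignment: ClusterAssignment,
    g: TemporalGraph,
    lg: LightGraph,
    units: UnitTable,
) -> ClusterReport:
    """Characterize each cluster chemically and by its transformations.

    Unit shares count only predicted records internal to the cluster (both
    endpoints assigned to it); boundary records are tallied separately.  The
    mean intensity trend collects, for every internal predicted record, the
    educt and product SAME_AS trends on its transition; values near 1 mean
    the cluster mixes educts (trend < 1) and products (trend > 1).
    """
    unknown = set(assignment.labels) - set(lg.nodes)
    if unknown:
        raise ValueError(f"assignment references unknown formula(s): {sorted(unknown)[:5]}")

    from .formulas import parse_formula

    members = assignment.clusters()
    rows = []
    shares: dict[int, pd.Series] = {}
    empty: list[int] = []
    boundary = 0

    # internal predicted record counts per cluster x unit, and trends
    counts: dict[int, dict[str, int]] = {lab: {} for lab in members}
    trends: dict[int, list[float]] = {lab: [] for lab in members}
    for (a, b), records in lg.edges.items():
        la, lb = assignment.labels.get(a), assignment.labels.get(b)
        for r in records:
            if not r.predicted:
                continue
            if la is None or lb is None or la != lb:
                boundary += 1
                continue
            counts[la][r.unit] = counts[la].get(r.unit, 0) + 1
            for f in (a, b):
                tr = g.trend(f, r.transition)
                if tr is not None:
                    trends[la].append(tr)

    for lab, formulas in members.items():
        descs = [descriptors(parse_formula(f)) for f in formulas]
        comp = pd.Series([d.element_class for d in descs]).value_counts(normalize=True)
        row = {
            "cluster": lab,
            "size": len(formulas),
            "mean_hc": float(np.mean([d.hc for d in descs])),
            "mean_oc": float(np.mean([d.oc for d in descs])),
            "mean_mw": float(np.mean([d.mw for d in descs])),
            "mean_ai": float(np.mean([d.ai for d in descs])),
            "mean_nosc": float(np.mean([d.nosc for d in descs])),
            "mean_intensity_trend": float(np.mean(trends[lab])) if trends[lab] else np.nan,
        }
        for cls in ("CHO", "CHNO", "CHOS", "CHNOS", "other"):
            row[f"frac_{cls}"] = float(comp.get(cls, 0.0))
        rows.append(row)

        total = sum(counts[lab].values())
        if total == 0:
            empty.append(lab)
            shares[lab] = pd.Series(0.0, index=units.names())
        else:
            s = pd.Series(0.0, index=units.names())
            for u, c in counts[lab].items():
                s[u] = c / total
            shares[lab] = s

    summary = (
        pd.DataFrame(rows)
        .sort_values(["size", "cluster"], ascending=[False, True])
        .set_index("cluster")
    )
    return ClusterReport(
        summary=summary,
        unit_shares=shares,
        empty_unit_shares=sorted(empty),
        boundary_records=boundary,
    )
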