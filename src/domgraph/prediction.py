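"""Transformation Prediction Algorithm (TPA).

A potential transformation becomes a *predicted* transformation when the
intensity record supports it: the educt's intensity trend over the transition
is decreasing and the product's is increasing, both beyond a measurement
error margin (default 5%).  The margin is applied to the intensity *ratio*
I(t+1)/I(t): a trend within [1-m, 1+m] (inclusive) counts as consistent, so
a ratio of exactly 1.05 at m=0.05 does not qualify as a change.

Formulas that appear or disappear between snapshots have no SAME_AS edge on
the transition.  Two policies handle them:

* ``strict`` (default) — both SAME_AS trends are required; appearing or
  disappearing formulas never take part in a prediction.
* ``zero_fill`` — a formula absent at t but present at t+1 counts as
  increasing (a newly formed, transient compound); present at t but absent
  at t+1 counts as decreasing (fully consumed).

Each predicted edge is weighted by equal apportionment of the educt's
intensity loss over its outgoing predictions and the product's gain over its
incoming predictions:

    weight(A -> B) = 1/2 * ( loss_A / outdeg(A) + gain_B / indeg(B) )

which conserves, per transition, half the total participating loss plus gain.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .temporal import PREDICTED, POTENTIAL, SAME_AS, TemporalGraph

__all__ = [
    "TrendClass",
    "PredictionError",
    "classify_trend",
    "predict_transformations",
    "compute_edge_weights",
    "POLICIES",
]

POLICIES = ("strict", "zero_fill")


class PredictionError(ValueError):
    pass


class TrendClass(Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"
    CONSISTENT = "consistent"


def classify_trend(trend: float, margin: float = 0.05) -> TrendClass:
    """Classify an intensity ratio against the error margin.

    Boundary values 1 +- m are consistent: the change must be strictly
    larger than the margin to count.
    """
    if trend <= 0:
        raise PredictionError(f"intensity trend must be positive, got {trend}")
    if not 0 <= margin < 1:
        raise PredictionError(f"margin must be in [0, 1), got {margin}")
    if trend < 1 - margin:
        return TrendClass.DECREASING
    if trend > 1 + margin:
        return TrendClass.INCREASING
    return TrendClass.CONSISTENT


def _node_trend_class(
    g: TemporalGraph, formula: str, transition: int, margin: float, policy: str,
    end: str,
) -> Optional[TrendClass]:
    """Trend class of a node on a transition, or None when it cannot be
    classified under the policy.  ``end`` says which end of the transition
    the caller sits on ('educt' at t, 'product' at t+1)."""
    trend = g.trend(formula, transition)
    if trend is not None:
        return classify_trend(trend, margin)
    if policy == "strict":
        return None
    # zero_fill: non-detection on the far side of the transition implies the
    # largest possible change in the caller's direction.
    if end == "educt":
        # detected at t (guaranteed by the potential edge), absent at t+1
        detected_later = g.detected_intensity(formula, transition + 1) is not None
        return None if detected_later else TrendClass.DECREASING
    else:
        detected_earlier = g.detected_intensity(formula, transition) is not None
        return None if detected_earlier else TrendClass.INCREASING


def predict_transformations(
    g: TemporalGraph, margin: float = 0.05, policy: str = "strict"
) -> list[tuple[str, str, int, str]]:
    """Run the TPA: materialize predicted edges in the graph.

    Iterates product nodes per transition; a product whose incoming SAME_AS
    trend is increasing keeps those incoming potential edges whose educt
    trend is decreasing.  The predicate is edge-local, so the result does
    not depend on iteration order.  Returns the predicted edges as
    (educt, product, transition, unit) tuples; they are also added to the
    graph as ``PREDICTED_TRANSFORMATION`` edges.
    """
    if policy not in POLICIES:
        raise PredictionError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    # drop stale predictions so the call is idempotent
    stale = [
        (u, v, k)
        for u, v, k, d in g.graph.edges(keys=True, data=True)
        if d["kind"] == PREDICTED
    ]
    g.graph.remove_edges_from(stale)

    predicted = []
    by_transition = g.edges_by_transition(POTENTIAL)
    for t in g.transitions:
        cache: dict[tuple[str, str], Optional[TrendClass]] = {}
        for u, v, _, d in by_transition[t]:
            educt, product = u[0], v[0]
            key = (product, "product")
            if key not in cache:
                cache[key] = _node_trend_class(g, product, t, margin, policy, "product")
            if cache[key] is not TrendClass.INCREASING:
                continue
            key = (educt, "educt")
            if key not in cache:
                cache[key] = _node_trend_class(g, educt, t, margin, policy, "educt")
            if cache[key] is not TrendClass.DECREASING:
                continue
            g.graph.add_edge(u, v, kind=PREDICTED, unit=d["unit"], weight=None)
            predicted.append((educt, product, t, d["unit"]))
    return predicted


def _loss(g: TemporalGraph, formula: str, t: int) -> float:
    before = g.detected_intensity(formula, t)
    after = g.detected_intensity(formula, t + 1)
    return before - (after or 0.0)


def _gain(g: TemporalGraph, formula: str, t: int) -> float:
    before = g.detected_intensity(formula, t)
    after = g.detected_intensity(formula, t + 1)
    return after - (before or 0.0)


def compute_edge_weights(g: TemporalGraph) -> dict[tuple, float]:
    """Attach weights to the predicted edges.

    Per transition, each educt's intensity loss is split evenly over its
    outgoing predicted edges, each product's gain over its incoming ones;
    the edge weight is the mean of its two shares.  Degrees count predicted
    edges (parallel unit edges separately).  Summed over a transition the
    weights equal half the total participating loss plus gain.
    """
    weights: dict[tuple, float] = {}
    by_transition = g.edges_by_transition(PREDICTED)
    for t in g.transitions:
        edges = by_transition[t]
        outdeg: dict[tuple, int] = {}
        indeg: dict[tuple, int] = {}
        for u, v, _, _ in edges:
            outdeg[u] = outdeg.get(u, 0) + 1
            indeg[v] = indeg.get(v, 0) + 1
        for u, v, k, d in edges:
            loss = _loss(g, u[0], t)
            gain = _gain(g, v[0], t)
            w = 0.5 * (loss / outdeg[u] + gain / indeg[v])
            g.graph[u][v][k]["weight"] = w
            weights[(u, v, k)] = w
    return weights
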