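"""Light-graph conversion (lossless both ways) and label propagation."""
import pytest

from domgraph.light import (
    LightGraph,
    TransformationRecord,
    clustering_weights,
    from_light,
    label_propagation,
    to_light,
)
from domgraph.prediction import compute_edge_weights, predict_transformations
from domgraph.temporal import GraphBuildError, build_graph

from .conftest import random_peak_tables


def build_predicted(tables, units, policy="strict"):
    g = build_graph(tables, units)
    predict_transformations(g, policy=policy)
    compute_edge_weights(g)
    return g


def test_to_light_aggregates_series_and_records(units):
    tables = {
        1: {"C10H12O5": 0.50, "C9H12O3": 0.10},
        2: {"C10H12O5": 0.40, "C9H12O3": 0.18},
        3: {"C10H12O5": 0.30, "C9H12O3": 0.25},
    }
    g = build_graph(tables, units, prune=False)
    predict_transformations(g)
    compute_edge_weights(g)
    lg = to_light(g)
    assert lg.nodes["C10H12O5"] == pytest.approx({1: 0.5, 2: 0.4, 3: 0.3})
    records = lg.edges[("C10H12O5", "C9H12O3")]
    # one aggregated edge carrying one record per transition
    assert [(r.transition, r.unit, r.predicted) for r in records] == [
        (1, "-CO2", True),
        (2, "-CO2", True),
    ]
    assert all(r.weight is not None for r in records)


def test_to_light_of_empty_graph(units):
    tables = {1: {"C16H22O2": 0.5}, 2: {"C21H24O9": 0.5}}  # no unit connects them
    g = build_graph(tables, units)
    assert g.graph.number_of_nodes() == 0
    lg = to_light(g)
    assert lg.nodes == {} and lg.edges == {}
    assert from_light(lg).graph.number_of_nodes() == 0


@pytest.mark.parametrize("policy", ["strict", "zero_fill"])
@pytest.mark.parametrize("seed", range(8))
def test_round_trip_identity(units, seed, policy):
    """from_light(to_light(g)) is structurally identical to g."""
    tables = random_peak_tables(seed=seed, n_snapshots=4)
    g = build_predicted(tables, units, policy=policy)
    assert from_light(to_light(g)) == g
    # and the light graphs agree again after a second round trip
    assert to_light(from_light(to_light(g))) == to_light(g)


def test_from_light_consistency_error():
    lg = LightGraph(
        nodes={"C10H12O5": {1: 0.5}, "C9H12O3": {2: 0.2}},
        edges={("C10H12O5", "C9H12O3"): [TransformationRecord(2, "-CO2")]},
        n_snapshots=3,
    )
    with pytest.raises(GraphBuildError, match="absent"):
        from_light(lg)


def test_duplicate_records_rejected():
    with pytest.raises(GraphBuildError, match="duplicate"):
        LightGraph(
            nodes={"C10H12O5": {1: 0.5, 2: 0.4}, "C9H12O3": {1: 0.1, 2: 0.2}},
            edges={("C10H12O5", "C9H12O3"): [
                TransformationRecord(1, "-CO2"),
                TransformationRecord(1, "-CO2", predicted=True),
            ]},
            n_snapshots=2,
        )


def test_singleton_series_yields_no_same_as():
    lg = LightGraph(
        nodes={"C10H12O5": {1: 0.5}, "C9H12O3": {2: 0.2}},
        edges={("C10H12O5", "C9H12O3"): [TransformationRecord(1, "-CO2")]},
        n_snapshots=2,
    )
    g = from_light(lg)
    assert len(g.same_as_edges()) == 0
    assert len(g.potential_edges()) == 1


# ---------------------------------------------------------------------------
# label propagation
# ---------------------------------------------------------------------------

def two_triangles() -> LightGraph:
    """Two tightly connected triads joined by one weak edge.

    Formulas are arbitrary but valid; weights come from predicted-record
    counts: 5 records inside each triad pair, 1 on the bridge.
    """
    tri1 = ["C10H12O5", "C9H12O3", "C9H12O4"]
    tri2 = ["C20H22O9", "C19H22O7", "C19H22O8"]
    nodes = {f: {1: 0.5, 2: 0.5} for f in tri1 + tri2}
    def records(n):
        return [TransformationRecord(1, f"u{i}", predicted=True) for i in range(n)]
    edges = {}
    for tri in (tri1, tri2):
        for a, b in [(0, 1), (1, 2), (0, 2)]:
            edges[(tri[a], tri[b])] = records(5)
    edges[(tri1[2], tri2[0])] = records(1)
    return LightGraph(nodes=nodes, edges=edges, n_snapshots=2)


@pytest.mark.parametrize("seed", range(10))
def test_lpa_splits_two_triangles_under_every_order(seed):
    lg = two_triangles()
    assignment = label_propagation(lg, seed=seed)
    assert assignment.converged
    clusters = assignment.clusters()
    assert len(clusters) == 2
    sizes = sorted(len(m) for m in clusters.values())
    assert sizes == [3, 3]
    members = {frozenset(m) for m in clusters.values()}
    assert frozenset(["C10H12O5", "C9H12O3", "C9H12O4"]) in members


def test_lpa_deterministic_given_seed():
    lg = two_triangles()
    a = label_propagation(lg, seed=42)
    b = label_propagation(lg, seed=42)
    assert a.labels == b.labels and a.n_iter == b.n_iter


def test_lpa_fixed_point():
    lg = two_triangles()
    a = label_propagation(lg, seed=3)
    again = label_propagation(lg, seed=99, init_labels=a.labels)
    assert again.labels == a.labels
    assert again.n_iter == 1  # first sweep already changes nothing


def test_isolated_and_zero_weight_nodes_stay_singletons():
    lg = two_triangles()
    lg.nodes["C5H8O2"] = {1: 0.1}  # no edges at all
    lg.nodes["C6H8O2"] = {1: 0.1, 2: 0.1}
    lg.edges[("C6H8O2", "C10H12O5")] = [TransformationRecord(1, "ux")]  # potential only
    assignment = label_propagation(lg, seed=0)
    clusters = assignment.clusters()
    assert ["C5H8O2"] in clusters.values()
    assert ["C6H8O2"] in clusters.values()


def test_clustering_weights_count_predicted_records_both_directions(units):
    tables = {
        1: {"C10H12O5": 0.50, "C9H12O3": 0.10},
        2: {"C10H12O5": 0.40, "C9H12O3": 0.18},
        3: {"C10H12O5": 0.30, "C9H12O3": 0.25},
    }
    g = build_predicted(tables, units)
    lg = to_light(g)
    w = clustering_weights(lg)
    pair = tuple(sorted(("C10H12O5", "C9H12O3")))
    assert w[pair] == 2
    assert lg.predicted_record_count("C9H12O3", "C10H12O5") == 2


def test_lpa_partition_covers_all_nodes():
    lg = two_triangles()
    assignment = label_propagation(lg, seed=1)
    assert set(assignment.labels) == set(lg.nodes)
    with pytest.raises(ValueError):
        label_propagation(lg, max_iter=0)
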