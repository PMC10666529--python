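"""Transition metrics, unit shares/importance, weighted descriptors,
cluster characterization."""
import numpy as np
import pytest

from domgraph.analytics import (
    cluster_report,
    group_shares,
    out_degree_histogram,
    transition_stats,
    unit_importance,
    unit_shares,
    weighted_descriptors,
)
from domgraph.formulas import descriptors, parse_formula
from domgraph.light import label_propagation, to_light
from domgraph.prediction import compute_edge_weights, predict_transformations
from domgraph.temporal import build_graph

from .conftest import random_peak_tables


@pytest.fixture()
def toy_graph(units):
    tables = {
        1: {"C10H12O5": 0.50, "C9H12O3": 0.10},
        2: {"C10H12O5": 0.40, "C9H12O3": 0.18},
    }
    g = build_graph(tables, units)
    predict_transformations(g)
    compute_edge_weights(g)
    return g


def test_transition_stats_toy(toy_graph):
    stats = transition_stats(toy_graph)
    row = stats.loc[1]
    assert row["same_as"] == 2
    assert row["potential"] >= 1
    assert row["predicted"] == 1
    assert row["increasing"] == 1 and row["decreasing"] == 1 and row["consistent"] == 0
    assert row["mean_predicted_per_molecule"] == pytest.approx(1 / 2)


@pytest.mark.parametrize("seed", range(4))
def test_trend_counts_partition_same_as(units, seed):
    tables = random_peak_tables(seed=seed, n_snapshots=4)
    g = build_graph(tables, units)
    predict_transformations(g)
    stats = transition_stats(g)
    for t in g.transitions:
        row = stats.loc[t]
        assert row["increasing"] + row["decreasing"] + row["consistent"] == row["same_as"]
        assert row["predicted"] <= row["potential"]


def test_stats_without_predictions_report_zeros(units):
    tables = {1: {"C10H12O5": 0.5, "C9H12O3": 0.1},
              2: {"C10H12O5": 0.5, "C9H12O3": 0.1}}
    g = build_graph(tables, units)
    stats = transition_stats(g)
    assert stats.loc[1, "predicted"] == 0
    assert stats.loc[1, "mean_predicted_per_molecule"] == 0.0


def test_out_degree_histogram_sums_to_node_count(units):
    tables = random_peak_tables(seed=5, n_snapshots=4)
    g = build_graph(tables, units)
    predict_transformations(g, policy="zero_fill")
    hist = out_degree_histogram(g)
    for t in g.transitions:
        sub = hist[hist["transition"] == t]
        assert sub["count"].sum() == len(g.detected_formulas_at(t))


def test_unit_shares_counting(units):
    # transition 1 carries two -CO2 predictions and one +O prediction
    tables = {
        1: {"C10H12O5": 0.50, "C9H12O3": 0.10, "C8H10O4": 0.40,
            "C7H10O2": 0.10, "C12H14O3": 0.30},
        2: {"C10H12O5": 0.40, "C9H12O3": 0.18, "C8H10O4": 0.30,
            "C7H10O2": 0.18, "C12H14O3": 0.20, "C12H14O4": 0.30},
    }
    g = build_graph(tables, units)
    predicted = predict_transformations(g, policy="zero_fill")
    by_unit = {}
    for _, _, _, u in predicted:
        by_unit[u] = by_unit.get(u, 0) + 1
    assert by_unit == {"-CO2": 2, "+O": 1}

    shares = unit_shares(g, units)
    assert shares.per_transition.loc[1, "-CO2"] == pytest.approx(2 / 3)
    assert shares.per_transition.loc[1, "+O"] == pytest.approx(1 / 3)
    # shares over the full tabulation sum to 1, so the grand mean is 1/K
    assert shares.per_transition.loc[1].sum() == pytest.approx(1.0)
    assert shares.grand_mean == pytest.approx(1 / len(units))


def test_unit_shares_relative_change_and_undefined_flag(units):
    tables = {
        1: {"C10H12O5": 0.50, "C9H12O3": 0.10},
        2: {"C10H12O5": 0.40, "C9H12O3": 0.18, "C8H10O4": 0.40, "C7H10O2": 0.10},
        3: {"C8H10O4": 0.30, "C7H10O2": 0.18, "C9H12O3": 0.10},
    }
    g = build_graph(tables, units)
    predict_transformations(g)
    shares = unit_shares(g, units)
    # -CO2 carries all predictions in the first transition but shares the
    # last transition with a ketene elimination: share drops 1.0 -> 0.5
    assert shares.relative_change["-CO2"] == pytest.approx(-50.0)
    # units with zero share in the first transition have undefined change
    assert "+O" in shares.undefined_change
    assert np.isnan(shares.relative_change["+O"])


def test_unit_shares_requires_predictions(units):
    tables = {1: {"C10H12O5": 0.5, "C9H12O3": 0.1},
              2: {"C10H12O5": 0.5, "C9H12O3": 0.1}}
    g = build_graph(tables, units)
    predict_transformations(g)
    with pytest.raises(ValueError, match="no predicted"):
        unit_shares(g, units)


def test_group_shares_rollup(units):
    tables = {
        1: {"C10H12O5": 0.50, "C9H12O3": 0.10, "C12H14O3": 0.30},
        2: {"C10H12O5": 0.40, "C9H12O3": 0.18, "C12H14O3": 0.20, "C12H14O4": 0.30},
    }
    g = build_graph(tables, units)
    predict_transformations(g, policy="zero_fill")
    shares = unit_shares(g, units)
    rollup = group_shares(shares, units)
    assert rollup.loc[1].sum() == pytest.approx(1.0)
    assert rollup.loc[1, "photo_addition"] == pytest.approx(1 / 2)  # the +O edge
    assert rollup.loc[1, "photo_elimination"] == pytest.approx(1 / 2)


def test_unit_importance(units):
    tables = {
        1: {"C10H12O5": 0.50, "C9H12O3": 0.10, "C9H12O4": 0.10},
        2: {"C10H12O5": 0.40, "C9H12O3": 0.18, "C9H12O4": 0.14},
    }
    g = build_graph(tables, units)
    predict_transformations(g)
    compute_edge_weights(g)
    imp = unit_importance(g, units)
    # weights 0.065 (-CO2) and 0.045 (-CO) normalize to 0.591 / 0.409
    assert imp.loc[1, "-CO2"] == pytest.approx(0.065 / 0.11)
    assert imp.loc[1, "-CO"] == pytest.approx(0.045 / 0.11)
    assert imp.loc[1].sum() == pytest.approx(1.0)


def test_unit_importance_single_unit_and_missing_weights(toy_graph, units):
    imp = unit_importance(toy_graph, units)
    assert imp.loc[1, "-CO2"] == pytest.approx(1.0)

    tables = {1: {"C10H12O5": 0.5, "C9H12O3": 0.1},
              2: {"C10H12O5": 0.4, "C9H12O3": 0.18}}
    g = build_graph(tables, units)
    predict_transformations(g)
    with pytest.raises(ValueError, match="weights"):
        unit_importance(g, units)


def test_weighted_descriptors(units):
    f1, f2 = "C10H12O5", "C9H12O3"
    tables = {1: {f1: 0.75, f2: 0.25}, 2: {f1: 0.5, f2: 0.5}}
    g = build_graph(tables, units)
    wd = weighted_descriptors(g)
    m1, m2 = parse_formula(f1).mass, parse_formula(f2).mass
    assert wd.loc[1, "mw"] == pytest.approx(0.75 * m1 + 0.25 * m2)
    # uniform intensities reduce to the arithmetic mean
    assert wd.loc[2, "mw"] == pytest.approx((m1 + m2) / 2)
    d1, d2 = descriptors(parse_formula(f1)), descriptors(parse_formula(f2))
    assert wd.loc[2, "hc"] == pytest.approx((d1.hc + d2.hc) / 2)


def test_cluster_report_hand_built(units):
    # two disconnected reaction pairs form two natural clusters
    tables = {
        1: {"C10H12O5": 0.50, "C9H12O3": 0.10,
            "C15H19NO6": 0.50, "C15H18O7": 0.10},
        2: {"C10H12O5": 0.40, "C9H12O3": 0.18,
            "C15H19NO6": 0.40, "C15H18O7": 0.18},
    }
    g = build_graph(tables, units)
    predict_transformations(g)
    compute_edge_weights(g)
    lg = to_light(g)
    assignment = label_propagation(lg, seed=0)
    report = cluster_report(assignment, g, lg, units)

    assert report.summary["size"].sum() == len(lg.nodes)
    assert sorted(report.summary["size"]) == [2, 2]
    assert report.boundary_records == 0
    # the CHNO-containing pair is separable by composition
    chno = report.summary[report.summary["frac_CHNO"] > 0]
    assert len(chno) == 1 and chno.iloc[0]["frac_CHNO"] == pytest.approx(0.5)
    for lab, s in report.unit_shares.items():
        if lab not in report.empty_unit_shares:
            assert s.sum() == pytest.approx(1.0)


def test_cluster_mean_trend_near_one_for_symmetric_transfers(units):
    # loss of the educt equals the gain of the product: trends 0.9 and 1.1
    tables = {
        1: {"C10H12O5": 1.00, "C9H12O3": 1.00},
        2: {"C10H12O5": 0.90, "C9H12O3": 1.10},
    }
    g = build_graph(tables, units)
    predict_transformations(g)
    lg = to_light(g)
    assignment = label_propagation(lg, seed=0)
    report = cluster_report(assignment, g, lg, units)
    trends = report.summary["mean_intensity_trend"].dropna()
    assert len(trends) >= 1
    assert np.allclose(trends, 1.0, atol=1e-9)


def test_cluster_report_rejects_unknown_formula(units, toy_graph):
    lg = to_light(toy_graph)
    assignment = label_propagation(lg, seed=0)
    assignment.labels["C99H99O9"] = 0
    with pytest.raises(ValueError, match="unknown formula"):
        cluster_report(assignment, toy_graph, lg, units)
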