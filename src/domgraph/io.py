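"""File formats: peak tables, graph exports/imports, run reports.

Peak tables are comma-separated UTF-8 text with a required header::

    molecular_formula,C,H,N,O,S,snapshot,normalized_intensity

Element columns are validated against the parsed formula string row by row.
Graph exports cover GraphML, a node/edge table pair suitable for bulk
graph-database import, and a text script of graph-creation statements; each
exporter has a matching importer that round-trips structurally.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
import pandas as pd

from .formulas import parse_formula
from .light import LightGraph, TransformationRecord
from .temporal import PREDICTED, POTENTIAL, SAME_AS, GraphBuildError, TemporalGraph

__all__ = [
    "PeakTableError",
    "read_peak_tables",
    "write_peak_tables",
    "export_graph",
    "import_graph",
    "export_light",
    "import_light",
    "write_run_report",
]

REQUIRED_COLUMNS = [
    "molecular_formula", "C", "H", "N", "O", "S", "snapshot", "normalized_intensity",
]


class PeakTableError(ValueError):
    pass


def read_peak_tables(
    paths: Union[str, Path, Iterable[Union[str, Path]]],
) -> dict[int, dict[str, float]]:
    """Read one or several peak-table CSV files into per-snapshot maps.

    Accepts a single file holding all snapshots or one file per snapshot.
    Validates the header, element-count/formula agreement, duplicate
    (formula, snapshot) rows, and consecutive 1-based snapshot indices.
    Extra columns (e.g. dose metadata) are ignored here.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for p in paths:
        p = Path(p)
        df = pd.read_csv(p)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise PeakTableError(f"{p}: missing required column(s) {missing}")
        df["__source__"] = str(p)
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)

    tables: dict[int, dict[str, float]] = {}
    for i, row in df.iterrows():
        loc = f"{row['__source__']} row {i + 2}"  # 1-based + header line
        try:
            mf = parse_formula(str(row["molecular_formula"]))
        except ValueError as exc:
            raise PeakTableError(f"{loc}: {exc}") from exc
        for col in ("C", "H", "N", "O", "S"):
            if int(row[col]) != mf.elements.count(col):
                raise PeakTableError(
                    f"{loc}: column {col}={int(row[col])} contradicts formula "
                    f"{mf.canonical} ({col}={mf.elements.count(col)})"
                )
        t = int(row["snapshot"])
        inten = float(row["normalized_intensity"])
        table = tables.setdefault(t, {})
        if mf.canonical in table:
            raise PeakTableError(f"{loc}: duplicate ({mf.canonical}, snapshot {t})")
        table[mf.canonical] = inten

    snaps = sorted(tables)
    if snaps != list(range(1, len(snaps) + 1)):
        raise PeakTableError(f"snapshot indices must be consecutive from 1, got {snaps}")
    return tables


def write_peak_tables(tables: dict[int, dict[str, float]], path: Union[str, Path]) -> Path:
    """Write per-snapshot maps as a single peak-table CSV."""
    rows = []
    for t in sorted(tables):
        for formula in sorted(tables[t]):
            mf = parse_formula(formula)
            ev = mf.elements
            rows.append(
                {
                    "molecular_formula": mf.canonical,
                    "C": ev.c, "H": ev.h, "N": ev.n, "O": ev.o, "S": ev.s,
                    "snapshot": t,
                    "normalized_intensity": tables[t][formula],
                }
            )
    path = Path(path)
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# temporal graph export / import
# ---------------------------------------------------------------------------

def _edge_frame(g: TemporalGraph) -> pd.DataFrame:
    rows = []
    for u, v, d in g.graph.edges(data=True):
        rows.append(
            {
                "from_formula": u[0], "from_snapshot": u[1],
                "to_formula": v[0], "to_snapshot": v[1],
                "kind": d["kind"],
                "unit": d.get("unit", ""),
                "trend": d.get("trend", ""),
                "weight": "" if d.get("weight") is None else d["weight"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["from_formula", "from_snapshot", "to_formula", "to_snapshot",
                 "kind", "unit", "trend", "weight"],
    )


def _node_frame(g: TemporalGraph) -> pd.DataFrame:
    rows = [
        {"molecular_formula": f, "snapshot": t, "normalized_intensity": d["intensity"]}
        for (f, t), d in g.graph.nodes(data=True)
    ]
    return pd.DataFrame(rows, columns=["molecular_formula", "snapshot", "normalized_intensity"])


def export_graph(
    g: TemporalGraph, path: Union[str, Path], format: str = "graphml"
) -> list[Path]:
    """Export a temporal graph.

    ``graphml`` writes a single file; ``node_edge_tables`` writes
    ``<path>.nodes.csv`` and ``<path>.edges.csv``; ``cypher_script`` writes a
    text script of CREATE statements for bulk import into a graph database.
    Returns the written paths.
    """
    path = Path(path)
    if format == "graphml":
        h = nx.MultiDiGraph(n_snapshots=g.n_snapshots)
        for (f, t), d in g.graph.nodes(data=True):
            h.add_node(f"{f}@{t}", formula=f, snapshot=t, intensity=d["intensity"])
        for u, v, d in g.graph.edges(data=True):
            attrs = {"kind": d["kind"]}
            if "unit" in d:
                attrs["unit"] = d["unit"]
            if "trend" in d:
                attrs["trend"] = d["trend"]
            if d.get("weight") is not None:
                attrs["weight"] = d["weight"]
            h.add_edge(f"{u[0]}@{u[1]}", f"{v[0]}@{v[1]}", **attrs)
        nx.write_graphml(h, path)
        return [path]
    if format == "node_edge_tables":
        npath = path.with_suffix(path.suffix + ".nodes.csv")
        epath = path.with_suffix(path.suffix + ".edges.csv")
        _node_frame(g).to_csv(npath, index=False)
        _edge_frame(g).to_csv(epath, index=False)
        return [npath, epath]
    if format == "cypher_script":
        lines = ["// graph-creation script generated by domgraph"]
        for (f, t), d in sorted(g.graph.nodes(data=True)):
            props = {"molecular_formula": f, "snapshot": t,
                     "normalized_intensity": d["intensity"]}
            lines.append(f"CREATE (:Molecule {json.dumps(props)});")
        label = {SAME_AS: "SAME_AS", POTENTIAL: "POTENTIAL_TRANSFORMATION",
                 PREDICTED: "PREDICTED_TRANSFORMATION"}
        for u, v, d in sorted(g.graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["kind"], e[2].get("unit", ""))):
            props = {k: d[k] for k in ("unit", "trend", "weight") if d.get(k) not in (None, "")}
            lines.append(
                "MATCH (a:Molecule {molecular_formula: %s, snapshot: %d}), "
                "(b:Molecule {molecular_formula: %s, snapshot: %d}) "
                "CREATE (a)-[:%s %s]->(b);"
                % (json.dumps(u[0]), u[1], json.dumps(v[0]), v[1],
                   label[d["kind"]], json.dumps(props))
            )
        lines.append(f"// n_snapshots={g.n_snapshots}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return [path]
    raise ValueError(f"unknown export format {format!r}")


def import_graph(path: Union[str, Path], format: str = "graphml",
                 n_snapshots: Optional[int] = None) -> TemporalGraph:
    """Re-read a temporal graph written by :func:`export_graph`."""
    path = Path(path)
    g = nx.MultiDiGraph()
    if format == "graphml":
        h = nx.read_graphml(path, force_multigraph=True)
        n_snapshots = int(h.graph["n_snapshots"])
        for _, d in h.nodes(data=True):
            f, t = d["formula"], int(d["snapshot"])
            g.add_node((f, t), formula=parse_formula(f), snapshot=t,
                       intensity=float(d["intensity"]))
        for u, v, d in h.edges(data=True):
            fu, tu = u.rsplit("@", 1)
            fv, tv = v.rsplit("@", 1)
            attrs = {"kind": d["kind"]}
            if "unit" in d:
                attrs["unit"] = d["unit"]
            if "trend" in d:
                attrs["trend"] = float(d["trend"])
            if d["kind"] == PREDICTED:
                attrs["weight"] = float(d["weight"]) if "weight" in d else None
            g.add_edge((fu, int(tu)), (fv, int(tv)), **attrs)
        return TemporalGraph(graph=g, n_snapshots=n_snapshots)
    if format == "node_edge_tables":
        npath = path.with_suffix(path.suffix + ".nodes.csv")
        epath = path.with_suffix(path.suffix + ".edges.csv")
        nodes = pd.read_csv(npath)
        edges = pd.read_csv(epath)
        for row in nodes.itertuples(index=False):
            f, t = row.molecular_formula, int(row.snapshot)
            g.add_node((f, t), formula=parse_formula(f), snapshot=t,
                       intensity=float(row.normalized_intensity))
        for row in edges.itertuples(index=False):
            attrs = {"kind": row.kind}
            if isinstance(row.unit, str) and row.unit:
                attrs["unit"] = row.unit
            if not pd.isna(row.trend) and row.trend != "":
                attrs["trend"] = float(row.trend)
            if row.kind == PREDICTED:
                attrs["weight"] = None if pd.isna(row.weight) else float(row.weight)
            g.add_edge(
                (row.from_formula, int(row.from_snapshot)),
                (row.to_formula, int(row.to_snapshot)), **attrs
            )
        if n_snapshots is None:
            n_snapshots = int(nodes["snapshot"].max()) if len(nodes) else 0
        return TemporalGraph(graph=g, n_snapshots=n_snapshots)
    if format == "cypher_script":
        return _import_cypher(path)
    raise ValueError(f"unknown import format {format!r}")


_CY_NODE = re.compile(r"^CREATE \(:Molecule (\{.*\})\);$")
_CY_EDGE = re.compile(
    r"^MATCH \(a:Molecule \{molecular_formula: (.*), snapshot: (\d+)\}\), "
    r"\(b:Molecule \{molecular_formula: (.*), snapshot: (\d+)\}\) "
    r"CREATE \(a\)-\[:(\w+) (\{.*\})\]->\(b\);$"
)


def _import_cypher(path: Path) -> TemporalGraph:
    """Parse the restricted graph-creation dialect emitted by this package."""
    g = nx.MultiDiGraph()
    n_snapshots = 0
    kind_of = {"SAME_AS": SAME_AS, "POTENTIAL_TRANSFORMATION": POTENTIAL,
               "PREDICTED_TRANSFORMATION": PREDICTED}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("// n_snapshots="):
            n_snapshots = int(line.split("=", 1)[1])
            continue
        m = _CY_NODE.match(line)
        if m:
            props = json.loads(m.group(1))
            f, t = props["molecular_formula"], int(props["snapshot"])
            g.add_node((f, t), formula=parse_formula(f), snapshot=t,
                       intensity=float(props["normalized_intensity"]))
            continue
        m = _CY_EDGE.match(line)
        if m:
            fa, ta, fb, tb = json.loads(m.group(1)), int(m.group(2)), json.loads(m.group(3)), int(m.group(4))
            props = json.loads(m.group(6))
            attrs = {"kind": kind_of[m.group(5)]}
            attrs.update(props)
            if attrs["kind"] == PREDICTED and "weight" not in attrs:
                attrs["weight"] = None
            g.add_edge((fa, ta), (fb, tb), **attrs)
    return TemporalGraph(graph=g, n_snapshots=n_snapshots)


# ---------------------------------------------------------------------------
# light graph export / import
# ---------------------------------------------------------------------------

def export_light(lg: LightGraph, path: Union[str, Path], format: str = "graphml") -> list[Path]:
    """Export a light graph (GraphML with JSON-serialized series/records, or a
    node/edge table pair)."""
    path = Path(path)
    if format == "graphml":
        h = nx.DiGraph(n_snapshots=lg.n_snapshots)
        for f, series in lg.nodes.items():
            h.add_node(f, series=json.dumps({str(t): i for t, i in sorted(series.items())}))
        for (a, b), records in lg.edges.items():
            h.add_edge(a, b, records=json.dumps(
                [[r.transition, r.unit, r.predicted, r.weight] for r in sorted(records)]
            ))
        nx.write_graphml(h, path)
        return [path]
    if format == "node_edge_tables":
        npath = path.with_suffix(path.suffix + ".nodes.csv")
        epath = path.with_suffix(path.suffix + ".edges.csv")
        nrows = [
            {"molecular_formula": f,
             "series": json.dumps({str(t): i for t, i in sorted(series.items())})}
            for f, series in sorted(lg.nodes.items())
        ]
        erows = [
            {"educt": a, "product": b,
             "records": json.dumps([[r.transition, r.unit, r.predicted, r.weight]
                                    for r in sorted(records)])}
            for (a, b), records in sorted(lg.edges.items())
        ]
        pd.DataFrame(nrows, columns=["molecular_formula", "series"]).to_csv(npath, index=False)
        pd.DataFrame(erows, columns=["educt", "product", "records"]).to_csv(epath, index=False)
        return [npath, epath]
    raise ValueError(f"unknown export format {format!r}")


def _records_from_json(payload: str) -> list[TransformationRecord]:
    return [
        TransformationRecord(transition=int(t), unit=u, predicted=bool(p),
                             weight=None if w is None else float(w))
        for t, u, p, w in json.loads(payload)
    ]


def import_light(path: Union[str, Path], format: str = "graphml") -> LightGraph:
    path = Path(path)
    if format == "graphml":
        h = nx.read_graphml(path)
        nodes = {
            f: {int(t): float(i) for t, i in json.loads(d["series"]).items()}
            for f, d in h.nodes(data=True)
        }
        edges = {(a, b): _records_from_json(d["records"]) for a, b, d in h.edges(data=True)}
        return LightGraph(nodes=nodes, edges=edges, n_snapshots=int(h.graph["n_snapshots"]))
    if format == "node_edge_tables":
        npath = path.with_suffix(path.suffix + ".nodes.csv")
        epath = path.with_suffix(path.suffix + ".edges.csv")
        ndf, edf = pd.read_csv(npath), pd.read_csv(epath)
        nodes = {
            row.molecular_formula: {int(t): float(i) for t, i in json.loads(row.series).items()}
            for row in ndf.itertuples(index=False)
        }
        edges = {
            (row.educt, row.product): _records_from_json(row.records)
            for row in edf.itertuples(index=False)
        }
        n_snap = max((max(s) for s in nodes.values()), default=0)
        return LightGraph(nodes=nodes, edges=edges, n_snapshots=n_snap)
    raise ValueError(f"unknown import format {format!r}")


def write_run_report(path: Union[str, Path], **fields) -> Path:
    """Write the structured run report (one JSON document per run) recording
    seeds, margin, policy, unit-table checksum and any extra fields."""
    path = Path(path)
    path.write_text(json.dumps(fields, indent=2, sort_keys=True, default=str) + "\n",
                    encoding="utf-8")
    return path
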