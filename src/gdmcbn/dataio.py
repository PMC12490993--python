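"""Readers and writers for the pipeline's file formats.

* datasets: CSV, header = variable names, cells = state codes, missing
  is the literal string ``"99"`` (codes are labels, never numbers);
* graphs: two/three-column edge-list CSV (``parent,child[,orientation]``
  with orientation ``directed``/``undirected``), plus DOT and GraphML
  export;
* Bayesian networks: XMLBIF, so fitted models can be opened in
  standard BN tools.

Readers validate and reject rather than coerce; every writer/reader
pair round-trips exactly on valid objects.
"""

from __future__ import annotations

import csv
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .cbn import Cbn, Cpt
from .dataset import DiscreteDataset
from .graphs import Dag, Pdag
from .schema import VariableSpec

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_edge_list",
    "write_graph",
    "write_cbn",
    "read_cbn",
]


# ------------------------------------------------------------------ datasets

def read_dataset(path: str | Path, schema: list[VariableSpec]) -> DiscreteDataset:
    """Read a cohort CSV; columns may appear in any order."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.empty:
        raise ValueError(f"{path}: empty dataset")
    return DiscreteDataset.from_frame(frame, schema)


def write_dataset(data: DiscreteDataset, path: str | Path) -> None:
    data.to_frame().to_csv(path, index=False)


# ------------------------------------------------------------------ graphs

def read_edge_list(path: str | Path) -> Pdag:
    """Parse ``parent,child[,orientation]`` CSV into a Pdag.

    Nodes are inferred from edge endpoints.  Duplicate rows collapse
    with a warning; contradictory duplicates (both orientations of the
    same pair given as directed, or the same pair both directed and
    undirected) are an error, as are self-loops.
    """
    graph = Pdag()
    seen_directed: set[tuple[str, str]] = set()
    seen_undirected: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            row = [c.strip() for c in row if c.strip() != ""]
            if not row:
                continue
            if lineno == 1 and row[0].lower() in ("parent", "from", "source"):
                continue  # header
            if len(row) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2-3 columns, got {row}")
            u, v = row[0], row[1]
            kind = row[2].lower() if len(row) == 3 else "directed"
            if kind not in ("directed", "undirected"):
                raise ValueError(f"{path}:{lineno}: unknown orientation {row[2]!r}")
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop on {u!r}")
            pair = (u, v) if u <= v else (v, u)
            if kind == "directed":
                if (u, v) in seen_directed:
                    warnings.warn(f"{path}:{lineno}: duplicate edge {u}->{v} collapsed")
                    continue
                if (v, u) in seen_directed:
                    raise ValueError(
                        f"{path}:{lineno}: contradictory orientations for ({u},{v})"
                    )
                if pair in seen_undirected:
                    raise ValueError(
                        f"{path}:{lineno}: pair ({u},{v}) given both directed and undirected"
                    )
                graph.add_directed(u, v)
                seen_directed.add((u, v))
            else:
                if pair in seen_undirected:
                    warnings.warn(f"{path}:{lineno}: duplicate edge {u}--{v} collapsed")
                    continue
                if (u, v) in seen_directed or (v, u) in seen_directed:
                    raise ValueError(
                        f"{path}:{lineno}: pair ({u},{v}) given both directed and undirected"
                    )
                graph.add_undirected(u, v)
                seen_undirected.add(pair)
    return graph


def write_graph(graph: Pdag, path: str | Path, format: str = "edge_csv") -> None:
    """Write a graph as edge-list CSV, DOT, or GraphML.

    ``edge_csv`` round-trips through :func:`read_edge_list` except that
    isolated nodes are not representable in an edge list; DOT and
    GraphML render all nodes including isolates.
    """
    path = Path(path)
    if format == "edge_csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["parent", "child", "orientation"])
            for u, v in sorted(graph.directed):
                w.writerow([u, v, "directed"])
            for u, v in sorted(graph.undirected):
                w.writerow([u, v, "undirected"])
    elif format == "dot":
        lines = ["digraph G {"]
        for v in sorted(graph.nodes):
            lines.append(f'  "{v}";')
        for u, v in sorted(graph.directed):
            lines.append(f'  "{u}" -> "{v}";')
        for u, v in sorted(graph.undirected):
            lines.append(f'  "{u}" -> "{v}" [dir=none];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(sorted(graph.nodes))
        g.add_edges_from(sorted(graph.directed), orientation="directed")
        g.add_edges_from(sorted(graph.undirected), orientation="undirected")
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ------------------------------------------------------------------ XMLBIF

def write_cbn(cbn: Cbn, path: str | Path) -> None:
    """Serialise a CBN as XMLBIF 0.3.

    TABLE entries are row-major over parent configurations in the
    CPT's parent order (first listed parent most significant), with
    the child's states varying fastest — matching the CPT layout.
    """
    bif = ET.Element("BIF", VERSION="0.3")
    net = ET.SubElement(bif, "NETWORK")
    ET.SubElement(net, "NAME").text = "network"
    for node in sorted(cbn.dag.nodes):
        var = ET.SubElement(net, "VARIABLE", TYPE="nature")
        ET.SubElement(var, "NAME").text = node
        for s in cbn.states[node]:
            ET.SubElement(var, "OUTCOME").text = s
    for node in sorted(cbn.dag.nodes):
        cpt = cbn.cpts[node]
        d = ET.SubElement(net, "DEFINITION")
        ET.SubElement(d, "FOR").text = node
        for p in cpt.parents:
            ET.SubElement(d, "GIVEN").text = p
        ET.SubElement(d, "TABLE").text = " ".join(
            format(x, ".17g") for x in cpt.table.reshape(-1)
        )
    ET.indent(bif)
    ET.ElementTree(bif).write(path, encoding="unicode", xml_declaration=True)


def read_cbn(path: str | Path) -> Cbn:
    """Read an XMLBIF 0.3 network; CPT rows are validated to sum to 1."""
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed XMLBIF: {exc}") from exc
    net = root.find("NETWORK")
    if net is None:
        raise ValueError(f"{path}: no NETWORK element")
    states: dict[str, tuple[str, ...]] = {}
    for var in net.findall("VARIABLE"):
        name = var.findtext("NAME")
        outcomes = tuple(o.text for o in var.findall("OUTCOME"))
        if name is None or len(outcomes) < 1:
            raise ValueError(f"{path}: VARIABLE without name or outcomes")
        states[name] = outcomes
    edges: list[tuple[str, str]] = []
    cpts: dict[str, Cpt] = {}
    for d in net.findall("DEFINITION"):
        node = d.findtext("FOR")
        parents = tuple(g.text for g in d.findall("GIVEN"))
        if node not in states:
            raise ValueError(f"{path}: DEFINITION for unknown variable {node!r}")
        table_text = d.findtext("TABLE") or ""
        values = np.array([float(x) for x in table_text.split()])
        q = 1
        for p in parents:
            if p not in states:
                raise ValueError(f"{path}: unknown parent {p!r} of {node!r}")
            q *= len(states[p])
        r = len(states[node])
        if values.size != q * r:
            raise ValueError(
                f"{path}: {node!r} TABLE has {values.size} entries, expected {q * r}"
            )
        table = values.reshape(q, r)
        sums = table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"{path}: {node!r} CPT rows do not sum to 1")
        cpts[node] = Cpt(node, parents, table)
        edges.extend((p, node) for p in parents)
    if set(cpts) != set(states):
        missing = sorted(set(states) - set(cpts))
        raise ValueError(f"{path}: variables without DEFINITION: {missing}")
    dag = Dag(set(states), edges)
    return Cbn(dag, cpts, states)
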