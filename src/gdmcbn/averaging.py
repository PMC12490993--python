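"""Majority-vote fusion of a graph ensemble into one consensus DAG.

Edges are tallied across the ensemble and inserted into the average
graph in descending occurrence order, subject to a minimum-count
threshold (default: an edge must appear in at least 4 of the learnt
structures).  Acyclicity takes precedence over majority directionality:
an edge whose insertion would close a cycle is reversed and the
reversal recorded, so the output is always a DAG.  Every skip and
reversal is written to an audit log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .graphs import Dag, Pdag

__all__ = ["EdgeFrequencyTable", "AuditEntry", "count_edges", "average_graphs", "threshold_sweep"]

DEFAULT_THRESHOLD = 4


@dataclass
class EdgeFrequencyTable:
    """Per-edge occurrence counts across ``n_models`` learned graphs."""

    directed_counts: dict[tuple[str, str], int]
    undirected_counts: dict[tuple[str, str], int]
    n_models: int
    nodes: set[str] = field(default_factory=set)

    def __post_init__(self):
        for cnt in (*self.directed_counts.values(), *self.undirected_counts.values()):
            if not (1 <= cnt <= self.n_models):
                raise ValueError(f"count {cnt} outside [1, {self.n_models}]")
        for u, v in self.directed_counts:
            self.nodes.update((u, v))
        for u, v in self.undirected_counts:
            self.nodes.update((u, v))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parent": u, "child": v, "orientation": "directed", "count": c}
            for (u, v), c in sorted(self.directed_counts.items())
        ] + [
            {"parent": u, "child": v, "orientation": "undirected", "count": c}
            for (u, v), c in sorted(self.undirected_counts.items())
        ]
        return pd.DataFrame(rows, columns=["parent", "child", "orientation", "count"])


def count_edges(graphs: list[Pdag]) -> EdgeFrequencyTable:
    """Tally directed and undirected edge occurrences over an ensemble.

    Both orientations of a pair are tallied separately; a graph
    contributes at most 1 to any given edge.
    """
    if not graphs:
        raise ValueError("empty ensemble")
    directed: dict[tuple[str, str], int] = {}
    undirected: dict[tuple[str, str], int] = {}
    nodes: set[str] = set()
    for g in graphs:
        nodes |= g.nodes
        for e in g.directed:
            directed[e] = directed.get(e, 0) + 1
        for u, v in g.undirected:
            key = (u, v) if u <= v else (v, u)
            undirected[key] = undirected.get(key, 0) + 1
    return EdgeFrequencyTable(directed, undirected, len(graphs), nodes)


@dataclass(frozen=True)
class AuditEntry:
    step: int          # 1 = directed pass, 2 = undirected pass, 3 = deferred pass
    edge: tuple[str, str]
    count: int
    action: str        # "added" | "reversed" | "skipped"
    rule: str

    def to_dict(self) -> dict:
        return {"step": self.step, "edge": list(self.edge), "count": self.count,
                "action": self.action, "rule": self.rule}


def average_graphs(
    table: EdgeFrequencyTable, threshold: int = DEFAULT_THRESHOLD
) -> tuple[Dag, list[AuditEntry]]:
    """Fuse the frequency table into one DAG via the four-step procedure.

    1. Insert directed edges by descending count; skip an edge whose
       reverse is already present; reverse-then-add an edge that would
       close a cycle.
    2. Insert surviving undirected edges by descending count, skipped
       if the pair is already directed, otherwise oriented toward the
       direction with the higher directed count (lexicographic on
       ties) and inserted under the same cycle rule.
    3. Re-examine the edges deferred in step 1 (reverse already
       present) by descending count; with this reading they remain
       excluded, and the audit log records why.

    Edges below the threshold never enter.  Ties between equal-count
    edges are processed in lexicographic (parent, child) order.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    dag = Dag(set(table.nodes))
    audit: list[AuditEntry] = []
    deferred: list[tuple[int, str, str]] = []

    directed = sorted(
        ((c, u, v) for (u, v), c in table.directed_counts.items() if c >= threshold),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    for c, u, v in directed:
        if (v, u) in dag.directed:
            audit.append(AuditEntry(1, (u, v), c, "skipped", "reverse already present"))
            deferred.append((c, u, v))
        elif dag.has_directed_path(v, u):
            dag.add_directed(v, u)
            audit.append(AuditEntry(1, (u, v), c, "reversed", "cycle, reversed"))
        else:
            dag.add_directed(u, v)
            audit.append(AuditEntry(1, (u, v), c, "added", "directed insertion"))

    undirected = sorted(
        ((c, u, v) for (u, v), c in table.undirected_counts.items() if c >= threshold),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    for c, u, v in undirected:
        if (u, v) in dag.directed or (v, u) in dag.directed:
            audit.append(AuditEntry(2, (u, v), c, "skipped", "already added as directed"))
            continue
        fwd = table.directed_counts.get((u, v), 0)
        rev = table.directed_counts.get((v, u), 0)
        a, b = (u, v) if fwd >= rev else (v, u)
        if dag.has_directed_path(b, a):
            dag.add_directed(b, a)
            audit.append(AuditEntry(2, (u, v), c, "reversed", "cycle, reversed"))
        else:
            dag.add_directed(a, b)
            audit.append(AuditEntry(2, (u, v), c, "added",
                                    f"undirected, oriented {a}->{b}"))

    for c, u, v in sorted(deferred, key=lambda t: (-t[0], t[1], t[2])):
        audit.append(AuditEntry(3, (u, v), c, "skipped", "pair already adjacent"))
    return dag, audit


def threshold_sweep(
    table: EdgeFrequencyTable,
    thresholds: list[int],
    watched_edges: list[tuple[str, str]],
) -> pd.DataFrame:
    """Retention matrix: is each watched edge kept at each cut-off?

    Rows are watched edges, columns thresholds, cells "Yes"/"No".
    Watched edges over unknown nodes are flagged and reported "No"
    everywhere.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for u, v in watched_edges:
        known = u in table.nodes and v in table.nodes
        row: dict[str, object] = {
            "edge": f"{u} -> {v}" if known else f"{u} -> {v} (unknown nodes)"
        }
        for t in thresholds:
            if not known:
                row[f">={t}"] = "No"
                continue
            dag, _ = average_graphs(table, t)
            row[f">={t}"] = "Yes" if (u, v) in dag.directed else "No"
        rows.append(row)
    return pd.DataFrame(rows, columns=["edge", *[f">={t}" for t in thresholds]])
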