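"""Partially directed and directed acyclic graph containers.

A :class:`Pdag` holds a node set plus disjoint sets of directed and
undirected edges (the output of constraint-based learners is a CPDAG,
which is a Pdag).  A :class:`Dag` is a Pdag with no undirected edges and
a topological order.  Both are thin, validated containers; algorithmic
work (cycle checks, components, traversal) delegates to networkx.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import networkx as nx

__all__ = ["Pdag", "Dag", "CycleError"]


class CycleError(ValueError):
    """Raised when a graph required to be acyclic contains a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__(f"directed cycle: {' -> '.join(self.cycle + self.cycle[:1])}")


def _norm_pair(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class Pdag:
    """Graph with directed and undirected edges, no self-loops.

    Invariants enforced on construction:

    * no self-loops;
    * a node pair appears at most once across the directed (either
      orientation) and undirected edge sets.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        directed: Iterable[tuple[str, str]] = (),
        undirected: Iterable[tuple[str, str]] = (),
    ):
        self.nodes: set[str] = set(nodes)
        self.directed: set[tuple[str, str]] = set()
        self.undirected: set[tuple[str, str]] = set()
        for u, v in directed:
            self.add_directed(u, v)
        for u, v in undirected:
            self.add_undirected(u, v)

    # -- mutation -----------------------------------------------------
    def add_node(self, v: str) -> None:
        self.nodes.add(v)

    def add_directed(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop {u!r}")
        if (v, u) in self.directed:
            raise ValueError(f"edge {u}->{v} contradicts existing {v}->{u}")
        if _norm_pair(u, v) in self.undirected:
            raise ValueError(f"pair ({u},{v}) already present as undirected")
        self.nodes.update((u, v))
        self.directed.add((u, v))

    def add_undirected(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop {u!r}")
        if (u, v) in self.directed or (v, u) in self.directed:
            raise ValueError(f"pair ({u},{v}) already present as directed")
        self.nodes.update((u, v))
        self.undirected.add(_norm_pair(u, v))

    # -- queries ------------------------------------------------------
    def adjacent(self, u: str, v: str) -> bool:
        return (
            (u, v) in self.directed
            or (v, u) in self.directed
            or _norm_pair(u, v) in self.undirected
        )

    def neighbours(self, v: str) -> set[str]:
        """All nodes adjacent to *v*, ignoring orientation."""
        out = {b for a, b in self.directed if a == v}
        out |= {a for a, b in self.directed if b == v}
        for a, b in self.undirected:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        return out

    def parents(self, v: str) -> set[str]:
        return {a for a, b in self.directed if b == v}

    def children(self, v: str) -> set[str]:
        return {b for a, b in self.directed if a == v}

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)

    def copy(self) -> "Pdag":
        return Pdag(self.nodes, self.directed, self.undirected)

    def to_networkx(self) -> nx.DiGraph:
        """Directed part only, all nodes included."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.directed))
        return g

    def to_networkx_skeleton(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.directed))
        g.add_edges_from(sorted(self.undirected))
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Pdag):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.directed == other.directed
            and self.undirected == other.undirected
        )

    def __hash__(self):  # pragma: no cover - mutable, not hashable
        raise TypeError("Pdag is mutable and unhashable")

    def __repr__(self) -> str:
        return (
            f"{type(self).__name__}(|V|={len(self.nodes)}, "
            f"directed={len(self.directed)}, undirected={len(self.undirected)})"
        )


class Dag(Pdag):
    """Fully directed acyclic graph."""

    def __init__(self, nodes: Iterable[str] = (), directed: Iterable[tuple[str, str]] = ()):
        super().__init__(nodes, directed)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = self.to_networkx()
        try:
            cyc = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise CycleError([u for u, _ in cyc])

    def add_undirected(self, u: str, v: str) -> None:
        raise TypeError("Dag cannot hold undirected edges")

    def add_directed(self, u: str, v: str) -> None:
        if self.has_directed_path(v, u):
            raise CycleError([u, v])
        super().add_directed(u, v)

    def has_directed_path(self, src: str, dst: str) -> bool:
        if src == dst:
            return True
        if src not in self.nodes or dst not in self.nodes:
            return False
        stack, seen = [src], {src}
        while stack:
            cur = stack.pop()
            for nxt in self.children(cur):
                if nxt == dst:
                    return True
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def ancestors(self, v: str) -> set[str]:
        return nx.ancestors(self.to_networkx(), v)

    def descendants(self, v: str) -> set[str]:
        return nx.descendants(self.to_networkx(), v)

    def copy(self) -> "Dag":
        return Dag(self.nodes, self.directed)

    def edges_sorted(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self.directed))
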