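"""Structure learning for discrete data.

Native learners cover one or more representatives of each class used in
ensemble causal-discovery studies:

* score-based: hill climbing (``hc``) and TABU search (``tabu``), both
  greedy add/delete/reverse search maximising the decomposable BIC;
* constraint-based: PC-Stable (``pc_stable``, order-independent
  skeleton phase) and Grow-Shrink (``gs``, Markov-blanket based), both
  returning CPDAGs via v-structure orientation and Meek rules;
* hybrid: MMHC (``mmhc``), MMPC skeleton restriction followed by
  hill climbing.

Graphs learned by external tools enter the ensemble through the
edge-list adapter (:func:`gdmcbn.dataio.read_edge_list`);
:func:`extend_cpdag` turns any CPDAG into a DAG by drawing a
representative of its Markov equivalence class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import DiscreteDataset
from .graphs import CycleError, Dag, Pdag
from .independence import ci_test_g2
from .scoring import FamilyScoreCache

__all__ = ["LearnConfig", "EnsembleMember", "learn_structure", "extend_cpdag", "run_ensemble"]

_ALGORITHMS = ("hc", "tabu", "pc_stable", "gs", "mmhc")
_EPS = 1e-10


@dataclass(frozen=True)
class LearnConfig:
    """Hyperparameters of one structure-learning run."""

    algorithm: str = "hc"
    score: str = "bic"
    alpha: float = 0.05
    tabu_length: int = 10
    max_parents: int | None = None
    seed: int = 0
    name: str | None = None

    def __post_init__(self):
        if self.algorithm not in _ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {_ALGORITHMS}")
        if self.score != "bic":
            raise ValueError("only the BIC score is supported")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.tabu_length < 1:
            raise ValueError("tabu_length must be >= 1")
        if self.max_parents is not None and self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")

    @property
    def label(self) -> str:
        return self.name or self.algorithm


def learn_structure(data: DiscreteDataset, config: LearnConfig) -> Pdag:
    """Learn a graph; DAG for hc/tabu/mmhc, CPDAG for pc_stable/gs."""
    if data.n < 1:
        raise ValueError("empty dataset")
    if len(data.schema) < 2:
        raise ValueError("need at least two variables")
    if config.algorithm == "hc":
        return _hill_climb(data, config, tabu=False)
    if config.algorithm == "tabu":
        return _hill_climb(data, config, tabu=True)
    if config.algorithm == "pc_stable":
        return _pc_stable(data, config)
    if config.algorithm == "gs":
        return _grow_shrink(data, config)
    return _mmhc(data, config)


# ------------------------------------------------------------- score search

class _SearchState:
    """Mutable DAG over column indices with cached family scores."""

    def __init__(self, data: DiscreteDataset, max_parents: int | None):
        self.m = len(data.schema)
        self.names = data.names
        self.cache = FamilyScoreCache(data)
        self.parents: list[set[int]] = [set() for _ in range(self.m)]
        self.children: list[set[int]] = [set() for _ in range(self.m)]
        self.node_score = [self.cache.score(v, frozenset()) for v in range(self.m)]
        self.max_parents = max_parents

    # descendant matrix, recomputed after each applied move
    def descendants(self) -> np.ndarray:
        reach = np.zeros((self.m, self.m), dtype=bool)
        for v in range(self.m):
            stack = list(self.children[v])
            while stack:
                w = stack.pop()
                if not reach[v, w]:
                    reach[v, w] = True
                    stack.extend(self.children[w])
        return reach

    def family_delta(self, child: int, new_parents: set[int]) -> float:
        return self.cache.score(child, frozenset(new_parents)) - self.node_score[child]

    def candidate_moves(self, allowed: set[tuple[int, int]] | None = None):
        """Yield (delta, op, u, v); op in {'add','delete','reverse'}."""
        reach = self.descendants()
        mp = self.max_parents
        for u in range(self.m):
            for v in range(self.m):
                if u == v:
                    continue
                if u in self.parents[v]:
                    continue
                if v in self.parents[u]:
                    continue  # reverse handled from the edge's own loop
                if allowed is not None and (u, v) not in allowed and (v, u) not in allowed:
                    continue
                if reach[v, u]:
                    continue  # u->v would close a cycle
                if mp is not None and len(self.parents[v]) >= mp:
                    continue
                yield (self.family_delta(v, self.parents[v] | {u}), "add", u, v)
        for v in range(self.m):
            for u in self.parents[v]:
                yield (self.family_delta(v, self.parents[v] - {u}), "delete", u, v)
        for v in range(self.m):
            for u in list(self.parents[v]):
                # reverse u->v to v->u: illegal iff another u~>v path exists
                if self._path_avoiding(u, v, skip_edge=(u, v)):
                    continue
                if mp is not None and len(self.parents[u]) >= mp:
                    continue
                d = self.family_delta(v, self.parents[v] - {u}) + self.family_delta(
                    u, self.parents[u] | {v}
                )
                yield (d, "reverse", u, v)

    def _path_avoiding(self, src: int, dst: int, skip_edge: tuple[int, int]) -> bool:
        stack, seen = [src], {src}
        while stack:
            cur = stack.pop()
            for nxt in self.children[cur]:
                if (cur, nxt) == skip_edge:
                    continue
                if nxt == dst:
                    return True
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return False

    def apply(self, op: str, u: int, v: int) -> None:
        if op == "add":
            self.parents[v].add(u)
            self.children[u].add(v)
            self.node_score[v] = self.cache.score(v, frozenset(self.parents[v]))
        elif op == "delete":
            self.parents[v].discard(u)
            self.children[u].discard(v)
            self.node_score[v] = self.cache.score(v, frozenset(self.parents[v]))
        else:  # reverse
            self.apply("delete", u, v)
            self.apply("add", v, u)

    def signature(self) -> frozenset[tuple[int, int]]:
        return frozenset((u, v) for v in range(self.m) for u in self.parents[v])

    def total_score(self) -> float:
        return float(sum(self.node_score))

    def to_dag(self) -> Dag:
        edges = [(self.names[u], self.names[v]) for v in range(self.m) for u in self.parents[v]]
        return Dag(set(self.names), edges)


_OP_ORDER = {"add": 0, "delete": 1, "reverse": 2}


def _best_move(state: _SearchState, forbidden: set[frozenset] | None = None,
               allowed: set[tuple[int, int]] | None = None):
    """Deterministic argmax over moves: score first, then op, then (u,v) names."""
    best = None
    for delta, op, u, v in state.candidate_moves(allowed):
        if forbidden is not None:
            sig = _move_signature(state, op, u, v)
            if sig in forbidden:
                continue
        key = (-delta, _OP_ORDER[op], state.names[u], state.names[v])
        if best is None or key < best[0]:
            best = (key, delta, op, u, v)
    return best


def _move_signature(state: _SearchState, op: str, u: int, v: int) -> frozenset:
    sig = set(state.signature())
    if op == "add":
        sig.add((u, v))
    elif op == "delete":
        sig.discard((u, v))
    else:
        sig.discard((u, v))
        sig.add((v, u))
    return frozenset(sig)


def _hill_climb(data: DiscreteDataset, config: LearnConfig, tabu: bool) -> Dag:
    state = _SearchState(data, config.max_parents)
    if not tabu:
        while True:
            best = _best_move(state)
            if best is None or best[1] <= _EPS:
                break
            state.apply(best[2], best[3], best[4])
        return state.to_dag()

    # TABU: keep a list of recently visited structures, allow the best
    # non-improving move while the list blocks immediate backtracking.
    visited: list[frozenset] = [state.signature()]
    forbidden = set(visited)
    best_sig, best_score = state.signature(), state.total_score()
    stagnation = 0
    while stagnation <= config.tabu_length:
        best = _best_move(state, forbidden=forbidden)
        if best is None:
            break
        state.apply(best[2], best[3], best[4])
        sig = state.signature()
        visited.append(sig)
        if len(visited) > config.tabu_length:
            visited.pop(0)
        forbidden = set(visited)
        score = state.total_score()
        if score > best_score + _EPS:
            best_score, best_sig = score, sig
            stagnation = 0
        else:
            stagnation += 1
    names = state.names
    return Dag(set(names), [(names[u], names[v]) for u, v in best_sig])


# ------------------------------------------------------------- constraint-based

def _orient_cpdag(
    names: list[str],
    adjacency: dict[str, set[str]],
    sepsets: dict[tuple[str, str], set[str]],
) -> Pdag:
    """V-structure orientation followed by Meek rules 1-3."""
    directed: set[tuple[str, str]] = set()
    undirected = {tuple(sorted((a, b))) for a in adjacency for b in adjacency[a] if a < b}

    def is_adj(a, b):
        return b in adjacency[a]

    # v-structures: unshielded a - c - b with c outside sepset(a, b)
    for c in sorted(adjacency):
        for a, b in itertools.combinations(sorted(adjacency[c]), 2):
            if is_adj(a, b):
                continue
            sep = sepsets.get((a, b) if a < b else (b, a))
            if sep is None or c in sep:
                continue
            for x in (a, b):
                pair = tuple(sorted((x, c)))
                if pair in undirected:
                    undirected.discard(pair)
                    directed.add((x, c))
                # an arrow already pointing away from c is left alone:
                # conflicting v-structures are resolved first-come in
                # deterministic node order

    def try_orient(x, y):
        pair = tuple(sorted((x, y)))
        if pair in undirected:
            undirected.discard(pair)
            directed.add((x, y))
            return True
        return False

    changed = True
    while changed:
        changed = False
        und = sorted(undirected)
        for a, b in und:
            for x, y in ((a, b), (b, a)):
                # R1: w -> x, x - y, w and y non-adjacent  =>  x -> y
                if any((w, x) in directed and not is_adj(w, y) and w != y for w in names):
                    if try_orient(x, y):
                        changed = True
                        break
                # R2: x -> w -> y and x - y  =>  x -> y
                if any((x, w) in directed and (w, y) in directed for w in names):
                    if try_orient(x, y):
                        changed = True
                        break
                # R3: x - w1 -> y, x - w2 -> y, w1,w2 non-adjacent, x - y => x -> y
                ws = [
                    w
                    for w in names
                    if tuple(sorted((x, w))) in undirected and (w, y) in directed
                ]
                if any(
                    not is_adj(w1, w2)
                    for w1, w2 in itertools.combinations(ws, 2)
                ):
                    if try_orient(x, y):
                        changed = True
                        break
            if changed:
                break
    return Pdag(set(names), directed, undirected)


def _pc_stable(data: DiscreteDataset, config: LearnConfig) -> Pdag:
    """Order-independent PC: stable skeleton, v-structures, Meek rules."""
    names = data.names
    adjacency = {v: set(names) - {v} for v in names}
    sepsets: dict[tuple[str, str], set[str]] = {}
    level = 0
    while True:
        frozen = {v: set(adjacency[v]) for v in names}  # the "stable" copy
        if all(len(frozen[x] - {y}) < level for x in names for y in frozen[x]):
            break
        for x in sorted(names):
            for y in sorted(frozen[x]):
                if y not in adjacency[x]:
                    continue
                others = sorted(frozen[x] - {y})
                if len(others) < level:
                    continue
                for cond in itertools.combinations(others, level):
                    res = ci_test_g2(data, x, y, cond)
                    if res.uninformative or res.p > config.alpha:
                        adjacency[x].discard(y)
                        adjacency[y].discard(x)
                        sepsets[(x, y) if x < y else (y, x)] = set(cond)
                        break
        level += 1
    return _orient_cpdag(names, adjacency, sepsets)


def _markov_blanket(data: DiscreteDataset, target: str, alpha: float) -> list[str]:
    """Grow-shrink Markov blanket estimate under the G2 test."""
    names = [v for v in data.names if v != target]
    mb: list[str] = []
    changed = True
    while changed:  # grow
        changed = False
        for y in names:
            if y in mb:
                continue
            res = ci_test_g2(data, target, y, mb)
            if not res.uninformative and res.p <= alpha:
                mb.append(y)
                changed = True
    for y in list(mb):  # shrink
        rest = [z for z in mb if z != y]
        res = ci_test_g2(data, target, y, rest)
        if res.uninformative or res.p > alpha:
            mb.remove(y)
    return mb


def _resolve_neighbours(
    data: DiscreteDataset, mb: dict[str, list[str]], alpha: float
) -> tuple[dict[str, set[str]], dict[tuple[str, str], set[str]]]:
    """From symmetric MB relations to direct neighbours + separating sets."""
    names = data.names
    adjacency: dict[str, set[str]] = {v: set() for v in names}
    sepsets: dict[tuple[str, str], set[str]] = {}
    for x, y in itertools.combinations(sorted(names), 2):
        if y not in mb[x] or x not in mb[y]:
            continue
        base = mb[x] if len(mb[x]) <= len(mb[y]) else mb[y]
        pool = sorted(set(base) - {x, y})
        separated = False
        for k in range(len(pool) + 1):
            for cond in itertools.combinations(pool, k):
                res = ci_test_g2(data, x, y, cond)
                if res.uninformative or res.p > alpha:
                    sepsets[(x, y)] = set(cond)
                    separated = True
                    break
            if separated:
                break
        if not separated:
            adjacency[x].add(y)
            adjacency[y].add(x)
    return adjacency, sepsets


def _grow_shrink(data: DiscreteDataset, config: LearnConfig) -> Pdag:
    """Grow-Shrink: MB discovery, neighbour resolution, CPDAG orientation."""
    mb_raw = {v: _markov_blanket(data, v, config.alpha) for v in data.names}
    mb = {
        v: [y for y in mb_raw[v] if v in mb_raw[y]]  # symmetry (AND rule)
        for v in data.names
    }
    adjacency, sepsets = _resolve_neighbours(data, mb, config.alpha)
    return _orient_cpdag(data.names, adjacency, sepsets)


def _mmpc_forward_backward(data: DiscreteDataset, target: str, alpha: float) -> list[str]:
    """MMPC candidate parent/children set via the max-min heuristic."""
    cpc: list[str] = []
    candidates = [v for v in data.names if v != target]

    def min_assoc(y: str) -> float:
        """Largest p-value of target vs y over subsets of the current CPC."""
        worst = 0.0
        for k in range(len(cpc) + 1):
            for cond in itertools.combinations(cpc, k):
                res = ci_test_g2(data, target, y, cond)
                p = 1.0 if res.uninformative else res.p
                if p > worst:
                    worst = p
                if worst > alpha:
                    return worst  # already separable, no need to continue
        return worst

    while True:
        scored = [(min_assoc(y), y) for y in candidates if y not in cpc]
        scored = [(p, y) for p, y in scored if p <= alpha]
        if not scored:
            break
        scored.sort(key=lambda t: (t[0], t[1]))
        cpc.append(scored[0][1])
    # backward: drop members separable given the rest
    for y in list(cpc):
        rest = [z for z in cpc if z != y]
        separable = False
        for k in range(len(rest) + 1):
            for cond in itertools.combinations(rest, k):
                res = ci_test_g2(data, target, y, cond)
                if res.uninformative or res.p > alpha:
                    separable = True
                    break
            if separable:
                break
        if separable:
            cpc.remove(y)
    return cpc


def _mmhc(data: DiscreteDataset, config: LearnConfig) -> Dag:
    """MMHC: MMPC skeleton restriction + BIC hill climbing."""
    cpc = {v: _mmpc_forward_backward(data, v, config.alpha) for v in data.names}
    col = {v: j for j, v in enumerate(data.names)}
    allowed = {
        (col[x], col[y])
        for x in data.names
        for y in cpc[x]
        if x in cpc[y]  # symmetry
    }
    state = _SearchState(data, config.max_parents)
    while True:
        best = _best_move(state, allowed=allowed)
        if best is None or best[1] <= _EPS:
            break
        state.apply(best[2], best[3], best[4])
    return state.to_dag()


# ------------------------------------------------------------- CPDAG -> DAG

def extend_cpdag(cpdag: Pdag, seed: int = 0) -> Dag:
    """Consistent extension of a CPDAG (Dor-Tarsi), randomised under seed.

    The result keeps every directed edge, orients every undirected edge,
    and introduces neither cycles nor new v-structures.  Ties among
    admissible sink nodes are broken uniformly at random under ``seed``,
    which spreads the choice across the Markov equivalence class.
    """
    if not cpdag.undirected:
        dag = Dag(cpdag.nodes, cpdag.directed)  # validates acyclicity
        return dag
    rng = np.random.default_rng(seed)
    work = cpdag.copy()
    result_edges = set(cpdag.directed)
    remaining = set(work.nodes)

    def nbrs(v):
        return work.neighbours(v) & remaining

    while remaining and (work.directed or work.undirected):
        candidates = []
        for x in sorted(remaining):
            if work.children(x) & remaining:
                continue  # not a sink
            und = {
                u for u in remaining
                if tuple(sorted((x, u))) in work.undirected
            }
            adj_x = nbrs(x)
            if all(adj_x - {y} <= work.neighbours(y) for y in und):
                candidates.append(x)
        if not candidates:
            raise ValueError(
                "CPDAG admits no consistent extension; offending subgraph over "
                f"{sorted(remaining)}"
            )
        x = candidates[int(rng.integers(len(candidates)))]
        for u in nbrs(x):
            pair = tuple(sorted((x, u)))
            if pair in work.undirected:
                result_edges.add((u, x))
        # remove x from the working graph
        work.directed = {(a, b) for a, b in work.directed if x not in (a, b)}
        work.undirected = {p for p in work.undirected if x not in p}
        remaining.discard(x)
    try:
        return Dag(cpdag.nodes, result_edges)
    except CycleError as exc:  # directed part was already cyclic
        raise ValueError(f"CPDAG's directed subgraph is cyclic: {exc}") from exc


def force_orient(pdag: Pdag, seed: int = 0) -> Dag:
    """Orient every undirected edge without creating cycles.

    Finite-sample constraint-based output is not always a valid CPDAG
    and may admit no consistent extension; this fallback keeps all
    directed edges and orients the rest in random order, choosing for
    each edge a direction that preserves acyclicity (possible whenever
    the directed part is itself acyclic).  Unlike :func:`extend_cpdag`
    it may create new v-structures.
    """
    dag = Dag(pdag.nodes, pdag.directed)  # validates the directed part
    rng = np.random.default_rng(seed)
    pairs = sorted(pdag.undirected)
    rng.shuffle(pairs)
    for u, v in pairs:
        first, second = ((u, v), (v, u)) if rng.random() < 0.5 else ((v, u), (u, v))
        if not dag.has_directed_path(first[1], first[0]):
            dag.add_directed(*first)
        else:
            dag.add_directed(*second)
    return dag


# ------------------------------------------------------------- ensembles

@dataclass
class EnsembleMember:
    label: str
    graph: Dag
    source: str  # "native" or "external"


def run_ensemble(
    data: DiscreteDataset | None,
    configs: list[LearnConfig],
    external_graphs: list[tuple[str, Pdag]] | None = None,
) -> list[EnsembleMember]:
    """Learn all native configs, extend all CPDAGs, append external graphs.

    External members that cannot be extended to a DAG are dropped with a
    warning rather than failing the ensemble.
    """
    external_graphs = external_graphs or []
    if not configs and not external_graphs:
        raise ValueError("need at least one native config or external graph")
    if configs and data is None:
        raise ValueError("native configs require data")
    members: list[EnsembleMember] = []
    for cfg in configs:
        graph = learn_structure(data, cfg)
        if not isinstance(graph, Dag) or graph.undirected:
            try:
                graph = extend_cpdag(graph, seed=cfg.seed)
            except ValueError:
                warnings.warn(
                    f"{cfg.label}: no consistent extension; forcing orientations"
                )
                graph = force_orient(graph, seed=cfg.seed)
        members.append(EnsembleMember(cfg.label, graph, "native"))
    for label, graph in external_graphs:
        try:
            if isinstance(graph, Dag) and not graph.undirected:
                dag = graph
            else:
                dag = extend_cpdag(graph, seed=0)
        except (ValueError, CycleError) as exc:
            warnings.warn(f"external graph {label!r} excluded: {exc}")
            continue
        members.append(EnsembleMember(label, dag, "external"))
    return members
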