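"""Causal Bayesian networks: parameterisation, exact inference, interventions.

A :class:`Cbn` couples a DAG with one conditional probability table
(CPT) per node and is interpreted causally: an intervention do(X=x) is
graph surgery (remove X's incoming edges, clamp its CPT to a point
mass), after which ordinary inference on the mutilated network yields
interventional probabilities.  Inference is exact variable elimination
with a min-fill ordering, so posteriors agree with brute-force joint
enumeration up to floating-point error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import DiscreteDataset
from .graphs import Dag
from .scoring import family_counts

__all__ = [
    "Cpt",
    "Cbn",
    "InterventionResult",
    "SensitivityEntry",
    "SensitivityReport",
    "fit_cpts",
    "infer_posterior",
    "intervene",
    "risk_difference",
    "sensitivity_analysis",
]

_ATOL = 1e-9


@dataclass
class Cpt:
    """P(node | parents): rows are parent configurations (mixed radix,
    first listed parent most significant), columns node states."""

    node: str
    parents: tuple[str, ...]
    table: np.ndarray  # shape (q, r)

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=np.float64)
        if self.table.ndim != 2:
            raise ValueError(f"{self.node}: CPT must be 2-D (rows x states)")
        if (self.table < -_ATOL).any():
            raise ValueError(f"{self.node}: negative CPT entry")
        sums = self.table.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=_ATOL):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"{self.node}: CPT row {bad} sums to {sums[bad]!r}, expected 1"
            )

    @property
    def n_states(self) -> int:
        return self.table.shape[1]


class Cbn:
    """A DAG plus CPTs; ``states[node]`` lists the node's state labels."""

    def __init__(self, dag: Dag, cpts: dict[str, Cpt], states: dict[str, tuple[str, ...]]):
        if set(cpts) != dag.nodes or set(states) != dag.nodes:
            raise ValueError("cpts/states must cover exactly the DAG's nodes")
        for node, cpt in cpts.items():
            if set(cpt.parents) != dag.parents(node):
                raise ValueError(
                    f"{node}: CPT parents {cpt.parents} != DAG parents {sorted(dag.parents(node))}"
                )
            q = 1
            for p in cpt.parents:
                q *= len(states[p])
            if cpt.table.shape != (q, len(states[node])):
                raise ValueError(
                    f"{node}: CPT shape {cpt.table.shape}, expected {(q, len(states[node]))}"
                )
        self.dag = dag
        self.cpts = dict(cpts)
        self.states = {k: tuple(v) for k, v in states.items()}

    def state_index(self, node: str, label: str) -> int:
        try:
            return self.states[node].index(label)
        except ValueError:
            raise KeyError(f"{label!r} is not a state of {node} {self.states[node]}") from None

    def copy(self) -> "Cbn":
        cpts = {k: Cpt(v.node, v.parents, v.table.copy()) for k, v in self.cpts.items()}
        return Cbn(self.dag.copy(), cpts, self.states)

    def subnetwork(self, keep: set[str]) -> "Cbn":
        """Restriction to an ancestrally closed node set."""
        for v in keep:
            if not self.dag.parents(v) <= keep:
                raise ValueError(f"{v}'s parents are not all inside the kept set")
        dag = Dag(keep, [(u, v) for u, v in self.dag.directed if u in keep and v in keep])
        return Cbn(dag, {v: self.cpts[v] for v in keep}, {v: self.states[v] for v in keep})

    def __repr__(self) -> str:
        return f"Cbn(|V|={len(self.dag.nodes)}, edges={len(self.dag.directed)})"


# ---------------------------------------------------------------- fitting

def fit_cpts(dag: Dag, data: DiscreteDataset, alpha: float = 1.0) -> Cbn:
    """Estimate CPTs from data with additive (Dirichlet) smoothing.

    Each entry is ``(N_ijk + alpha) / (N_ij + alpha * r)``; ``alpha=0``
    is the MLE, with empty parent configurations falling back to the
    uniform distribution.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    missing = dag.nodes - set(data.names)
    if missing:
        raise ValueError(f"DAG nodes absent from data: {sorted(missing)}")
    cards = data.cardinalities
    cpts: dict[str, Cpt] = {}
    for node in sorted(dag.nodes):
        parents = tuple(sorted(dag.parents(node)))
        ci = data.column_index(node)
        pi = [data.column_index(p) for p in parents]
        counts = family_counts(data.codes, ci, pi, cards).astype(np.float64)
        r = counts.shape[1]
        num = counts + alpha
        den = num.sum(axis=1, keepdims=True)
        empty = den[:, 0] == 0
        table = np.where(empty[:, None], 1.0 / r, num / np.where(den == 0, 1.0, den))
        cpts[node] = Cpt(node, parents, table)
    states = {s.name: tuple(s.states) for s in data.schema if s.name in dag.nodes}
    return Cbn(dag, cpts, states)


# ---------------------------------------------------------------- inference

class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray):
        self.vars = vars
        self.values = values


def _broadcast_to(f: _Factor, vars_out: tuple[str, ...]) -> np.ndarray:
    """Reshape/transpose a factor's array onto the joint axis order."""
    if not f.vars:
        return f.values
    perm = np.argsort([vars_out.index(v) for v in f.vars])
    arr = np.transpose(f.values, perm)
    shape = [f.values.shape[f.vars.index(v)] if v in f.vars else 1 for v in vars_out]
    return arr.reshape(shape)


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    vars_out = a.vars + tuple(v for v in b.vars if v not in a.vars)
    return _Factor(vars_out, _broadcast_to(a, vars_out) * _broadcast_to(b, vars_out))


def _sum_out(f: _Factor, var: str) -> _Factor:
    ax = f.vars.index(var)
    return _Factor(tuple(v for v in f.vars if v != var), f.values.sum(axis=ax))


def _reduce(f: _Factor, var: str, idx: int) -> _Factor:
    ax = f.vars.index(var)
    return _Factor(
        tuple(v for v in f.vars if v != var), np.take(f.values, idx, axis=ax)
    )


def _min_fill_order(factors: list[_Factor], eliminate: set[str]) -> list[str]:
    neighbours: dict[str, set[str]] = {v: set() for f in factors for v in f.vars}
    for f in factors:
        for v in f.vars:
            neighbours[v].update(u for u in f.vars if u != v)
    order = []
    remaining = set(eliminate)
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nb = neighbours[v] & set(neighbours)
            fill = sum(
                1
                for a in nb
                for b in nb
                if a < b and b not in neighbours[a]
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        order.append(best)
        nb = neighbours[best]
        for a in nb:
            neighbours[a].update(nb - {a})
            neighbours[a].discard(best)
        del neighbours[best]
        remaining.discard(best)
    return order


def infer_posterior(
    cbn: Cbn, query: str, evidence: dict[str, str] | None = None
) -> np.ndarray:
    """Exact posterior P(query | evidence) as a vector over query states.

    Raises ``ValueError`` on zero-probability evidence.
    """
    evidence = dict(evidence or {})
    if query not in cbn.dag.nodes:
        raise KeyError(f"unknown query variable {query!r}")
    ev_idx = {v: cbn.state_index(v, s) for v, s in evidence.items()}

    if query in ev_idx:  # degenerate one-hot posterior, evidence permitting
        rest = {v: s for v, s in evidence.items()}
        qi = ev_idx[query]
        del rest[query]
        post = infer_posterior(cbn, query, rest)
        if post[qi] <= 0:
            raise ValueError(f"evidence {evidence!r} has probability zero")
        out = np.zeros_like(post)
        out[qi] = 1.0
        return out

    # barren-node pruning: only ancestors of query/evidence matter
    relevant = {query} | set(ev_idx)
    for v in list(relevant):
        relevant |= cbn.dag.ancestors(v)

    factors: list[_Factor] = []
    for node in sorted(relevant):
        cpt = cbn.cpts[node]
        shape = [len(cbn.states[p]) for p in cpt.parents] + [cpt.n_states]
        f = _Factor(cpt.parents + (node,), cpt.table.reshape(shape))
        for v, idx in ev_idx.items():
            if v in f.vars:
                f = _reduce(f, v, idx)
        factors.append(f)

    eliminate = {v for f in factors for v in f.vars} - {query}
    for v in _min_fill_order(factors, eliminate):
        bucket = [f for f in factors if v in f.vars]
        factors = [f for f in factors if v not in f.vars]
        if not bucket:
            continue
        prod = bucket[0]
        for f in bucket[1:]:
            prod = _multiply(prod, f)
        factors.append(_sum_out(prod, v))

    result = _Factor((), np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    vals = np.squeeze(np.asarray(result.values))
    if vals.ndim != 1:
        raise RuntimeError("elimination left an unexpected factor shape")
    z = vals.sum()
    if not math.isfinite(z) or z <= 0:
        raise ValueError(f"evidence {evidence!r} has probability zero")
    return vals / z


# ---------------------------------------------------------------- interventions

def intervene(cbn: Cbn, assignments: dict[str, str]) -> Cbn:
    """Graph surgery do(X=x): cut incoming edges, clamp CPTs to point mass."""
    for v in assignments:
        if v not in cbn.dag.nodes:
            raise KeyError(f"unknown intervention variable {v!r}")
    idx = {v: cbn.state_index(v, s) for v, s in assignments.items()}
    edges = [(u, v) for u, v in cbn.dag.directed if v not in assignments]
    dag = Dag(cbn.dag.nodes, edges)
    cpts = {}
    for node, cpt in cbn.cpts.items():
        if node in assignments:
            row = np.zeros((1, cpt.n_states))
            row[0, idx[node]] = 1.0
            cpts[node] = Cpt(node, (), row)
        else:
            cpts[node] = Cpt(cpt.node, cpt.parents, cpt.table.copy())
    return Cbn(dag, cpts, cbn.states)


@dataclass(frozen=True)
class InterventionResult:
    """Absolute risk difference P(Y=y|do(X=x1)) - P(Y=y|do(X=x0))."""

    target: str
    target_state: str
    intervention: str
    x1: str
    x0: str
    p_do_x1: float
    p_do_x0: float

    @property
    def risk_difference(self) -> float:
        return self.p_do_x1 - self.p_do_x0

    @property
    def percentage_points(self) -> float:
        return 100.0 * self.risk_difference

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "target_state": self.target_state,
            "intervention": self.intervention,
            "x1": self.x1,
            "x0": self.x0,
            "p_do_x1": self.p_do_x1,
            "p_do_x0": self.p_do_x0,
            "risk_difference": self.risk_difference,
            "percentage_points": self.percentage_points,
        }


def risk_difference(
    cbn: Cbn, X: str, x1: str, x0: str, Y: str, y: str
) -> InterventionResult:
    """Interventional contrast between setting X to x1 versus x0."""
    if X == Y:
        raise ValueError("intervention and target variable must differ")
    yi = cbn.state_index(Y, y)
    p1 = float(infer_posterior(intervene(cbn, {X: x1}), Y)[yi])
    p0 = float(infer_posterior(intervene(cbn, {X: x0}), Y)[yi])
    return InterventionResult(Y, y, X, x1, x0, p1, p0)


# ---------------------------------------------------------------- sensitivity

@dataclass(frozen=True)
class SensitivityEntry:
    node: str
    sensitivity: float
    rank: int
    truncated: bool = False


@dataclass
class SensitivityReport:
    target: str
    delta: float
    evidence: dict[str, str] = field(default_factory=dict)
    entries: list[SensitivityEntry] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "delta": self.delta,
            "evidence": dict(self.evidence),
            "entries": [
                {"node": e.node, "sensitivity": e.sensitivity, "rank": e.rank,
                 "truncated": e.truncated}
                for e in self.entries
            ],
        }


def _perturb_row(row: np.ndarray, k: int, new_p: float) -> np.ndarray:
    """Set entry k to new_p, rescale the rest proportionally."""
    out = row.copy()
    old_p = row[k]
    rest = 1.0 - old_p
    out[k] = new_p
    if rest > 0:
        scale = (1.0 - new_p) / rest
        for j in range(len(row)):
            if j != k:
                out[j] = row[j] * scale
    else:  # degenerate row: spread the freed mass uniformly
        share = (1.0 - new_p) / (len(row) - 1)
        for j in range(len(row)):
            if j != k:
                out[j] = share
    return out


def sensitivity_analysis(
    cbn: Cbn,
    target: str,
    delta: float = 0.05,
    evidence: dict[str, str] | None = None,
) -> SensitivityReport:
    """One-way CPT sensitivity of the target's posterior to each ancestor.

    Every CPT entry of every ancestor node is shifted by +/- ``delta``
    (truncated to [0, 1]) with proportional co-variation of the rest of
    its row; a node's sensitivity is the maximum absolute change this
    induces in any state of the target's posterior.  Nodes with no
    directed path to the target have sensitivity exactly 0.
    """
    if not (0 < delta < 0.5):
        raise ValueError("delta must lie in (0, 0.5)")
    if target not in cbn.dag.nodes:
        raise KeyError(f"unknown target {target!r}")
    evidence = dict(evidence or {})

    relevant = {target} | set(evidence)
    for v in list(relevant):
        relevant |= cbn.dag.ancestors(v)
    sub = cbn.subnetwork(relevant)

    baseline = infer_posterior(sub, target, evidence)
    ancestors = cbn.dag.ancestors(target)

    results: list[tuple[str, float, bool]] = []
    for node in sorted(cbn.dag.nodes - {target}):
        if node not in ancestors:
            results.append((node, 0.0, False))
            continue
        cpt = sub.cpts[node]
        best, truncated = 0.0, False
        for row_idx in range(cpt.table.shape[0]):
            row = cpt.table[row_idx]
            for k in range(cpt.n_states):
                for sign in (+1.0, -1.0):
                    raw = row[k] + sign * delta
                    new_p = min(1.0, max(0.0, raw))
                    if new_p != raw:
                        truncated = True
                    if new_p == row[k]:
                        continue
                    saved = row.copy()
                    cpt.table[row_idx] = _perturb_row(row, k, new_p)
                    try:
                        post = infer_posterior(sub, target, evidence)
                        change = float(np.max(np.abs(post - baseline)))
                    except ValueError:  # evidence probability driven to zero
                        change = float(np.max(np.abs(baseline)))
                    finally:
                        cpt.table[row_idx] = saved
                    if change > best:
                        best = change
        results.append((node, best, truncated))

    results.sort(key=lambda t: (-t[1], t[0]))
    entries = [
        SensitivityEntry(node, sens, rank + 1, trunc)
        for rank, (node, sens, trunc) in enumerate(results)
    ]
    return SensitivityReport(target, delta, evidence, entries)
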