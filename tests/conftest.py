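"""Shared fixtures and independent oracles.

The inference oracle here enumerates the full joint distribution of a
CBN by brute force; it is deliberately independent of the package's
variable-elimination engine.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gdmcbn.cbn import Cbn, Cpt
from gdmcbn.graphs import Dag
from gdmcbn.schema import VariableSpec
from gdmcbn.synthetic import make_toy_network

TOY_NAMES = ["chain", "collider", "confounder", "sprinkler"]


def enumerate_joint(cbn: Cbn) -> tuple[list[str], np.ndarray]:
    """Full joint by explicit product over all state combinations."""
    nodes = sorted(cbn.dag.nodes)
    cards = [len(cbn.states[v]) for v in nodes]
    joint = np.zeros(cards)
    for combo in itertools.product(*(range(c) for c in cards)):
        assign = dict(zip(nodes, combo))
        p = 1.0
        for v in nodes:
            cpt = cbn.cpts[v]
            idx = 0
            for par in cpt.parents:
                idx = idx * len(cbn.states[par]) + assign[par]
            p *= cpt.table[idx, assign[v]]
        joint[combo] = p
    return nodes, joint


def brute_posterior(cbn: Cbn, query: str, evidence: dict[str, str] | None = None) -> np.ndarray:
    """P(query | evidence) from the enumerated joint."""
    nodes, joint = enumerate_joint(cbn)
    evidence = evidence or {}
    for var, lab in evidence.items():
        ax = nodes.index(var)
        idx = cbn.states[var].index(lab)
        joint = np.take(joint, [idx], axis=ax)
    qax = nodes.index(query)
    other = tuple(ax for ax in range(joint.ndim) if ax != qax)
    marginal = joint.sum(axis=other)
    total = marginal.sum()
    if total <= 0:
        raise ValueError("zero-probability evidence")
    return marginal / total


def random_cbn(rng: np.random.Generator, n_nodes: int = 8, edge_prob: float = 0.3) -> Cbn:
    """Random small CBN: random sparse DAG, cards 2-3, Dirichlet CPTs."""
    names = [f"V{i}" for i in range(n_nodes)]
    edges = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < edge_prob
    ]
    dag = Dag(set(names), edges)
    cards = {v: int(rng.integers(2, 4)) for v in names}
    states = {v: tuple(str(k) for k in range(cards[v])) for v in names}
    cpts = {}
    for v in names:
        parents = tuple(sorted(dag.parents(v)))
        q = int(np.prod([cards[p] for p in parents])) if parents else 1
        table = rng.dirichlet(np.ones(cards[v]), size=q)
        cpts[v] = Cpt(v, parents, table)
    return Cbn(dag, cpts, states)


def binary_schema(names: str | list[str]) -> list[VariableSpec]:
    return [VariableSpec(n, ("0", "1")) for n in names]


@pytest.fixture(params=TOY_NAMES)
def toy_network(request):
    return make_toy_network(request.param)


@pytest.fixture
def sprinkler():
    return make_toy_network("sprinkler")


@pytest.fixture
def confounder():
    return make_toy_network("confounder")
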