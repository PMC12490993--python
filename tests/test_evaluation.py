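"""The seven evaluation criteria and their fixed points."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdmcbn.dataset import DiscreteDataset
from gdmcbn.evaluation import (
    ConfusionCounts,
    bic,
    bootstrap_ci,
    bsf,
    confusion,
    count_fragments,
    count_free_parameters,
    evaluate_all,
    f1,
    log_likelihood,
    shd,
)
from gdmcbn.graphs import Dag, Pdag
from gdmcbn.schema import VariableSpec

from conftest import binary_schema


def _complete_dag(reference: Dag) -> Dag:
    """Fully connected DAG containing every reference edge correctly."""
    edges = set(reference.directed)
    order = reference.topological_order()
    pos = {v: i for i, v in enumerate(order)}
    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            if not reference.adjacent(u, v):
                edges.add((u, v))
    return Dag(reference.nodes, edges)


def _random_dag(rng, nodes, p=0.4):
    order = list(nodes)
    rng.shuffle(order)
    edges = [
        (order[i], order[j])
        for i in range(len(order))
        for j in range(i + 1, len(order))
        if rng.random() < p
    ]
    return Dag(set(nodes), edges)


class TestConfusion:
    def test_identity_case(self):
        ref = Dag("ABCDEF", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F")])
        c = confusion(ref, ref)
        assert (c.tp, c.fn, c.fp, c.tn) == (5, 0, 0, 10)
        assert c.a == 5 and c.i == 10

    def test_empty_learned(self):
        ref = Dag("ABC", [("A", "B"), ("B", "C")])
        c = confusion(Dag(ref.nodes), ref)
        assert (c.tp, c.fn, c.fp, c.tn) == (0, 2, 0, 1)

    def test_hand_enumeration_three_pairs(self):
        ref = Dag("ABC", [("A", "B"), ("B", "C")])
        c = confusion(Dag(ref.nodes, [("A", "B")]), ref)
        assert (c.tp, c.fn, c.fp, c.tn) == (1, 1, 0, 1)

    def test_reversed_edge_counts_as_fn_not_fp(self):
        ref = Dag("AB", [("A", "B")])
        c = confusion(Dag(ref.nodes, [("B", "A")]), ref)
        assert (c.tp, c.fn, c.fp, c.tn) == (0, 1, 0, 0)

    def test_identities_hold_on_random_pairs(self):
        rng = np.random.default_rng(3)
        nodes = list("ABCDEFG")
        for _ in range(50):
            c = confusion(_random_dag(rng, nodes), _random_dag(rng, nodes))
            assert c.tp + c.fn == c.a
            assert c.tn + c.fp == c.i

    def test_node_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(Dag("AB"), Dag("AC"))


class TestShd:
    def test_identity_is_zero(self):
        g = Dag("ABC", [("A", "B")])
        assert shd(g, g) == 0

    def test_orientation_difference_is_one(self):
        assert shd(Dag("AB", [("B", "A")]), Dag("AB", [("A", "B")])) == 1

    def test_two_missing_edges(self):
        ref = Dag("ABC", [("A", "B"), ("B", "C")])
        assert shd(Dag(ref.nodes), ref) == 2

    def test_directed_vs_undirected_counts_one(self):
        assert shd(Pdag("AB", [], [("A", "B")]), Pdag("AB", [("A", "B")])) == 1

    def test_symmetry_property(self):
        rng = np.random.default_rng(5)
        nodes = list("ABCDE")
        for _ in range(30):
            g1, g2 = _random_dag(rng, nodes), _random_dag(rng, nodes)
            assert shd(g1, g2) == shd(g2, g1)


class TestF1:
    def test_perfect_recovery(self):
        assert f1(ConfusionCounts(3, 3, 0, 0, 3, 3)) == 1.0

    def test_zero_tp_is_zero(self):
        assert f1(ConfusionCounts(0, 2, 1, 3, 3, 3)) == 0.0

    def test_balanced_half(self):
        # TP=1, FN=1, FP=1 (a=2): R = P = 0.5 so F1 = 0.5
        assert f1(ConfusionCounts(1, 1, 1, 1, 2, 2)) == pytest.approx(0.5)

    def test_no_reference_edges_not_applicable(self):
        assert math.isnan(f1(ConfusionCounts(0, 3, 0, 0, 0, 3)))


class TestBsf:
    def test_empty_graph_scores_exactly_zero(self):
        ref = Dag("ABCD", [("A", "B"), ("C", "D")])
        assert bsf(confusion(Dag(ref.nodes), ref)) == 0.0

    def test_complete_graph_scores_exactly_zero(self):
        ref = Dag("ABCD", [("A", "B"), ("C", "D")])
        assert bsf(confusion(_complete_dag(ref), ref)) == 0.0

    def test_perfect_recovery_scores_exactly_one(self):
        ref = Dag("ABCD", [("A", "B"), ("C", "D")])
        assert bsf(confusion(ref, ref)) == 1.0

    def test_hand_evaluation(self):
        # TP=1, FN=1, FP=0, TN=1 with a=2, i=1:
        # 0.5 * (1/2 + 1/1 - 0/1 - 1/2) = 0.5
        ref = Dag("ABC", [("A", "B"), ("B", "C")])
        assert bsf(confusion(Dag(ref.nodes, [("A", "B")]), ref)) == pytest.approx(0.5)

    def test_bounded_on_random_pairs(self):
        rng = np.random.default_rng(7)
        nodes = list("ABCDEF")
        for _ in range(200):
            ref = _random_dag(rng, nodes)
            if not ref.directed or len(ref.directed) == 15:
                continue
            val = bsf(confusion(_random_dag(rng, nodes), ref))
            assert -1.0 <= val <= 1.0

    def test_literal_i_variant_loses_fixed_point(self):
        ref = Dag("ABCD", [("A", "B"), ("C", "D")])
        assert bsf(confusion(Dag(ref.nodes), ref), literal_i=True) != 0.0


class TestLikelihoodAndBic:
    def _coin_data(self, n=100):
        codes = np.array([[0]] * (n // 2) + [[1]] * (n // 2))
        return DiscreteDataset(binary_schema("X"), codes)

    def test_fair_coin_closed_form(self):
        data = self._coin_data(100)
        ll = log_likelihood(Dag({"X"}), data)
        assert ll == pytest.approx(100 * math.log(0.5), rel=1e-12)

    def test_bic_closed_form(self):
        data = self._coin_data(100)
        val = bic(Dag({"X"}), data)
        assert val == pytest.approx(100 * math.log(0.5) - 0.5 * math.log(100), rel=1e-12)

    def test_bic_equals_ll_when_n_is_one(self):
        data = DiscreteDataset(binary_schema("XY"), np.array([[0, 1]]))
        g = Dag({"X", "Y"}, [("X", "Y")])
        assert bic(g, data) == pytest.approx(log_likelihood(g, data))

    def test_adding_edge_never_decreases_ll(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 2, size=(500, 3))
        data = DiscreteDataset(binary_schema("ABC"), codes)
        base = Dag({"A", "B", "C"}, [("A", "B")])
        bigger = Dag({"A", "B", "C"}, [("A", "B"), ("A", "C")])
        assert log_likelihood(bigger, data) >= log_likelihood(base, data) - 1e-9

    def test_deterministic_copy_entropy_identity(self):
        # Y a fair-coin copy of X: LL(X->Y) - LL(empty) = n ln 2
        n = 1000
        x = np.tile([0, 1], n // 2)
        data = DiscreteDataset(binary_schema("XY"), np.column_stack([x, x]))
        gain = log_likelihood(Dag({"X", "Y"}, [("X", "Y")]), data) - log_likelihood(
            Dag({"X", "Y"}), data
        )
        assert gain == pytest.approx(n * math.log(2), rel=1e-12)

    def test_penalty_dominates_for_null_edge(self):
        rng = np.random.default_rng(13)
        codes = rng.integers(0, 2, size=(5000, 2))
        data = DiscreteDataset(binary_schema("AB"), codes)
        assert bic(Dag({"A", "B"}), data) > bic(Dag({"A", "B"}, [("A", "B")]), data)


class TestFreeParameters:
    @pytest.mark.parametrize(
        "cards,edges,expected",
        [
            ((2, 2), [], 2),            # two disconnected binary nodes
            ((2, 2), [("A", "B")], 3),  # 1 + 1*2
            ((3, 3), [("A", "B")], 8),  # 2 + 2*3
        ],
    )
    def test_closed_forms(self, cards, edges, expected):
        schema = [
            VariableSpec(n, tuple(str(k) for k in range(c)))
            for n, c in zip("AB", cards)
        ]
        dag = Dag({"A", "B"}, edges)
        assert count_free_parameters(dag, schema) == expected

    def test_missing_state_counts_toward_cardinality(self):
        schema = [VariableSpec("A", ("0", "1", "99"))]
        assert count_free_parameters(Dag({"A"}), schema) == 2


class TestFragments:
    def test_edgeless_graph_counts_isolates(self):
        assert count_fragments(Pdag("ABC")) == 3

    def test_connected_chain_is_one(self):
        nodes = [f"N{i}" for i in range(62)]
        edges = [(nodes[i], nodes[i + 1]) for i in range(61)]
        assert count_fragments(Dag(set(nodes), edges)) == 1

    def test_two_disjoint_edges(self):
        assert count_fragments(Dag("ABCD", [("A", "B"), ("C", "D")])) == 2


class TestBootstrap:
    def test_identical_graphs_zero_interval(self):
        g = Dag("ABCD", [("A", "B"), ("C", "D")])
        assert bootstrap_ci("shd", g, g, B=200, seed=0) == (0.0, 0.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(17)
        g1, g2 = _random_dag(rng, list("ABCDE")), _random_dag(rng, list("ABCDE"))
        assert bootstrap_ci("shd", g1, g2, B=200, seed=4) == bootstrap_ci(
            "shd", g1, g2, B=200, seed=4
        )

    def test_doubling_b_is_stable(self):
        rng = np.random.default_rng(19)
        g1, g2 = _random_dag(rng, list("ABCDEFG")), _random_dag(rng, list("ABCDEFG"))
        lo1, hi1 = bootstrap_ci("shd", g1, g2, B=1000, seed=1)
        lo2, hi2 = bootstrap_ci("shd", g1, g2, B=2000, seed=2)
        # Monte-Carlo error bound at this scale: a couple of pair units
        assert abs(lo1 - lo2) <= 3 and abs(hi1 - hi2) <= 3

    def test_b_too_small_rejected(self):
        g = Dag("AB")
        with pytest.raises(ValueError):
            bootstrap_ci("shd", g, g, B=50)


class TestEvaluateAll:
    def _data(self, names="ABCD", n=200, seed=0):
        rng = np.random.default_rng(seed)
        return DiscreteDataset(
            binary_schema(names), rng.integers(0, 2, size=(n, len(names)))
        )

    def test_identity_row(self):
        ref = Dag("ABCD", [("A", "B"), ("B", "C")])
        rep = evaluate_all([("self", ref)], ref, self._data())[0]
        assert rep.shd == 0 and rep.f1 == 1.0 and rep.bsf == 1.0
        assert rep.fragments == 2

    def test_empty_graph_row(self):
        ref = Dag("ABCD", [("A", "B"), ("B", "C")])
        rep = evaluate_all([("empty", Dag(ref.nodes))], ref, self._data())[0]
        assert rep.f1 == 0.0 and rep.bsf == 0.0

    def test_cardinality(self):
        ref = Dag("ABCD", [("A", "B")])
        graphs = [("g1", ref), ("g2", Dag(ref.nodes)), ("g3", ref)]
        assert len(evaluate_all(graphs, ref, self._data())) == 3

    def test_relabelling_invariance(self):
        data = self._data("ABCD", seed=23)
        ref = Dag("ABCD", [("A", "B"), ("C", "D")])
        learned = Dag("ABCD", [("A", "B"), ("D", "C")])
        rep = evaluate_all([("g", learned)], ref, data)[0]

        mapping = {"A": "W", "B": "X", "C": "Y", "D": "Z"}
        relabel = lambda g: Dag(
            {mapping[v] for v in g.nodes},
            [(mapping[u], mapping[v]) for u, v in g.directed],
        )
        schema2 = binary_schema("WXYZ")
        data2 = DiscreteDataset(schema2, data.codes)
        rep2 = evaluate_all([("g", relabel(learned))], relabel(ref), data2)[0]
        for attr in ("shd", "f1", "bsf", "ll", "bic", "free_parameters", "fragments"):
            assert getattr(rep, attr) == pytest.approx(getattr(rep2, attr))
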