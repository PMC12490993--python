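"""Structure learners, CPDAG extension, ensemble assembly."""

import itertools

import numpy as np
import pytest

from gdmcbn.dataset import DiscreteDataset
from gdmcbn.evaluation import bic
from gdmcbn.graphs import Dag, Pdag
from gdmcbn.structure_learning import (
    EnsembleMember,
    LearnConfig,
    extend_cpdag,
    learn_structure,
    run_ensemble,
)
from gdmcbn.synthetic import build_ground_truth, sample_dataset

from conftest import binary_schema


def _pair_data(seed=0, n=5000, strength=0.85):
    """Strongly dependent A -> B."""
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = np.where(rng.random(n) < strength, a, 1 - a)
    return DiscreteDataset(binary_schema("AB"), np.column_stack([a, b]))


class TestLearnConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            LearnConfig(algorithm="notears")
        with pytest.raises(ValueError):
            LearnConfig(alpha=0.0)
        with pytest.raises(ValueError):
            LearnConfig(tabu_length=0)


class TestScoreBased:
    def test_hc_finds_strong_adjacency(self):
        # score oracle: the one-edge graph beats the empty graph on BIC
        data = _pair_data()
        empty = Dag({"A", "B"})
        one_edge = Dag({"A", "B"}, [("A", "B")])
        assert bic(one_edge, data) > bic(empty, data)
        learned = learn_structure(data, LearnConfig(algorithm="hc"))
        assert learned.adjacent("A", "B")

    @pytest.mark.parametrize("algo", ["hc", "tabu", "mmhc"])
    def test_returns_dag_and_never_scores_below_empty(self, algo):
        schema = binary_schema("ABCDE")
        m = build_ground_truth(
            schema, [("A", "B"), ("B", "C"), ("A", "D")], seed=4, dirichlet_alpha=0.4
        )
        data = sample_dataset(m, 2000, seed=5)
        g = learn_structure(data, LearnConfig(algorithm=algo))
        assert isinstance(g, Dag) and not g.undirected
        assert bic(g, data) >= bic(Dag(set(data.names)), data)

    def test_deterministic_under_seed(self):
        data = _pair_data(seed=3)
        for algo in ("hc", "tabu"):
            g1 = learn_structure(data, LearnConfig(algorithm=algo, seed=1))
            g2 = learn_structure(data, LearnConfig(algorithm=algo, seed=1))
            assert g1.directed == g2.directed

    def test_max_parents_respected(self):
        schema = binary_schema("ABCDE")
        m = build_ground_truth(
            schema,
            [("A", "E"), ("B", "E"), ("C", "E"), ("D", "E")],
            seed=8,
            dirichlet_alpha=0.3,
        )
        data = sample_dataset(m, 4000, seed=9)
        g = learn_structure(data, LearnConfig(algorithm="hc", max_parents=2))
        assert all(len(g.parents(v)) <= 2 for v in g.nodes)

    def test_empty_dataset_rejected(self):
        data = _pair_data(n=10)
        with pytest.raises(ValueError):
            learn_structure(
                DiscreteDataset(binary_schema("A") + binary_schema("B")[:0], data.codes[:, :1]),
                LearnConfig(),
            )


class TestConstraintBased:
    def test_independent_variables_stay_sparse(self):
        # type-I error of the G2 test: expected false-positive edges
        # is alpha * #pairs; average over 20 replicates stays at or
        # below that level (deeper levels only remove edges)
        rng = np.random.default_rng(10)
        schema = binary_schema("ABCDEF")
        edge_counts = []
        for _ in range(20):
            codes = rng.integers(0, 2, size=(5000, 6))
            data = DiscreteDataset(schema, codes)
            g = learn_structure(data, LearnConfig(algorithm="pc_stable", alpha=0.05))
            edge_counts.append(g.n_edges)
        assert np.mean(edge_counts) <= 0.05 * 15 + 0.35  # mean + sampling margin

    def test_collider_v_structure_oriented(self):
        # exhaustive CI-test oracle confirms the only independence is
        # X _|_ Y; PC must then orient the v-structure X -> Z <- Y
        schema = binary_schema("XYZ")
        m = build_ground_truth(schema, [("X", "Z"), ("Y", "Z")], seed=21, dirichlet_alpha=0.4)
        data = sample_dataset(m, 10_000, seed=22)
        from gdmcbn.independence import ci_test_g2

        assert ci_test_g2(data, "X", "Y").p > 0.05
        assert ci_test_g2(data, "X", "Y", ["Z"]).p < 0.05
        g = learn_structure(data, LearnConfig(algorithm="pc_stable"))
        assert ("X", "Z") in g.directed and ("Y", "Z") in g.directed

    def test_pc_stable_column_order_invariance(self):
        schema = binary_schema("ABCD")
        m = build_ground_truth(
            schema, [("A", "B"), ("C", "B"), ("B", "D")], seed=30, dirichlet_alpha=0.4
        )
        data = sample_dataset(m, 5000, seed=31)
        g1 = learn_structure(data, LearnConfig(algorithm="pc_stable"))
        perm = [2, 0, 3, 1]
        data2 = DiscreteDataset([data.schema[j] for j in perm], data.codes[:, perm])
        g2 = learn_structure(data2, LearnConfig(algorithm="pc_stable"))
        assert g1.directed == g2.directed
        assert g1.undirected == g2.undirected

    def test_gs_recovers_chain_skeleton(self):
        schema = binary_schema("ABC")
        m = build_ground_truth(schema, [("A", "B"), ("B", "C")], seed=40, dirichlet_alpha=0.4)
        data = sample_dataset(m, 8000, seed=41)
        g = learn_structure(data, LearnConfig(algorithm="gs"))
        assert g.adjacent("A", "B") and g.adjacent("B", "C")
        assert not g.adjacent("A", "C")


class TestExtendCpdag:
    def test_already_directed_returned_unchanged(self):
        g = Pdag("ABC", [("A", "B"), ("B", "C")])
        dag = extend_cpdag(g, seed=0)
        assert dag.directed == g.directed

    def test_chain_extension_avoids_new_collider(self):
        # the 3-member equivalence class of A - B - C, enumerated:
        # every extension must avoid a collider at B
        cp = Pdag("ABC", [], [("A", "B"), ("B", "C")])
        valid = {
            frozenset({("A", "B"), ("B", "C")}),
            frozenset({("B", "A"), ("B", "C")}),
            frozenset({("B", "A"), ("C", "B")}),
        }
        seen = set()
        for seed in range(40):
            dag = extend_cpdag(cp, seed=seed)
            assert frozenset(dag.directed) in valid
            seen.add(frozenset(dag.directed))
        assert len(seen) == 3  # the randomisation reaches the whole class

    def test_preserves_v_structure(self):
        cp = Pdag("XYZW", [("X", "Z"), ("Y", "Z")], [("Z", "W")])
        dag = extend_cpdag(cp, seed=1)
        assert ("X", "Z") in dag.directed and ("Y", "Z") in dag.directed
        # W - Z must orient away from Z, else a new collider at Z appears
        assert ("Z", "W") in dag.directed

    def test_directed_cycle_rejected(self):
        cp = Pdag("ABC", [("A", "B"), ("B", "C"), ("C", "A")], [])
        with pytest.raises(ValueError):
            extend_cpdag(cp, seed=0)

    def test_deterministic_under_seed(self):
        cp = Pdag("ABCD", [], [("A", "B"), ("B", "C"), ("C", "D")])
        assert extend_cpdag(cp, seed=5).directed == extend_cpdag(cp, seed=5).directed


class TestRunEnsemble:
    def _data(self):
        schema = binary_schema("ABCDEF")
        m = build_ground_truth(
            schema,
            [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "F")],
            seed=50,
            dirichlet_alpha=0.4,
        )
        return sample_dataset(m, 2000, seed=51)

    def test_five_native_configs_give_five_dags(self):
        data = self._data()
        configs = [LearnConfig(algorithm=a, seed=i)
                   for i, a in enumerate(("hc", "tabu", "pc_stable", "gs", "mmhc"))]
        members = run_ensemble(data, configs)
        assert len(members) == 5
        assert [m.label for m in members] == ["hc", "tabu", "pc_stable", "gs", "mmhc"]
        for m in members:
            assert isinstance(m.graph, Dag) and not m.graph.undirected

    def test_external_cpdag_is_extended(self):
        cp = Pdag("AB", [], [("A", "B")])
        members = run_ensemble(None, [], [("ext", cp)])
        assert len(members) == 1
        assert members[0].graph.directed in ({("A", "B")}, {("B", "A")})
        assert members[0].source == "external"

    def test_external_dags_pass_through_unchanged(self):
        dags = [Dag("AB", [("A", "B")]), Dag("AB", [("B", "A")]), Dag("AB")]
        members = run_ensemble(None, [], [(f"g{i}", d) for i, d in enumerate(dags)])
        assert [m.graph.directed for m in members] == [d.directed for d in dags]

    def test_unextendable_external_excluded_with_warning(self):
        bad = Pdag("ABC", [("A", "B"), ("B", "C"), ("C", "A")], [])
        good = Dag("AB", [("A", "B")])
        with pytest.warns(UserWarning, match="excluded"):
            members = run_ensemble(None, [], [("bad", bad), ("good", good)])
        assert [m.label for m in members] == ["good"]

    def test_empty_everything_rejected(self):
        with pytest.raises(ValueError):
            run_ensemble(None, [], [])
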