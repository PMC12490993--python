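"""Ground-truth construction, forward sampling, and missingness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdmcbn.cbn import fit_cpts
from gdmcbn.graphs import CycleError
from gdmcbn.schema import MISSING, VariableSpec, build_gdm_schema
from gdmcbn.synthetic import (
    DEFAULT_GDM_EDGES,
    MissingnessSpec,
    STUDY_N,
    apply_missingness,
    build_ground_truth,
    default_missingness,
    make_toy_network,
    sample_dataset,
    sample_study_cohort,
    study_ground_truth,
)

from conftest import binary_schema, enumerate_joint


class TestBuildGroundTruth:
    def test_chain_edges_copied_verbatim(self):
        m = build_ground_truth(binary_schema("ABC"), [("A", "B"), ("B", "C")], seed=7)
        assert m.dag.directed == {("A", "B"), ("B", "C")}

    def test_same_seed_identical_cpts(self):
        schema = binary_schema("ABC")
        edges = [("A", "B"), ("B", "C")]
        m1 = build_ground_truth(schema, edges, seed=7)
        m2 = build_ground_truth(schema, edges, seed=7)
        for v in "ABC":
            assert np.array_equal(m1.cpts[v].table, m2.cpts[v].table)

    def test_different_seed_differs(self):
        schema = binary_schema("AB")
        m1 = build_ground_truth(schema, [("A", "B")], seed=1)
        m2 = build_ground_truth(schema, [("A", "B")], seed=2)
        assert not np.array_equal(m1.cpts["B"].table, m2.cpts["B"].table)

    def test_huge_alpha_gives_near_uniform_rows(self):
        # Dirichlet concentration limit: rows -> uniform over live states
        schema = binary_schema("AB")
        m = build_ground_truth(schema, [("A", "B")], seed=3, dirichlet_alpha=1e6)
        for v in "AB":
            assert np.all(np.abs(m.cpts[v].table - 0.5) < 0.01)

    def test_cycle_rejected_with_report(self):
        with pytest.raises(CycleError, match="cycle"):
            build_ground_truth(
                binary_schema("ABC"), [("A", "B"), ("B", "C"), ("C", "A")], seed=0
            )

    def test_nodes_absent_from_edges_become_parentless(self):
        m = build_ground_truth(binary_schema("ABC"), [("A", "B")], seed=0)
        assert m.cpts["C"].parents == ()

    def test_ground_truth_puts_no_mass_on_missing_state(self):
        m = study_ground_truth(seed=4)
        for s in m.schema:
            j = s.index_of(MISSING)
            assert np.all(m.cpts[s.name].table[:, j] == 0.0)

    def test_default_knowledge_graph_shape(self):
        m = study_ground_truth(seed=0)
        assert len(m.dag.nodes) == 62
        assert len(m.dag.directed) == 75


class TestSampling:
    def test_study_preset_samples_1808_rows(self):
        _, data = sample_study_cohort(seed=0)
        assert data.n == STUDY_N == 1808
        assert len(data.schema) == 62

    def test_n_zero_rejected_n_one_ok(self):
        m = build_ground_truth(binary_schema("AB"), [("A", "B")], seed=0)
        with pytest.raises(ValueError):
            sample_dataset(m, 0)
        assert sample_dataset(m, 1, seed=5).n == 1

    def test_root_marginal_converges(self):
        # binomial oracle: P(X=1)=0.3, n=50,000 -> freq within 0.01
        schema = binary_schema("XY")
        m = build_ground_truth(schema, [("X", "Y")], seed=0)
        m.cpts["X"].table[:] = [[0.7, 0.3]]
        d = sample_dataset(m, 50_000, seed=9)
        assert abs(d.column("X").mean() - 0.3) < 0.01

    def test_no_missing_values_before_overlay(self):
        m = study_ground_truth(seed=1)
        d = sample_dataset(m, 500, seed=2)
        for s in d.schema:
            assert not np.any(d.column(s.name) == s.index_of(MISSING))

    def test_bit_reproducible(self):
        m = study_ground_truth(seed=1)
        d1 = sample_dataset(m, 200, seed=3)
        d2 = sample_dataset(m, 200, seed=3)
        assert np.array_equal(d1.codes, d2.codes)

    def test_cpt_round_trip_recovery(self):
        # sample then refit: entries within 3 binomial SEs for rows with
        # >= 100 effective observations
        schema = binary_schema("ABC")
        m = build_ground_truth(schema, [("A", "B"), ("B", "C")], seed=11)
        d = sample_dataset(m, 20_000, seed=12)
        fitted = fit_cpts(m.dag, d, alpha=0.0)
        from gdmcbn.scoring import family_counts

        for v in "ABC":
            truth = m.cpts[v].table
            est = fitted.cpts[v].table
            pi = [d.column_index(p) for p in fitted.cpts[v].parents]
            rows = family_counts(d.codes, d.column_index(v), pi, d.cardinalities)
            for r in range(truth.shape[0]):
                n_row = rows[r].sum()
                if n_row < 100:
                    continue
                for k in range(truth.shape[1]):
                    se = np.sqrt(truth[r, k] * (1 - truth[r, k]) / n_row)
                    assert abs(est[r, k] - truth[r, k]) <= 3 * se + 1e-12


class TestMissingness:
    def _model(self, rate=0.75, mechanism="MCAR", **kw):
        schema = [VariableSpec("X", ("0", "1", MISSING)), VariableSpec("Y", ("0", "1", MISSING))]
        m = build_ground_truth(schema, [("X", "Y")], seed=0)
        m.missingness = {"Y": MissingnessSpec(mechanism, rate, **kw)}
        return m

    def test_zero_rate_is_identity(self):
        m = self._model(rate=0.0)
        d = sample_dataset(m, 500, seed=1)
        out = apply_missingness(d, m, seed=2)
        assert np.array_equal(out.codes, d.codes)

    def test_mcar_rate_hits_binomial_band(self):
        m = self._model(rate=0.75)
        d = sample_dataset(m, 10_000, seed=1)
        out = apply_missingness(d, m, seed=2)
        miss = out.spec("Y").index_of(MISSING)
        frac = (out.column("Y") == miss).mean()
        assert abs(frac - 0.75) < 0.013  # 3 binomial SEs at n=10,000

    def test_mar_rate_depends_on_parent_value(self):
        m = self._model(
            rate=0.10, mechanism="MAR", parents=("X",),
            rate_map={("0",): 0.10, ("1",): 0.60},
        )
        m.cpts["X"].table[:] = [[0.5, 0.5, 0.0]]  # balanced strata
        d = sample_dataset(m, 20_000, seed=1)
        out = apply_missingness(d, m, seed=2)
        miss = out.spec("Y").index_of(MISSING)
        x = d.column("X")
        f0 = (out.column("Y") == miss)[x == 0].mean()
        f1 = (out.column("Y") == miss)[x == 1].mean()
        assert abs(f0 - 0.10) < 0.02
        assert abs(f1 - 0.60) < 0.02

    def test_never_alters_non_missing_cells(self):
        m, _ = sample_study_cohort(seed=5)
        d = sample_dataset(m, 300, seed=6)
        out = apply_missingness(d, m, seed=7)
        assert out.n == d.n
        for j, s in enumerate(d.schema):
            miss = s.index_of(MISSING)
            kept = out.codes[:, j] != miss
            assert np.array_equal(out.codes[kept, j], d.codes[kept, j])

    def test_default_preset_has_above_70_percent_variable(self):
        rates = default_missingness(build_gdm_schema())
        assert any(spec.rate > 0.70 for spec in rates.values())

    def test_rate_without_missing_state_rejected(self):
        schema = [VariableSpec("X", ("0", "1")), VariableSpec("Y", ("0", "1", MISSING))]
        m = build_ground_truth(schema, [("X", "Y")], seed=0)
        with pytest.raises(ValueError, match="99"):
            m.missingness = {"X": MissingnessSpec("MCAR", 0.5)}
            d = sample_dataset(m, 50, seed=1)
            apply_missingness(d, m, seed=2)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000), rate=st.floats(0.0, 1.0))
    def test_row_count_preserved_property(self, seed, rate):
        m = self._model(rate=rate)
        d = sample_dataset(m, 50, seed=seed)
        out = apply_missingness(d, m, seed=seed)
        assert out.n == d.n


class TestToyNetworks:
    def test_chain_structure(self):
        cbn = make_toy_network("chain")
        assert cbn.dag.directed == {("X", "Y"), ("Y", "Z")}

    def test_confounder_structure(self):
        cbn = make_toy_network("confounder")
        assert cbn.dag.directed == {("Z", "X"), ("Z", "Y"), ("X", "Y")}

    def test_collider_roots_marginally_independent(self):
        # verified by joint enumeration, not by construction
        cbn = make_toy_network("collider")
        nodes, joint = enumerate_joint(cbn)
        ix, iy = nodes.index("X"), nodes.index("Y")
        pxy = joint.sum(axis=nodes.index("Z"))
        px = pxy.sum(axis=1 if ix < iy else 0)
        py = pxy.sum(axis=0 if ix < iy else 1)
        assert np.allclose(pxy, np.outer(px, py), atol=1e-12)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown toy network"):
            make_toy_network("mystery")
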