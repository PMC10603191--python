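"""Wang similarity, BMA gene similarity and the pairwise row statistic,
validated against brute-force path-enumeration and hand arithmetic."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgti.errors import DomainError, FormatError
from mgti.go_similarity import (
    DEFAULT_EDGE_WEIGHTS,
    GeneSimMatrix,
    bma_gene_sim,
    gene_sim_matrix,
    m_simsc,
    m_simsc_matrix,
    parse_obo,
    wang_svalues,
    wang_term_sim,
)
from mgti.synthetic_data import SimulationConfig, simulate_ontology

from conftest import make_graph


def brute_force_svalues(graph, anchor):
    """Independent oracle: S(t) = max over all anchor->t ancestor paths of
    the product of edge weights along the path."""
    g = nx.DiGraph()
    for child, plist in graph.parents.items():
        for parent, etype in plist:
            w = DEFAULT_EDGE_WEIGHTS[etype]
            # parallel is_a/part_of edges: keep the heavier weight
            if g.has_edge(child, parent):
                w = max(w, g[child][parent]["w"])
            g.add_edge(child, parent, w=w)
    svals = {anchor: 1.0}
    for t in graph.ancestors(anchor):
        best = 0.0
        for path in nx.all_simple_paths(g, anchor, t):
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= g[a][b]["w"]
            best = max(best, prod)
        svals[t] = best
    return svals


def brute_force_term_sim(graph, t1, t2):
    s1 = brute_force_svalues(graph, t1)
    s2 = brute_force_svalues(graph, t2)
    shared = s1.keys() & s2.keys()
    if not shared:
        return 0.0
    return sum(s1[t] + s2[t] for t in shared) / (sum(s1.values()) + sum(s2.values()))


class TestWangSValues:
    def test_anchor_svalue_is_one(self, chain_graph):
        assert wang_svalues(chain_graph, "A").svalues["A"] == 1.0

    def test_chain_hand_propagation(self, chain_graph):
        sv = wang_svalues(chain_graph, "A").svalues
        assert sv == pytest.approx({"A": 1.0, "B": 0.8, "ROOT": 0.64})

    def test_part_of_weight(self):
        g = make_graph([("B", "ROOT", "is_a"), ("A", "B", "part_of")])
        sv = wang_svalues(g, "A").svalues
        assert sv["B"] == pytest.approx(0.6)
        assert sv["ROOT"] == pytest.approx(0.48)

    def test_diamond_takes_max_of_equal_paths(self):
        g = make_graph(
            [
                ("L", "ROOT", "is_a"),
                ("R", "ROOT", "is_a"),
                ("A", "L", "is_a"),
                ("A", "R", "is_a"),
            ]
        )
        sv = wang_svalues(g, "A").svalues
        assert sv["ROOT"] == pytest.approx(0.64)

    def test_svalues_strictly_decay_along_chain(self):
        g = make_graph(
            [("C", "ROOT", "is_a"), ("B", "C", "is_a"), ("A", "B", "part_of")]
        )
        sv = wang_svalues(g, "A").svalues
        assert sv["A"] > sv["B"] > sv["C"] > sv["ROOT"] > 0

    def test_unknown_term_rejected(self, chain_graph):
        with pytest.raises(KeyError):
            wang_svalues(chain_graph, "NOPE")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_dags(self, seed):
        g = simulate_ontology(SimulationConfig(n_go_terms=8, dag_depth=3, seed=seed))
        for t in g.terms_in_namespace("biological_process"):
            expected = brute_force_svalues(g, t)
            got = wang_svalues(g, t).svalues
            assert got == pytest.approx(expected, abs=1e-12)


class TestWangTermSim:
    def test_self_similarity_is_one(self, chain_graph):
        for t in chain_graph.terms:
            assert wang_term_sim(chain_graph, t, t) == pytest.approx(1.0)

    def test_siblings_hand_value(self, sibling_graph):
        # shared {ROOT}: (0.8 + 0.8) / (1.8 + 1.8)
        assert wang_term_sim(sibling_graph, "A", "B") == pytest.approx(0.444444444444)

    def test_cross_namespace_rejected(self):
        from mgti.go_similarity import GOGraph

        terms = {
            "ROOT": ("ROOT", "biological_process"),
            "A": ("A", "biological_process"),
            "MROOT": ("MROOT", "molecular_function"),
            "X": ("X", "molecular_function"),
        }
        parents = {"ROOT": [], "A": [("ROOT", "is_a")], "MROOT": [], "X": [("MROOT", "is_a")]}
        g = GOGraph(terms=terms, parents=parents)
        with pytest.raises(DomainError):
            wang_term_sim(g, "A", "X")

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_and_matches_brute_force(self, seed):
        g = simulate_ontology(SimulationConfig(n_go_terms=8, dag_depth=3, seed=seed))
        terms = g.terms_in_namespace("biological_process")
        for t1, t2 in itertools.combinations(terms, 2):
            s12 = wang_term_sim(g, t1, t2)
            assert s12 == pytest.approx(wang_term_sim(g, t2, t1), abs=1e-15)
            assert s12 == pytest.approx(brute_force_term_sim(g, t1, t2), abs=1e-12)
            assert 0.0 <= s12 <= 1.0


class TestBMAGeneSim:
    def test_identical_term_sets_give_one(self, sibling_graph):
        annot = {"g1": {"A", "B"}, "g2": {"A", "B"}}
        assert bma_gene_sim(sibling_graph, annot, "g1", "g2") == pytest.approx(1.0)

    def test_self_similarity_is_exactly_one(self, sim_bundle):
        annot = sim_bundle["annot"]
        graph = sim_bundle["graph"]
        for g in sorted(annot)[:5]:
            assert bma_gene_sim(graph, annot, g, g) == 1.0

    def test_one_by_two_hand_arithmetic(self, sibling_graph):
        annot = {"g1": {"A"}, "g2": {"A", "B"}}
        sim_ab = 0.8 * 2 / 3.6
        expected = (1.0 + (1.0 + sim_ab) / 2) / 2
        assert bma_gene_sim(sibling_graph, annot, "g1", "g2") == pytest.approx(expected)
        assert expected == pytest.approx(0.861, abs=5e-4)

    def test_missing_annotation_raises(self, sibling_graph):
        with pytest.raises(DomainError):
            bma_gene_sim(sibling_graph, {"g1": {"A"}}, "g1", "g2")

    @pytest.mark.parametrize("seed", range(3))
    def test_bounded_by_min_term_sim_and_one(self, seed):
        g = simulate_ontology(SimulationConfig(n_go_terms=10, dag_depth=3, seed=seed))
        terms = g.terms_in_namespace("biological_process")
        rng = np.random.default_rng(seed)
        annot = {
            "g1": set(rng.choice(terms, 3, replace=False)),
            "g2": set(rng.choice(terms, 2, replace=False)),
        }
        val = bma_gene_sim(g, annot, "g1", "g2")
        pair_sims = [wang_term_sim(g, a, b) for a in annot["g1"] for b in annot["g2"]]
        assert min(pair_sims) - 1e-12 <= val <= 1.0 + 1e-12


class TestGeneSimMatrix:
    def test_matrix_symmetric_unit_diagonal(self, sim_bundle):
        genes = sorted(sim_bundle["annot"])[:8]
        simm = gene_sim_matrix(sim_bundle["graph"], sim_bundle["annot"], genes)
        m = simm.bma.to_numpy()
        np.testing.assert_allclose(m, m.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert ((m >= 0) & (m <= 1 + 1e-12)).all()

    def test_unannotated_genes_dropped(self, sim_bundle):
        genes = sorted(sim_bundle["annot"])[:4] + ["GHOST"]
        simm = gene_sim_matrix(sim_bundle["graph"], sim_bundle["annot"], genes)
        assert "GHOST" not in simm.gene_ids
        assert len(simm.gene_ids) == 4


def _simm_from_matrix(values, genes):
    df = pd.DataFrame(values, index=genes, columns=genes, dtype=float)
    return GeneSimMatrix(gene_ids=list(genes), bma=df, namespace="biological_process")


class TestMSimsc:
    def test_identical_rows_reduce_to_squared_mean(self):
        genes = ["a", "b", "c", "d"]
        m = np.array(
            [
                [1.0, 0.5, 0.2, 0.4],
                [0.5, 1.0, 0.2, 0.4],
                [0.2, 0.2, 1.0, 0.3],
                [0.4, 0.4, 0.3, 1.0],
            ]
        )
        simm = _simm_from_matrix(m, genes)
        # rows a and b (self excluded) are both (0.5, 0.2, 0.4): mu = 0.36667
        mu = (0.5 + 0.2 + 0.4) / 3
        assert m_simsc(simm, "a", "b") == pytest.approx(mu**2)

    def test_hand_arithmetic_oracle(self):
        # arithmetic computed independently: mu/sd of each row excluding self
        genes = ["a", "b", "c"]
        m = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.8], [0.4, 0.8, 1.0]])
        simm = _simm_from_matrix(m, genes)
        mu1, d1 = np.mean([0.2, 0.4]), np.std([0.2, 0.4], ddof=1)
        mu2, d2 = np.mean([0.2, 0.8]), np.std([0.2, 0.8], ddof=1)
        expected = 0.5 * (d1**2 / d2**2 + d2**2 / d1**2) * ((mu1 + mu2) / 2) ** 2
        assert m_simsc(simm, "a", "b") == pytest.approx(expected, rel=1e-12)

    def test_spec_style_component_values(self):
        # variance factor and mean factor behave like the closed form
        mu1, mu2, d1, d2 = 0.2, 0.6, 0.1, 0.2
        expected = 0.5 * (d1**2 / d2**2 + d2**2 / d1**2) * ((mu1 + mu2) / 2) ** 2
        assert expected == pytest.approx(0.5 * (0.25 + 4.0) * 0.16)

    def test_symmetry(self, sim_bundle):
        genes = sorted(sim_bundle["annot"])[:6]
        simm = gene_sim_matrix(sim_bundle["graph"], sim_bundle["annot"], genes)
        for g1, g2 in itertools.combinations(simm.gene_ids, 2):
            assert m_simsc(simm, g1, g2) == pytest.approx(m_simsc(simm, g2, g1))

    @given(
        mus=st.tuples(
            st.floats(0.01, 1.0), st.floats(0.01, 1.0),
            st.floats(0.001, 0.5), st.floats(0.001, 0.5),
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_variance_factor_at_least_one(self, mus):
        mu1, mu2, d1, d2 = mus
        vf = 0.5 * (d1**2 / d2**2 + d2**2 / d1**2)
        assert vf >= 1.0 - 1e-12  # AM-GM
        score = vf * ((mu1 + mu2) / 2) ** 2
        assert score >= 0.0

    def test_single_gene_matrix_rejected(self):
        simm = _simm_from_matrix([[1.0]], ["a"])
        with pytest.raises(DomainError):
            m_simsc(simm, "a", "a")

    def test_matrix_populates_all_pairs(self, sim_bundle):
        genes = sorted(sim_bundle["annot"])[:5]
        simm = gene_sim_matrix(sim_bundle["graph"], sim_bundle["annot"], genes)
        mat = m_simsc_matrix(simm)
        assert np.isnan(np.diag(mat.to_numpy())).all()
        off = mat.to_numpy()[~np.eye(len(genes), dtype=bool)]
        assert np.isfinite(off).all() and (off >= 0).all()


class TestParseObo:
    def test_minimal_single_term(self, tmp_path):
        p = tmp_path / "one.obo"
        p.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:1\nname: root\n"
            "namespace: biological_process\n"
        )
        g = parse_obo(p)
        assert len(g.terms) == 1 and g.parents["GO:1"] == []

    def test_three_term_chain_topology(self, tmp_path):
        p = tmp_path / "chain.obo"
        p.write_text(
            "format-version: 1.2\n"
            "\n[Term]\nid: GO:1\nname: root\nnamespace: biological_process\n"
            "\n[Term]\nid: GO:2\nname: b\nnamespace: biological_process\nis_a: GO:1\n"
            "\n[Term]\nid: GO:3\nname: a\nnamespace: biological_process\nis_a: GO:2\n"
        )
        g = parse_obo(p)
        assert sum(len(ps) for ps in g.parents.values()) == 2
        order = list(nx.topological_sort(g.to_networkx().reverse()))
        assert order.index("GO:1") < order.index("GO:2") < order.index("GO:3")

    def test_obsolete_terms_dropped(self, tmp_path):
        p = tmp_path / "obs.obo"
        p.write_text(
            "format-version: 1.2\n"
            "\n[Term]\nid: GO:1\nname: root\nnamespace: biological_process\n"
            "\n[Term]\nid: GO:9\nname: gone\nnamespace: biological_process\n"
            "is_obsolete: true\n"
        )
        g = parse_obo(p)
        assert "GO:9" not in g.terms

    def test_other_relationships_ignored(self, tmp_path):
        p = tmp_path / "rel.obo"
        p.write_text(
            "format-version: 1.2\n"
            "\n[Term]\nid: GO:1\nname: root\nnamespace: biological_process\n"
            "\n[Term]\nid: GO:2\nname: b\nnamespace: biological_process\nis_a: GO:1\n"
            "relationship: regulates GO:1\n"
        )
        g = parse_obo(p)
        assert g.parents["GO:2"] == [("GO:1", "is_a")]

    def test_cycle_rejected(self, tmp_path):
        p = tmp_path / "cyc.obo"
        p.write_text(
            "format-version: 1.2\n"
            "\n[Term]\nid: GO:1\nname: a\nnamespace: biological_process\nis_a: GO:2\n"
            "\n[Term]\nid: GO:2\nname: b\nnamespace: biological_process\nis_a: GO:1\n"
        )
        with pytest.raises(FormatError):
            parse_obo(p)
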