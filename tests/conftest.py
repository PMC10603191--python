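import pytest

from mgti.go_similarity import GOGraph
from mgti.synthetic_data import (
    SimulationConfig,
    simulate_annotations,
    simulate_evidence,
    simulate_expression,
    simulate_ontology,
)


def make_graph(edges, extra_terms=(), namespace="biological_process"):
    """Build a GOGraph from (child, parent, etype) triples; terms inferred."""
    terms = {}
    parents = {}
    for child, parent, etype in edges:
        for t in (child, parent):
            terms.setdefault(t, (t, namespace))
            parents.setdefault(t, [])
        parents[child].append((parent, etype))
    for t in extra_terms:
        terms.setdefault(t, (t, namespace))
        parents.setdefault(t, [])
    return GOGraph(terms=terms, parents=parents)


@pytest.fixture
def chain_graph():
    """A is_a B is_a ROOT."""
    return make_graph([("B", "ROOT", "is_a"), ("A", "B", "is_a")])


@pytest.fixture
def sibling_graph():
    """A and B both is_a ROOT."""
    return make_graph([("A", "ROOT", "is_a"), ("B", "ROOT", "is_a")])


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_genes=80,
        n_samples_per_group=5,
        frac_de=0.1,
        effect_size=3.0,
        noise_sd=1.0,
        n_go_terms=40,
        dag_depth=4,
        annotations_per_gene=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def sim_bundle(small_cfg):
    expr, truth = simulate_expression(small_cfg)
    graph = simulate_ontology(small_cfg)
    annot = simulate_annotations(small_cfg, graph, truth)
    evidence = simulate_evidence(small_cfg, truth)
    return {"expr": expr, "truth": truth, "graph": graph, "annot": annot, "evidence": evidence}
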