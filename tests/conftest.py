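import pytest

from varlr.fixtures import FixtureSpec, make_diseases, make_ontology
from varlr.ontology import OntologyGraph

# the worked six-term chain: child -> parent lineage up to the root of the
# abnormality subontology, plus a sibling child of "short stature"
CHAIN_PARENTS = {
    "pituitary dwarfism": {"short stature"},
    "birth length less than 3rd percentile": {"short stature"},
    "short stature": {"abnormality of body height"},
    "abnormality of body height": {"growth delay"},
    "growth delay": {"growth abnormality"},
    "growth abnormality": {"phenotypic abnormality"},
}
CHAIN_ROOT = "phenotypic abnormality"


@pytest.fixture
def chain_graph():
    genes = [
        ("pituitary dwarfism", "GH1"),
        ("pituitary dwarfism", "POU1F1"),
        ("birth length less than 3rd percentile", "FGFR3"),
        ("short stature", "SHOX"),
        ("growth delay", "PTPN11"),
    ]
    return OntologyGraph.build(CHAIN_PARENTS, CHAIN_ROOT, genes)


@pytest.fixture
def diamond_graph():
    # root -> {a, b} -> c (two parents); gene sets shrink downward
    parents = {"a": {"root"}, "b": {"root"}, "c": {"a", "b"}}
    genes = [
        ("c", "g1"),
        ("c", "g2"),
        ("a", "g3"),
        ("a", "g4"),
        ("b", "g5"),
        ("root", "g6"),
        ("root", "g7"),
        ("root", "g8"),
    ]
    return OntologyGraph.build(parents, "root", genes)


def random_graph(seed, n_terms=30, depth=4, n_genes=15):
    spec = FixtureSpec(seed=seed, n_terms=n_terms, dag_depth=depth,
                       n_genes=n_genes, n_diseases=min(8, n_genes))
    graph, _ = make_ontology(spec)
    return graph


def random_corpus(seed, n_terms=30, depth=4, n_genes=15, n_diseases=8):
    spec = FixtureSpec(seed=seed, n_terms=n_terms, dag_depth=depth,
                       n_genes=n_genes, n_diseases=n_diseases)
    graph, _ = make_ontology(spec)
    return graph, make_diseases(spec, graph)
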