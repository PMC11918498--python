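"""Phenotype ontology graph: ancestral closures, frequency propagation, information content.

The graph is the "is a" DAG of phenotype terms.  Every term carries the set of
genes annotated at or below it (downward-closed), which drives the
information-content score used to rank patient phenotypes.  Per-disease
frequency annotations are propagated up the DAG into a lookup table keyed on
the ancestral closure of the annotated terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .errors import CyclicOntologyError, OntologyError, UnknownTermError

__all__ = [
    "OntologyGraph",
    "FrequencyTable",
    "ancestral_closure",
    "closure_of_set",
    "build_frequency_table",
    "information_content",
]


@dataclass
class OntologyGraph:
    """An "is a" DAG of phenotype terms with downward-closed gene sets.

    Attributes
    ----------
    terms
        All term IDs in the graph.
    parents
        Map term -> set of parent term IDs ("is a" edges, child to parent).
        The root has no entry (or an empty set).
    root
        The single term with no parents; every other term reaches it.
    gene_sets
        Map term -> frozenset of gene IDs annotated at or below the term.
        Monotone along edges: gene_sets[child] <= gene_sets[parent].
    """

    terms: frozenset
    parents: Mapping
    root: str
    gene_sets: Mapping
    _closure_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def build(
        cls,
        parents: Mapping,
        root: str,
        term_genes: Iterable = (),
    ) -> "OntologyGraph":
        """Validate structure and propagate gene annotations upward.

        Parameters
        ----------
        parents
            Map term -> iterable of parent term IDs.
        root
            Root term ID.  Must have no parents.
        term_genes
            Iterable of ``(term_id, gene_id)`` annotation pairs.  Each gene is
            added to the term and to every term in its ancestral closure,
            which enforces the downward-closed (monotone) invariant by
            construction.
        """
        terms = set(parents) | {root}
        for ps in parents.values():
            terms |= set(ps)
        parent_map = {t: frozenset(parents.get(t, ())) for t in terms}
        if parent_map[root]:
            raise OntologyError(f"root {root!r} must not have parents")

        dag = nx.DiGraph()
        dag.add_nodes_from(terms)
        dag.add_edges_from((c, p) for c, ps in parent_map.items() for p in ps)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise CyclicOntologyError(f"'is a' relation contains a cycle: {cycle}")
        for t in terms:
            if t != root and root not in nx.descendants(dag, t):
                raise OntologyError(f"term {t!r} cannot reach root {root!r}")

        graph = cls(
            terms=frozenset(terms),
            parents=parent_map,
            root=root,
            gene_sets={},
        )
        sets: dict = {t: set() for t in terms}
        for term, gene in term_genes:
            if term not in terms:
                raise UnknownTermError(f"gene annotation references unknown term {term!r}")
            for anc in ancestral_closure(term, graph):
                sets[anc].add(gene)
        graph.gene_sets = {t: frozenset(s) for t, s in sets.items()}
        return graph

    def __contains__(self, term: str) -> bool:
        return term in self.terms


@dataclass(frozen=True)
class FrequencyTable:
    """Per-disease propagated phenotype-frequency lookup table.

    Keys of ``freq`` are exactly the ancestral closure of the disease's
    annotated terms; values are in (0, 1] and monotone non-decreasing from
    child to parent along annotated lineages.
    """

    disease: str
    freq: Mapping

    def __contains__(self, term: str) -> bool:
        return term in self.freq


def ancestral_closure(term: str, graph: OntologyGraph) -> frozenset:
    """Return ``term`` plus every term on any path from it to the root."""
    if term not in graph.terms:
        raise UnknownTermError(f"unknown term {term!r}")
    cached = graph._closure_cache.get(term)
    if cached is not None:
        return cached
    seen = {term}
    stack = [term]
    while stack:
        for p in graph.parents.get(stack.pop(), ()):
            if p not in seen:
                seen.add(p)
                stack.append(p)
    closure = frozenset(seen)
    graph._closure_cache[term] = closure
    return closure


def closure_of_set(terms: Iterable, graph: OntologyGraph) -> frozenset:
    """Union of the ancestral closures of every term in ``terms``."""
    out: set = set()
    for t in terms:
        out |= ancestral_closure(t, graph)
    return frozenset(out)


def build_frequency_table(
    disease_annotations: Mapping,
    graph: OntologyGraph,
    disease: str = "",
) -> FrequencyTable:
    """Propagate annotated disease-phenotype frequencies up the DAG.

    Every term in the ancestral closure of the annotated set receives the
    maximum frequency over all annotated descendants whose closure contains
    it (a term's own annotation counts as one such descendant).  When a term
    has several annotated child lineages only the highest frequency is kept:
    co-expression of sibling phenotypes is unknown, so the maximum is the
    tightest defensible lower bound.
    """
    table: dict = {}
    for term, f in disease_annotations.items():
        if term not in graph.terms:
            raise UnknownTermError(
                f"disease annotation references unknown term {term!r}"
            )
        if not (0.0 < f <= 1.0):
            raise OntologyError(
                f"frequency for {term!r} must be in (0, 1], got {f!r}"
            )
        for anc in ancestral_closure(term, graph):
            if f > table.get(anc, 0.0):
                table[anc] = f
    return FrequencyTable(disease=disease, freq=table)


def information_content(term: str, graph: OntologyGraph) -> float:
    """Gene-annotation information content of ``term``, in bits.

    IC(t) = -log2(|G_t| / |intersection of parent gene sets|), with
    IC(root) = 0.  More specific terms — fewer annotated genes relative to
    their ancestors — score higher.  A term with no annotated genes is
    treated as maximally specific: IC = log2(|G_root|), which keeps the score
    finite while dominating every annotated sibling.
    """
    if term not in graph.terms:
        raise UnknownTermError(f"unknown term {term!r}")
    if term == graph.root:
        return 0.0
    n_root = len(graph.gene_sets.get(graph.root, ()))
    n_term = len(graph.gene_sets.get(term, ()))
    if n_term == 0:
        return math.log2(n_root) if n_root > 0 else 0.0
    parent_sets = [graph.gene_sets.get(p, frozenset()) for p in graph.parents[term]]
    inter = frozenset.intersection(*parent_sets) if parent_sets else frozenset()
    # gene sets are monotone, so the intersection contains G_term; guard anyway
    denom = max(len(inter), n_term, 1)
    return max(0.0, -math.log2(n_term / denom))
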