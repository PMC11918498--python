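"""Phenotype likelihood ratio.

Patient terms are ranked (information content for clinician-curated sets,
occurrence counts for NLP-derived sets), per-term likelihood ratios are taken
against a disease's propagated frequency table, and the joint LR is maximized
over incremental prefixes of the ranking.  The prefix maximization is what
makes the score robust to large, noisy phenotype sets: irrelevant terms with
per-term LR below 1 simply never enter the best subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import NoPhenotypesError, UnknownTermError
from .ontology import (
    FrequencyTable,
    OntologyGraph,
    ancestral_closure,
    information_content,
)

__all__ = [
    "RankedPhenotypes",
    "PhenoLRResult",
    "rank_terms",
    "prob_term_given_disease",
    "prob_term_background",
    "compute_pheno_lr",
]

logger = logging.getLogger(__name__)

MANUAL = "manual"
COMPUTATIONAL = "computational"


@dataclass(frozen=True)
class RankedPhenotypes:
    """Patient phenotype terms ordered most-informative first."""

    terms: tuple
    scores: tuple  # ranking keys, non-increasing
    source: str

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class PhenoLRResult:
    """Joint phenotype LR for one (case, disease) pair."""

    lr_pheno: float
    best_subset_size: int
    per_size_lr: tuple
    per_term_lr: Mapping


def rank_terms(
    terms: Iterable,
    counts: Optional[Mapping] = None,
    graph: Optional[OntologyGraph] = None,
    source: str = MANUAL,
) -> RankedPhenotypes:
    """Deduplicate, resolve and sort patient phenotype terms.

    ``source="manual"`` sorts by information content descending (clinician
    sets lean specific); ``source="computational"`` sorts by occurrence count
    descending and requires ``counts``.  Terms absent from the graph are
    dropped with a warning.  Ties break on term ID for determinism.
    """
    if source not in (MANUAL, COMPUTATIONAL):
        raise ValueError(f"unknown phenotype source {source!r}")
    if source == COMPUTATIONAL and counts is None:
        raise ValueError("computational ranking requires occurrence counts")

    seen: dict = {}
    for t in terms:
        seen.setdefault(t, None)
    usable = []
    for t in seen:
        if graph is not None and t not in graph:
            logger.warning("dropping unresolvable phenotype term %s", t)
            continue
        usable.append(t)
    if not usable:
        raise NoPhenotypesError("no phenotype terms resolvable in the ontology")

    if source == MANUAL:
        if graph is None:
            raise ValueError("manual ranking requires the ontology graph")
        keyed = [(information_content(t, graph), t) for t in usable]
    else:
        keyed = [(float(counts.get(t, 0)), t) for t in usable]
    keyed.sort(key=lambda kv: (-kv[0], kv[1]))
    return RankedPhenotypes(
        terms=tuple(t for _, t in keyed),
        scores=tuple(k for k, _ in keyed),
        source=source,
    )


def prob_term_given_disease(
    x_p: str,
    disease_table: FrequencyTable,
    graph: OntologyGraph,
) -> float:
    """Pr(patient term | disease) from the propagated frequency table.

    If the term is inside the disease's closed table its propagated frequency
    is returned directly.  Otherwise the highest-frequency common ancestor
    x_ca* (the table always contains the root, so one exists) is found and
    its frequency is scaled down by the gene-count ratio |G_term| / |G_ca*|,
    reflecting how much more specific the patient term is than the shared
    context.
    """
    if x_p in disease_table.freq:
        return disease_table.freq[x_p]
    closure = ancestral_closure(x_p, graph)
    common = [t for t in closure if t in disease_table.freq]
    if not common:
        raise UnknownTermError(
            f"term {x_p!r} shares no ancestor with disease {disease_table.disease!r}"
        )
    x_ca = max(common, key=lambda t: (disease_table.freq[t], t))
    n_term = max(1, len(graph.gene_sets.get(x_p, ())))
    n_ca = max(n_term, len(graph.gene_sets.get(x_ca, ())))
    return disease_table.freq[x_ca] * n_term / n_ca


def prob_term_background(x_p: str, corpus: Sequence) -> float:
    """Pr(patient term | no disease): smoothed share of diseases whose closed
    table contains the term.

    Add-one smoothing keeps the value strictly inside (0, 1) so terms absent
    from every disease never zero out a likelihood ratio.
    """
    if not corpus:
        raise ValueError("background corpus is empty")
    count = sum(1 for table in corpus if x_p in table.freq)
    return (count + 1) / (len(corpus) + 2)


def compute_pheno_lr(
    ranked: RankedPhenotypes,
    disease_table: FrequencyTable,
    corpus: Sequence,
    graph: OntologyGraph,
    subset_max: int = 10,
) -> PhenoLRResult:
    """Maximize the joint phenotype LR over prefixes of the ranked terms.

    per_size_lr[i-1] is the product of per-term LRs over the i top-ranked
    terms, for i = 1 .. min(len(ranked), subset_max); the result is the
    maximum of that vector, with the smallest prefix winning ties.
    """
    if len(ranked) == 0:
        raise NoPhenotypesError("cannot score an empty phenotype ranking")
    if subset_max < 1:
        raise ValueError("subset_max must be >= 1")

    per_term = {}
    for t in ranked.terms:
        p_d = prob_term_given_disease(t, disease_table, graph)
        p_bg = prob_term_background(t, corpus)
        per_term[t] = p_d / p_bg

    limit = min(len(ranked), subset_max)
    per_size = []
    product = 1.0
    for t in ranked.terms[:limit]:
        product *= per_term[t]
        per_size.append(product)

    best_idx = max(range(limit), key=lambda i: (per_size[i], -i))
    return PhenoLRResult(
        lr_pheno=per_size[best_idx],
        best_subset_size=best_idx + 1,
        per_size_lr=tuple(per_size),
        per_term_lr=per_term,
    )
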