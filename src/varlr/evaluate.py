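"""Cohort-level accuracy metrics for ranked candidate genes.

Precision-recall is computed by pooling (score, label) pairs across cases —
per-gene, not per-case — which keeps nondiagnostic cases informative.  Rank
metrics use worst-case (maximum) rank among score ties, the conservative
deterministic choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score

__all__ = [
    "RankedCohort",
    "pr_auc",
    "mean_rank",
    "top_n",
    "diagnostic_recall",
    "cohort_metrics",
    "stratified_metrics",
]


@dataclass
class RankedCohort:
    """Per-case ranked candidates plus truth labels.

    ``cases`` maps case ID to a list of ``(gene, score)`` pairs; ``truth``
    maps case ID to the (possibly empty) set of diagnostic genes; ``strata``
    optionally maps case ID to a stratum name (e.g. trio/duo/singleton).
    """

    cases: Mapping
    truth: Mapping
    strata: Mapping = field(default_factory=dict)

    def subset(self, case_ids) -> "RankedCohort":
        ids = set(case_ids)
        return RankedCohort(
            cases={c: v for c, v in self.cases.items() if c in ids},
            truth={c: v for c, v in self.truth.items() if c in ids},
            strata={c: v for c, v in self.strata.items() if c in ids},
        )


def _pooled(cohort: RankedCohort):
    scores, labels = [], []
    for case_id, candidates in cohort.cases.items():
        positives = cohort.truth.get(case_id, set())
        for gene, score in candidates:
            scores.append(score)
            labels.append(gene in positives)
    return np.asarray(scores, dtype=float), np.asarray(labels, dtype=bool)


def pr_auc(cohort: RankedCohort) -> float:
    """Area under the pooled per-gene precision-recall curve."""
    scores, labels = _pooled(cohort)
    if not labels.any():
        raise ValueError("cohort has no positive labels; PR curve undefined")
    return float(average_precision_score(labels, scores))


def _tie_max_ranks(candidates: Sequence) -> Dict:
    """Rank of each gene with ties taking the worst (maximum) rank."""
    scores = np.array([s for _, s in candidates], dtype=float)
    ranks = {}
    for gene, s in candidates:
        ranks[gene] = int((scores >= s).sum())
    return ranks


def _case_ranks(cohort: RankedCohort) -> Dict:
    """Best diagnostic-gene rank per diagnosed case whose gene survived.

    Cases whose diagnostic gene(s) were all filtered out have no rank and are
    excluded here; they still count against top-N and diagnostic recall.
    """
    out = {}
    for case_id, positives in cohort.truth.items():
        if not positives:
            continue
        candidates = cohort.cases.get(case_id, [])
        ranks = _tie_max_ranks(candidates)
        present = [ranks[g] for g in positives if g in ranks]
        if present:
            out[case_id] = min(present)
    return out


def mean_rank(cohort: RankedCohort) -> float:
    """Mean diagnostic-gene rank over diagnosed cases (best gene per case)."""
    ranks = _case_ranks(cohort)
    if not ranks:
        raise ValueError("no diagnosed case has a ranked diagnostic gene")
    return float(np.mean(list(ranks.values())))


def top_n(cohort: RankedCohort, n: int) -> float:
    """Fraction of diagnosed cases with a diagnostic gene ranked <= n.

    The denominator is every diagnosed case; a case whose diagnostic gene was
    filtered out of the candidate list counts as a miss.
    """
    diagnosed = [c for c, pos in cohort.truth.items() if pos]
    if not diagnosed:
        raise ValueError("cohort has no diagnosed cases")
    ranks = _case_ranks(cohort)
    hits = sum(1 for c in diagnosed if ranks.get(c, n + 1) <= n)
    return hits / len(diagnosed)


def diagnostic_recall(cohort: RankedCohort) -> float:
    """Fraction of diagnostic genes surviving into the candidate lists."""
    total, recovered = 0, 0
    for case_id, positives in cohort.truth.items():
        genes = {g for g, _ in cohort.cases.get(case_id, [])}
        for g in positives:
            total += 1
            recovered += g in genes
    if total == 0:
        raise ValueError("cohort has no truth labels")
    return recovered / total


def cohort_metrics(cohort: RankedCohort, top_ns=(1, 5, 10)) -> Dict:
    """Bundle of the standard metrics for one cohort (or stratum)."""
    diagnosed = [c for c, pos in cohort.truth.items() if pos]
    out = {
        "n_cases": len(cohort.cases),
        "n_diagnosed": len(diagnosed),
    }
    if diagnosed:
        out["pr_auc"] = pr_auc(cohort)
        out["diagnostic_recall"] = diagnostic_recall(cohort)
        try:
            out["mean_rank"] = mean_rank(cohort)
        except ValueError:
            out["mean_rank"] = None
        for n in top_ns:
            out[f"top_{n}"] = top_n(cohort, n)
    return out


def stratified_metrics(cohort: RankedCohort, top_ns=(1, 5, 10)) -> Dict:
    """Metrics overall and per stratum (trio/duo/singleton or custom)."""
    result = {"overall": cohort_metrics(cohort, top_ns)}
    for stratum in sorted(set(cohort.strata.values())):
        ids = [c for c, s in cohort.strata.items() if s == stratum]
        result[stratum] = cohort_metrics(cohort.subset(ids), top_ns)
    return result
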