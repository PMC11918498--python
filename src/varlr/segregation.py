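"""Segregation likelihood ratio from trio/duo/singleton inheritance patterns.

Observed inheritance of a gene's contributing variants is compared with the
candidate disease's mode of inheritance.  The LR is a fixed heuristic scale:
10 for a match, 0.1 for a mismatch (tolerating incomplete penetrance),
1 when no parental data is available; with a single parent the evidence is
partial and the match/mismatch value is square-rooted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple

from .genotype import AD, AR, CandidateGene, n_alt_alleles

__all__ = [
    "Pedigree",
    "MATCH",
    "MISMATCH",
    "UNKNOWN",
    "classify_inheritance",
    "compute_seg_lr",
]

logger = logging.getLogger(__name__)

MATCH = "match"
MISMATCH = "mismatch"
UNKNOWN = "unknown"

_BASE_LR = {MATCH: 10.0, MISMATCH: 0.1, UNKNOWN: 1.0}


@dataclass(frozen=True)
class Pedigree:
    """Proband-centric view of a PED file."""

    proband: str
    father: Optional[str] = None
    mother: Optional[str] = None
    affected: Mapping = field(default_factory=dict)  # sample -> bool

    @property
    def parents(self) -> Tuple:
        return tuple(p for p in (self.mother, self.father) if p)

    def is_affected(self, sample: str) -> bool:
        return bool(self.affected.get(sample, False))


def _usable_parents(g: CandidateGene, ped: Pedigree):
    """Parents with a called genotype at every contributing site.

    A listed parent missing a call at any contributing site is treated as
    absent for this gene (logged), per the partial-evidence model.
    """
    usable = []
    for p in ped.parents:
        calls = [n_alt_alleles(v.genotypes.get(p)) for v in g.variants]
        if any(c is None for c in calls):
            logger.debug(
                "parent %s lacks a genotype at a contributing site of %s; "
                "treated as absent",
                p,
                g.gene,
            )
            continue
        usable.append(p)
    return usable


def classify_inheritance(g: CandidateGene, ped: Pedigree):
    """Classify observed inheritance against the gene's MOI.

    Returns ``(classification, parents_available)`` where classification is
    one of MATCH / MISMATCH / UNKNOWN and parents_available counts parents
    with usable genotype data (0, 1 or 2).

    Dominant: de novo (no parent carries) matches; transmission from an
    affected parent matches; transmission from an unaffected parent
    mismatches.  Recessive homozygous: every available parent must carry the
    allele.  Recessive compound het: the two alleles must be attributable to
    different parents (in trans); two variants forced onto one parental
    haplotype (in cis) mismatch.  No usable parents: unknown.
    """
    parents = _usable_parents(g, ped)
    n_avail = len(parents)
    if n_avail == 0:
        return UNKNOWN, 0

    if g.moi == AD:
        v = g.variants[0]
        carriers = [p for p in parents if n_alt_alleles(v.genotypes[p])]
        if not carriers:
            return MATCH, n_avail  # consistent with de novo
        if any(ped.is_affected(p) for p in carriers):
            return MATCH, n_avail
        return MISMATCH, n_avail

    if g.moi == AR:
        if len(g.variants) == 1:
            # homozygous (or single variant contributing both alleles)
            v = g.variants[0]
            for p in parents:
                if not n_alt_alleles(v.genotypes[p]):
                    return MISMATCH, n_avail
            return MATCH, n_avail
        # compound heterozygous: which parents carry each allele?
        va, vb = g.variants[0], g.variants[1]
        carriers_a = frozenset(p for p in parents if n_alt_alleles(va.genotypes[p]))
        carriers_b = frozenset(p for p in parents if n_alt_alleles(vb.genotypes[p]))
        if n_avail == 1:
            p = parents[0]
            both = p in carriers_a and p in carriers_b
            return (MISMATCH if both else MATCH), n_avail
        # two parents: mismatch only when one parent carries both alleles and
        # the other carries neither — cis is then forced; any configuration
        # admitting a trans assignment (de novo counting as a wildcard) matches
        if len(carriers_a) == 1 and carriers_a == carriers_b:
            return MISMATCH, n_avail
        return MATCH, n_avail

    raise ValueError(f"unsupported mode of inheritance {g.moi!r}")


def compute_seg_lr(classification: str, parents_available: int) -> float:
    """Map a classification to its heuristic LR value.

    Codomain is exactly {0.1, sqrt(0.1), 1, sqrt(10), 10}: full-strength with
    two parents, square-rooted with one, and always 1 when inheritance is
    undetermined.
    """
    if classification not in _BASE_LR:
        raise ValueError(f"unknown classification {classification!r}")
    if parents_available not in (0, 1, 2):
        raise ValueError(f"parents_available must be 0, 1 or 2")
    base = _BASE_LR[classification]
    if classification == UNKNOWN:
        return 1.0
    if parents_available == 1:
        return math.sqrt(base)
    return base
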