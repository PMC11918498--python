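"""Genotype likelihood ratio: variant filtering, pathogenicity heuristics, MOI aggregation.

The filter chain mirrors a clinical preprocessing pipeline: artifact regions,
quality/depth, proband-allele validation, normalization, then the three
annotation filters (common in gnomAD, nonexonic, synonymous) with two
rescues — canonical splice sites escape the exonic filter, and anything with
submitted pathogenic significance in ClinVar escapes all three.

Pathogenicity scores come from pluggable predictor annotations; the heuristics
here only decide how to use them per functional class.  LR_geno is computed
once per gene (it is identical across diseases sharing the gene's candidate
variants) as agg_pathogenicity * disease_freq / max(f_pop, f_floor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .errors import MissingSampleError

__all__ = [
    "Variant",
    "CandidateGene",
    "GenotypeConfig",
    "preprocess_variants",
    "score_pathogenicity",
    "aggregate_gene",
    "compute_geno_lr",
    "n_alt_alleles",
]

logger = logging.getLogger(__name__)

AD = "AD"
AR = "AR"

FUNC_EFFECTS = frozenset(
    {
        "frameshift",
        "startloss",
        "stoploss",
        "nonsynonymous_snv",
        "nonframeshift_indel",
        "synonymous",
        "splice_canonical",
        "intronic",
        "other_exonic",
        "nonexonic",
    }
)

# classes assigned probability one outright
_LOF_EFFECTS = frozenset({"frameshift", "startloss", "stoploss"})
# classes removed by the nonexonic filter unless rescued
_NONEXONIC_EFFECTS = frozenset({"intronic", "nonexonic"})


@dataclass(frozen=True)
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float = 0.0
    depth: int = 0
    genotypes: Mapping = field(default_factory=dict)  # sample -> "0/1" etc.
    func_effect: str = "other_exonic"
    gene: str = ""
    gnomad_freq: Optional[float] = None  # max subpopulation frequency
    cohort_freq: Optional[float] = None
    clinvar_pathogenic: bool = False
    predictor_score: Optional[float] = None

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.func_effect not in FUNC_EFFECTS:
            raise ValueError(f"unknown functional effect {self.func_effect!r}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class CandidateGene:
    """A gene surviving aggregation, with its contributing variants."""

    gene: str
    variants: tuple  # contributing variants (those entering agg_pathogenicity)
    moi: str  # AD | AR
    agg_pathogenicity: float
    lr_geno: Optional[float] = None
    all_scored: tuple = ()


@dataclass(frozen=True)
class GenotypeConfig:
    quality_min: float = 20.0
    depth_min: int = 8
    gnomad_max: float = 0.01
    cohort_mode: bool = False
    cohort_quality_min: float = 50.0
    cohort_max: float = 0.02
    score_min: float = 0.5
    indel_scoring: bool = False  # dedicated inframe-indel predictor off by default
    indel_default_score: float = 0.5
    clinvar_floor: float = 0.95
    f_floor: float = 1e-6
    disease_freq_default: float = 1e-4


def n_alt_alleles(gt: Optional[str]) -> Optional[int]:
    """Count ALT alleles in a diploid GT string; None for missing ('./.')."""
    if gt is None:
        return None
    gt = gt.replace("|", "/")
    if "." in gt:
        return None
    return sum(1 for a in gt.split("/") if a != "0")


def _trim_alleles(v: Variant) -> Variant:
    """Minimal left-alignment: trim shared suffix then shared prefix bases.

    Reference-free, so this only canonicalizes padding, not repeat placement.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (ref, alt, pos) == (v.ref, v.alt, v.pos):
        return v
    return replace(v, ref=ref, alt=alt, pos=pos)


def _in_regions(v: Variant, regions: Sequence) -> bool:
    p0 = v.pos - 1  # BED is 0-based half-open
    return any(c == v.chrom and s <= p0 < e for c, s, e in regions)


def preprocess_variants(
    variants: Iterable,
    config: GenotypeConfig,
    proband: str,
    artifact_regions: Optional[Sequence] = None,
):
    """Filter raw variants down to the candidate list.

    Returns ``(kept, removed)`` where ``removed`` is a list of
    ``(variant, reason)`` pairs; ``len(kept) + len(removed)`` always equals
    the input count.  ClinVar-pathogenic variants bypass the gnomAD,
    nonexonic and synonymous filters but not artifact/quality/proband checks.
    """
    kept, removed = [], []
    regions = artifact_regions or ()

    def drop(v: Variant, reason: str) -> None:
        logger.debug("removed %s: %s", v.key, reason)
        removed.append((v, reason))

    for v in variants:
        if _in_regions(v, regions):
            drop(v, "artifact_region")
            continue
        if v.qual < config.quality_min:
            drop(v, "low_quality")
            continue
        if v.depth < config.depth_min:
            drop(v, "low_depth")
            continue
        if config.cohort_mode:
            if v.qual < config.cohort_quality_min:
                drop(v, "cohort_quality")
                continue
            if v.cohort_freq is not None and v.cohort_freq > config.cohort_max:
                drop(v, "cohort_frequency")
                continue
        if proband not in v.genotypes:
            raise MissingSampleError(
                f"proband sample {proband!r} absent from variant {v.key}"
            )
        alt_count = n_alt_alleles(v.genotypes[proband])
        if not alt_count:
            drop(v, "no_proband_alt")
            continue
        v = _trim_alleles(v)
        if not v.clinvar_pathogenic:
            if v.gnomad_freq is not None and v.gnomad_freq > config.gnomad_max:
                drop(v, "common_gnomad")
                continue
            if v.func_effect in _NONEXONIC_EFFECTS:
                # canonical splice variants are rescued from this filter
                drop(v, "nonexonic")
                continue
            if v.func_effect == "synonymous":
                drop(v, "synonymous")
                continue
        kept.append(v)
    return kept, removed


def score_pathogenicity(v: Variant, config: GenotypeConfig):
    """Assign a pathogenic probability to a preprocessed variant.

    Returns ``(score, None)`` or ``(None, reason)`` when the variant is
    heuristically omitted.  Frameshift/start-loss/stop-loss get probability
    one; nonsynonymous SNVs and canonical splice variants take their
    predictor annotation; inframe indels take theirs unless indel scoring is
    disabled (the shipped default), in which case they get 0.5 flat.  Scores
    below ``score_min`` are omitted.  ClinVar-pathogenic variants are floored
    at ``clinvar_floor`` and never omitted.
    """
    score: Optional[float] = None
    reason: Optional[str] = None
    eff = v.func_effect
    if eff in _LOF_EFFECTS:
        score = 1.0
    elif eff == "nonsynonymous_snv":
        if v.predictor_score is None:
            reason = "missing_predictor_score"
        else:
            score = v.predictor_score
    elif eff == "nonframeshift_indel":
        if config.indel_scoring:
            if v.predictor_score is None:
                reason = "missing_predictor_score"
            else:
                score = v.predictor_score
        else:
            score = config.indel_default_score
    elif eff == "splice_canonical":
        if v.predictor_score is None:
            reason = "missing_predictor_score"
        else:
            score = v.predictor_score
    else:
        reason = "unscored_class"

    if v.clinvar_pathogenic:
        return max(score or 0.0, config.clinvar_floor), None
    if score is None:
        logger.debug("omitted %s: %s", v.key, reason)
        return None, reason
    if score < config.score_min:
        logger.debug("omitted %s: below_threshold (%.3f)", v.key, score)
        return None, "below_threshold"
    return score, None


def aggregate_gene(
    scored: Sequence,
    moi: str,
    proband: str,
) -> Optional[CandidateGene]:
    """Aggregate scored variants of one gene under a mode of inheritance.

    ``scored`` is a sequence of ``(variant, score)`` pairs that survived
    :func:`score_pathogenicity`.  Dominant: the top-scoring variant alone.
    Recessive: the mean of the top two allele scores, a homozygous variant
    contributing two alleles at its score; genes with fewer than two alleles
    are omitted (returns None).
    """
    if moi not in (AD, AR):
        raise ValueError(f"unsupported mode of inheritance {moi!r}")
    if not scored:
        return None
    ordered = sorted(scored, key=lambda vs: (-vs[1], vs[0].key))
    if moi == AD:
        top_v, top_s = ordered[0]
        return CandidateGene(
            gene=top_v.gene,
            variants=(top_v,),
            moi=AD,
            agg_pathogenicity=top_s,
            all_scored=tuple(ordered),
        )
    # recessive: expand per-allele scores
    alleles = []
    for v, s in ordered:
        n = n_alt_alleles(v.genotypes.get(proband)) or 0
        alleles.extend([(v, s)] * n)
    if len(alleles) < 2:
        logger.debug(
            "omitted gene %s: %d allele(s) under AR", ordered[0][0].gene, len(alleles)
        )
        return None
    top2 = alleles[:2]  # ordered already sorts by score desc
    contributing = tuple({v.key: v for v, _ in top2}.values())
    agg = (top2[0][1] + top2[1][1]) / 2.0
    return CandidateGene(
        gene=top2[0][0].gene,
        variants=contributing,
        moi=AR,
        agg_pathogenicity=agg,
        all_scored=tuple(ordered),
    )


def compute_geno_lr(
    g: CandidateGene,
    disease_freq: float,
    config: GenotypeConfig,
) -> float:
    """LR_geno = agg_pathogenicity * disease_freq / max(f_pop, f_floor).

    f_pop is the maximum gnomAD frequency among contributing variants; a
    variant never observed in the population counts as the floor (absence of
    observation is evidence of rarity).
    """
    if disease_freq <= 0:
        raise ValueError(f"disease frequency must be positive, got {disease_freq!r}")
    freqs = [v.gnomad_freq for v in g.variants if v.gnomad_freq is not None]
    f_pop = max(freqs) if freqs else config.f_floor
    return g.agg_pathogenicity * disease_freq / max(f_pop, config.f_floor)
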