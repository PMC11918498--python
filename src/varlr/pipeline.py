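"""End-to-end case and cohort execution.

run_case: preprocess variants -> score genes under their MOI -> per-disease
LR_pheno -> LR_seg -> composite -> posterior -> ranked TSV.  run_cohort loops
cases against shared resources and aggregates a cohort summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import evaluate, io
from .config import RunConfig
from .errors import VarlrError
from .genotype import (
    AD,
    CandidateGene,
    aggregate_gene,
    compute_geno_lr,
    preprocess_variants,
    score_pathogenicity,
)
from .ontology import OntologyGraph, build_frequency_table
from .phenotype import compute_pheno_lr, rank_terms
from .scoring import (
    CaseScores,
    GaussianCalibration,
    LikelihoodBundle,
    composite_score,
    odds_posterior,
    rank_bundles,
)
from .segregation import Pedigree, classify_inheritance, compute_seg_lr

logger = logging.getLogger(__name__)

OUTPUT_COLUMNS = (
    "gene",
    "disease",
    "lr_pheno",
    "lr_geno",
    "lr_seg",
    "composite_log10",
    "posterior",
    "rank",
)


@dataclass
class Resources:
    """Shared reference data loaded once per run."""

    graph: OntologyGraph
    disease_tables: Dict  # disease -> FrequencyTable
    corpus: List  # list of FrequencyTable (background)
    disease_genes: Dict  # disease -> {gene, moi, prevalence}
    gene_diseases: Dict  # gene -> [disease, ...]
    artifact_regions: List = field(default_factory=list)


@dataclass
class Case:
    case_id: str
    ped: Pedigree
    variants: List
    terms: List
    counts: Optional[Dict] = None
    stratum: str = ""


def load_resources(config: RunConfig) -> Resources:
    graph = io.load_ontology(config.ontology, config.gene_annotations)
    annotations = io.load_disease_annotations(config.disease_annotations)
    disease_genes = io.load_disease_genes(config.disease_genes)
    tables, gene_diseases = {}, {}
    for disease, info in sorted(disease_genes.items()):
        ann = annotations.get(disease)
        if not ann:
            logger.warning("disease %s has no phenotype annotations; skipped", disease)
            continue
        tables[disease] = build_frequency_table(ann, graph, disease=disease)
        gene_diseases.setdefault(info["gene"], []).append(disease)
    regions = io.load_bed(config.artifact_bed) if config.artifact_bed else []
    return Resources(
        graph=graph,
        disease_tables=tables,
        corpus=[tables[d] for d in sorted(tables)],
        disease_genes=disease_genes,
        gene_diseases=gene_diseases,
        artifact_regions=regions,
    )


def load_case(config: RunConfig, stratum: str = "") -> Case:
    ped = io.load_ped(config.ped)
    sidecar = io.load_sidecar_annotations(config.sidecar) if config.sidecar else None
    variants = io.read_vcf(config.vcf, info_keys=config.info_keys, sidecar=sidecar)
    terms, counts = io.load_phenotypes_csv(config.phenotypes)
    return Case(
        case_id=config.case_id,
        ped=ped,
        variants=variants,
        terms=terms,
        counts=counts,
        stratum=stratum,
    )


def score_case(
    resources: Resources,
    case: Case,
    config: RunConfig,
    calibration: Optional[GaussianCalibration] = None,
) -> List:
    """Produce ranked :class:`LikelihoodBundle` rows (one per candidate gene)."""
    w = config.weights
    ranked = rank_terms(
        case.terms,
        counts=case.counts,
        graph=resources.graph,
        source=config.phenotype_source,
    )
    kept, removed = preprocess_variants(
        case.variants,
        config.genotype,
        proband=case.ped.proband,
        artifact_regions=resources.artifact_regions,
    )
    logger.info(
        "%s: %d/%d variants survive preprocessing",
        case.case_id,
        len(kept),
        len(kept) + len(removed),
    )

    by_gene: Dict = {}
    for v in kept:
        if v.gene in resources.gene_diseases:
            by_gene.setdefault(v.gene, []).append(v)

    bundles: List = []
    for gene in sorted(by_gene):
        diseases = resources.gene_diseases[gene]
        mois = {resources.disease_genes[d]["moi"] for d in diseases}
        moi = AD if AD in mois else "AR"  # dual-MOI genes are treated as dominant
        scored = []
        for v in by_gene[gene]:
            s, reason = score_pathogenicity(v, config.genotype)
            if s is None:
                logger.debug("%s: %s omitted (%s)", case.case_id, v.key, reason)
            else:
                scored.append((v, s))
        cand = aggregate_gene(scored, moi, proband=case.ped.proband)
        if cand is None:
            logger.debug("%s: gene %s omitted at aggregation", case.case_id, gene)
            continue
        prevalences = [
            resources.disease_genes[d]["prevalence"]
            or config.genotype.disease_freq_default
            for d in diseases
        ]
        cand.lr_geno = compute_geno_lr(cand, max(prevalences), config.genotype)
        classification, n_parents = classify_inheritance(cand, case.ped)
        lr_seg = compute_seg_lr(classification, n_parents)

        best: Optional[LikelihoodBundle] = None
        for d in diseases:
            table = resources.disease_tables.get(d)
            if table is None:
                continue
            pheno = compute_pheno_lr(
                ranked, table, resources.corpus, resources.graph, w.subset_max
            )
            comp = composite_score((pheno.lr_pheno, cand.lr_geno, lr_seg), w)
            bundle = LikelihoodBundle(
                case_id=case.case_id,
                disease=d,
                gene=gene,
                lr_pheno=pheno.lr_pheno,
                lr_geno=cand.lr_geno,
                lr_seg=lr_seg,
                composite=comp,
            )
            if best is None or (bundle.composite, bundle.disease) > (
                best.composite,
                best.disease,
            ):
                best = bundle
        if best is not None:
            bundles.append(best)

    for b in bundles:
        if calibration is not None:
            b.posterior = float(calibration(b.composite))
        else:
            b.posterior = odds_posterior(b.composite, w.prior)
    rank_bundles(bundles)
    bundles.sort(key=lambda b: b.rank)
    return bundles


def _bundle_rows(bundles: Sequence) -> List:
    return [
        {
            "gene": b.gene,
            "disease": b.disease,
            "lr_pheno": f"{b.lr_pheno:.6g}",
            "lr_geno": f"{b.lr_geno:.6g}",
            "lr_seg": f"{b.lr_seg:.6g}",
            "composite_log10": f"{b.composite:.6f}",
            "posterior": f"{b.posterior:.6g}",
            "rank": b.rank,
        }
        for b in bundles
    ]


def run_case(config: RunConfig, resources: Optional[Resources] = None):
    """Execute one case end to end; write the ranked TSV; return the bundles."""
    config.validate_paths(need_case=True)
    if resources is None:
        resources = load_resources(config)
    case = load_case(config)
    bundles = score_case(resources, case, config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out_path = outdir / f"{case.case_id}.scores.tsv"
    io.write_tsv(out_path, _bundle_rows(bundles), OUTPUT_COLUMNS, config.hash)
    return bundles, out_path


def run_cohort(cohort_dir, config: Optional[RunConfig] = None, outdir=None):
    """Run every case in a cohort manifest directory.

    ``cohort_dir`` must contain cohort.json as written by the fixture
    generator (or hand-assembled to the same schema).  Returns
    ``(per_case_bundles, cohort, summary_path)`` where ``cohort`` is a
    :class:`~varlr.evaluate.RankedCohort` scored by posterior.
    """
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "cohort.json") as fh:
        manifest = json.load(fh)
    base = config or RunConfig()
    base.ontology = str(cohort_dir / manifest["ontology"])
    base.gene_annotations = str(cohort_dir / manifest["gene_annotations"])
    base.disease_annotations = str(cohort_dir / manifest["disease_annotations"])
    base.disease_genes = str(cohort_dir / manifest["disease_genes"])
    resources = load_resources(base)

    outdir = Path(outdir or base.outdir)
    (outdir / "cases").mkdir(parents=True, exist_ok=True)

    truth = {}
    truth_path = cohort_dir / manifest.get("truth", "truth.csv")
    if truth_path.exists():
        truth = io.load_truth_csv(truth_path)

    per_case: Dict = {}
    cases_scores: Dict = {}
    strata: Dict = {}
    for meta in manifest["cases"]:
        cid = meta["id"]
        cfg = RunConfig.from_dict(
            {
                **base.to_dict(),
                "vcf": str(cohort_dir / meta["vcf"]),
                "ped": str(cohort_dir / meta["ped"]),
                "phenotypes": str(cohort_dir / meta["phenotypes"]),
                "case_id": cid,
                "outdir": str(outdir / "cases"),
            }
        )
        case = load_case(cfg, stratum=meta.get("stratum", ""))
        bundles = score_case(resources, case, cfg)
        io.write_tsv(
            outdir / "cases" / f"{cid}.scores.tsv",
            _bundle_rows(bundles),
            OUTPUT_COLUMNS,
            cfg.hash,
        )
        per_case[cid] = bundles
        cases_scores[cid] = [(b.gene, b.posterior) for b in bundles]
        strata[cid] = meta.get("stratum", "")

    cohort = evaluate.RankedCohort(
        cases=cases_scores,
        truth={cid: truth.get(cid, set()) for cid in cases_scores},
        strata=strata,
    )

    # cohort summary: genes most often prioritized across cases
    gene_stats: Dict = {}
    for cid, bundles in per_case.items():
        for b in bundles:
            st = gene_stats.setdefault(
                b.gene, {"gene": b.gene, "n_cases": 0, "n_top1": 0, "best_posterior": 0.0}
            )
            st["n_cases"] += 1
            st["n_top1"] += b.rank == 1
            st["best_posterior"] = max(st["best_posterior"], b.posterior)
    rows = sorted(
        gene_stats.values(),
        key=lambda r: (-r["n_top1"], -r["best_posterior"], r["gene"]),
    )
    for r in rows:
        r["best_posterior"] = f"{r['best_posterior']:.6g}"
    summary_path = outdir / "cohort_summary.tsv"
    io.write_tsv(
        summary_path,
        rows,
        ("gene", "n_cases", "n_top1", "best_posterior"),
        base.hash,
    )
    return per_case, cohort, summary_path


def case_scores_for_training(per_case: Mapping, truth: Mapping) -> List:
    """Convert scored cases + truth labels into weight-optimization rows."""
    out = []
    for cid, bundles in sorted(per_case.items()):
        if not bundles:
            continue
        positives = truth.get(cid, set())
        log_lrs = np.array(
            [
                [np.log10(b.lr_pheno), np.log10(b.lr_geno), np.log10(b.lr_seg)]
                for b in bundles
            ]
        )
        labels = np.array([b.gene in positives for b in bundles])
        out.append(CaseScores(case_id=cid, log_lrs=log_lrs, labels=labels))
    return out
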