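"""Synthetic self-contained inputs: toy ontology, disease corpus, labeled trio cohort.

Everything is a pure function of the spec seed, so fixture files are
byte-identical across runs.  Diagnostic cases carry a planted variant in the
disease gene with MOI-consistent trio genotypes and phenotype terms sampled
from the disease's annotations by frequency; noise terms and noise variants
emulate computational-phenotype noise and benign background variation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genotype import AD, AR, Variant
from .io import write_vcf
from .ontology import OntologyGraph, closure_of_set

__all__ = ["FixtureSpec", "Disease", "make_ontology", "make_diseases", "make_cohort", "generate"]

_REF_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_terms: int = 250
    dag_depth: int = 6
    n_genes: int = 80
    n_diseases: int = 20
    terms_per_disease: int = 5
    n_cases: int = 100
    diagnostic_fraction: float = 0.3
    noise_terms_per_case: int = 6
    noise_variants_per_case: int = 15
    trio_fraction: float = 0.6
    duo_fraction: float = 0.2
    ad_fraction: float = 0.6  # share of AD diseases in the corpus

    def __post_init__(self):
        for name in ("n_terms", "dag_depth", "n_genes", "n_diseases",
                     "terms_per_disease", "n_cases"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("diagnostic_fraction", "trio_fraction", "duo_fraction",
                     "ad_fraction"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.trio_fraction + self.duo_fraction > 1.0:
            raise ValueError("trio_fraction + duo_fraction must be <= 1")
        if self.n_terms <= self.dag_depth:
            raise ValueError("need more terms than DAG layers")
        if self.n_diseases > self.n_genes:
            raise ValueError("need at least one gene per disease")


@dataclass(frozen=True)
class Disease:
    disease_id: str
    gene: str
    moi: str
    annotations: Dict  # term -> frequency in (0, 1]
    prevalence: float = 1e-4


def make_ontology(spec: FixtureSpec) -> Tuple:
    """Random layered single-root DAG with leaf gene annotations unioned upward.

    Returns ``(graph, annotation_pairs)``; the pairs are what the gene
    annotation TSV would contain.
    """
    rng = np.random.default_rng(spec.seed)
    root = "T:0000"
    n_rest = spec.n_terms - 1
    weights = np.arange(1, spec.dag_depth + 1, dtype=float)
    sizes = np.maximum(1, np.floor(weights / weights.sum() * n_rest)).astype(int)
    while sizes.sum() < n_rest:
        sizes[-1] += 1
    while sizes.sum() > n_rest:
        sizes[np.argmax(sizes)] -= 1

    layers: List[List[str]] = [[root]]
    idx = 1
    parents: Dict = {}
    for depth, size in enumerate(sizes, start=1):
        layer = []
        for _ in range(size):
            term = f"T:{idx:04d}"
            idx += 1
            prev = layers[depth - 1]
            chosen = {prev[rng.integers(len(prev))]}
            if depth > 1 and rng.random() < 0.3:
                pool = [t for lay in layers[:depth] for t in lay if t not in chosen]
                if pool:
                    chosen.add(pool[rng.integers(len(pool))])
            parents[term] = chosen
            layer.append(term)
        layers.append(layer)

    used_as_parent = {p for ps in parents.values() for p in ps}
    leaves = sorted(t for lay in layers[1:] for t in lay if t not in used_as_parent)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    pairs: List = []
    assigned = set()
    for leaf in leaves:
        k = int(rng.integers(1, 4))
        for g in rng.choice(genes, size=min(k, len(genes)), replace=False):
            pairs.append((leaf, str(g)))
            assigned.add(str(g))
    for g in genes:  # every gene must appear somewhere
        if g not in assigned:
            pairs.append((str(rng.choice(leaves)), g))
    pairs = sorted(set(pairs))
    graph = OntologyGraph.build(parents, root, pairs)
    return graph, pairs


def make_diseases(spec: FixtureSpec, graph: OntologyGraph) -> List:
    """Disease corpus: one gene per disease, AD/AR mix, frequency annotations."""
    rng = np.random.default_rng(spec.seed + 1)
    universe = sorted(graph.gene_sets[graph.root])
    if spec.n_diseases > len(universe):
        raise ValueError("not enough annotated genes for the requested diseases")
    disease_genes = rng.choice(universe, size=spec.n_diseases, replace=False)
    # prefer specific (small-gene-set) terms for annotations
    candidates = sorted(
        (t for t in graph.terms if t != graph.root and graph.gene_sets[t]),
        key=lambda t: (len(graph.gene_sets[t]), t),
    )
    specific = candidates[: max(len(candidates) * 3 // 4, spec.terms_per_disease)]
    n_ad = int(round(spec.ad_fraction * spec.n_diseases))
    # disease annotation sets are disjoint when the term pool allows: each
    # disease takes its own chunk of a shuffled pool (the large-IC-gap regime)
    shuffled = list(rng.permutation(specific))
    diseases = []
    for i in range(spec.n_diseases):
        k = spec.terms_per_disease
        if (i + 1) * k <= len(shuffled):
            terms = shuffled[i * k:(i + 1) * k]
        else:
            terms = rng.choice(specific, size=min(k, len(specific)), replace=False)
        annotations = {
            str(t): float(np.round(rng.uniform(0.6, 1.0), 2)) for t in sorted(terms)
        }
        diseases.append(
            Disease(
                disease_id=f"D:{i:03d}",
                gene=str(disease_genes[i]),
                moi=AD if i < n_ad else AR,
                annotations=annotations,
                prevalence=1e-4,
            )
        )
    return diseases


def _sample_phenotypes(rng, disease: Optional[Disease], graph: OntologyGraph,
                       spec: FixtureSpec, corpus_terms=frozenset()) -> List:
    """Disease terms sampled by frequency plus uniform noise terms.

    Noise is drawn uniformly from non-disease terms — outside every corpus
    disease's closed table — the simplest adversarial model of NLP-extraction
    noise.  Pass a different ``corpus_terms`` set to tighten or loosen it.
    """
    terms: List = []
    excluded: set = set(corpus_terms)
    if disease is not None:
        for t, f in disease.annotations.items():
            if rng.random() < f:
                terms.append(t)
        if not terms:  # at least the most frequent annotated term
            terms.append(max(disease.annotations, key=lambda t: (disease.annotations[t], t)))
        excluded |= set(closure_of_set(disease.annotations, graph))
    pool = sorted(t for t in graph.terms if t != graph.root and t not in excluded)
    n_noise = spec.noise_terms_per_case + (2 if disease is None else 0)
    noise = rng.choice(pool, size=min(n_noise, len(pool)), replace=False)
    terms.extend(str(t) for t in noise if t not in terms)
    return terms


def _genotype_block(samples: Sequence, proband_gt: str, parent_gts: Dict) -> Dict:
    gts = {}
    for s in samples:
        if s.endswith("_P"):
            gts[s] = proband_gt
        else:
            gts[s] = parent_gts.get(s, "0/0")
    return gts


def _planted_variants(rng, disease: Disease, samples: Sequence, pos0: int) -> List:
    """MOI-consistent disease variants: de novo het (AD), trans pair or
    hom-with-carrier-parents (AR)."""
    mother = next((s for s in samples if s.endswith("_M")), None)
    father = next((s for s in samples if s.endswith("_F")), None)
    out = []

    def mk(pos, proband_gt, parent_gts, effect="nonsynonymous_snv"):
        score = None if effect == "frameshift" else float(np.round(rng.uniform(0.85, 0.99), 3))
        ref = _REF_BASES[rng.integers(4)]
        alt = _REF_BASES[(rng.integers(1, 4) + _REF_BASES.index(ref)) % 4]
        return Variant(
            chrom="1", pos=pos, ref=ref, alt=alt, qual=100.0, depth=30,
            genotypes=_genotype_block(samples, proband_gt, parent_gts),
            func_effect=effect, gene=disease.gene, gnomad_freq=None,
            predictor_score=score,
        )

    if disease.moi == AD:
        effect = "frameshift" if rng.random() < 0.2 else "nonsynonymous_snv"
        out.append(mk(pos0, "0/1", {}, effect))
    else:
        if rng.random() < 0.3:  # homozygous, both parents carriers
            carriers = {s: "0/1" for s in (mother, father) if s}
            out.append(mk(pos0, "1/1", carriers))
        else:  # compound het in trans
            p1 = {mother: "0/1"} if mother else {}
            p2 = {father: "0/1"} if father else {}
            out.append(mk(pos0, "0/1", p1))
            out.append(mk(pos0 + 500, "0/1", p2))
    return out


def _noise_variants(rng, spec: FixtureSpec, samples: Sequence, gene_pool: Sequence,
                    pos0: int) -> List:
    """Background variants: some tripping each filter, some surviving as
    benign-leaning candidates inherited from an unaffected parent."""
    out = []
    parents = [s for s in samples if not s.endswith("_P")]
    for j in range(spec.noise_variants_per_case):
        pos = pos0 + j * 1000
        gene = str(gene_pool[rng.integers(len(gene_pool))])
        ref = _REF_BASES[rng.integers(4)]
        alt = _REF_BASES[(rng.integers(1, 4) + _REF_BASES.index(ref)) % 4]
        u = rng.random()
        effect, gnomad, score, qual = "nonsynonymous_snv", None, None, 80.0
        if u < 0.15:
            gnomad = float(np.round(rng.uniform(0.02, 0.2), 3))  # common -> filtered
            score = 0.8
        elif u < 0.30:
            effect = "synonymous"
        elif u < 0.40:
            effect = "intronic"
        elif u < 0.50:
            effect = "nonsynonymous_snv"
            score = float(np.round(rng.uniform(0.05, 0.45), 3))  # below threshold
            gnomad = float(np.round(rng.uniform(1e-4, 5e-3), 5))
        else:  # surviving negative candidate
            score = float(np.round(rng.uniform(0.55, 0.9), 3))
            gnomad = float(np.round(rng.uniform(1e-3, 9e-3), 5))
        parent_gts = {}
        if parents:
            carrier = parents[rng.integers(len(parents))]
            parent_gts[carrier] = "0/1"
        out.append(
            Variant(
                chrom="1", pos=pos, ref=ref, alt=alt, qual=qual,
                depth=int(rng.integers(15, 40)),
                genotypes=_genotype_block(samples, "0/1", parent_gts),
                func_effect=effect, gene=gene, gnomad_freq=gnomad,
                predictor_score=score,
            )
        )
    return out


def _write_obograph(path, graph: OntologyGraph) -> None:
    nodes = [{"id": t, "lbl": t} for t in sorted(graph.terms)]
    edges = [
        {"sub": c, "pred": "is_a", "obj": p}
        for c in sorted(graph.terms)
        for p in sorted(graph.parents.get(c, ()))
    ]
    with open(path, "w") as fh:
        json.dump({"graphs": [{"nodes": nodes, "edges": edges}]}, fh, indent=1)


def make_cohort(spec: FixtureSpec, graph: OntologyGraph, diseases: Sequence,
                outdir) -> Dict:
    """Write the full synthetic cohort under ``outdir``; return the manifest.

    Layout: ontology.json, genes.tsv, disease_pheno.tsv, disease_genes.tsv,
    truth.csv, cohort.json and a cases/ directory with per-case VCF, PED and
    phenotype CSV.  The manifest (cohort.json) lists every case with its
    stratum (trio/duo/singleton) and file paths relative to ``outdir``.
    """
    rng = np.random.default_rng(spec.seed + 2)
    outdir = Path(outdir)
    (outdir / "cases").mkdir(parents=True, exist_ok=True)

    _write_obograph(outdir / "ontology.json", graph)
    # minimal annotation pairs: a gene is written at every term whose children
    # do not already carry it, so loading the TSV reproduces gene_sets exactly
    children: Dict = {}
    for c, ps in graph.parents.items():
        for p in ps:
            children.setdefault(p, set()).add(c)
    minimal = []
    for t in sorted(graph.terms):
        below = set()
        for c in children.get(t, ()):
            below |= graph.gene_sets[c]
        for g in sorted(graph.gene_sets[t] - below):
            minimal.append((t, g))
    with open(outdir / "genes.tsv", "w") as fh:
        for t, g in minimal:
            fh.write(f"{t}\t{g}\n")
    with open(outdir / "disease_pheno.tsv", "w") as fh:
        for d in diseases:
            for t, f in sorted(d.annotations.items()):
                fh.write(f"{d.disease_id}\t{t}\t{f}\n")
    with open(outdir / "disease_genes.tsv", "w") as fh:
        for d in diseases:
            fh.write(f"{d.disease_id}\t{d.gene}\t{d.moi}\t{d.prevalence:g}\n")

    n_diag = int(round(spec.n_cases * spec.diagnostic_fraction))
    n_trio = int(round(spec.n_cases * spec.trio_fraction))
    n_duo = int(round(spec.n_cases * spec.duo_fraction))
    strata = ["trio"] * n_trio + ["duo"] * n_duo
    strata += ["singleton"] * (spec.n_cases - len(strata))
    strata = [str(s) for s in rng.permutation(strata)]
    diag_flags = [i < n_diag for i in range(spec.n_cases)]
    diag_flags = list(rng.permutation(diag_flags))

    gene_pool = sorted({d.gene for d in diseases})
    corpus_terms = frozenset(
        closure_of_set((t for d in diseases for t in d.annotations), graph)
    )
    truth_rows, cases_meta = [], []
    di = 0
    for i in range(spec.n_cases):
        cid = f"CASE{i:03d}"
        stratum = strata[i]
        samples = [f"{cid}_P"]
        mother = father = None
        if stratum in ("trio", "duo"):
            mother = f"{cid}_M"
            samples.append(mother)
        if stratum == "trio":
            father = f"{cid}_F"
            samples.append(father)

        disease = None
        if diag_flags[i]:
            disease = diseases[di % len(diseases)]
            di += 1

        terms = _sample_phenotypes(rng, disease, graph, spec, corpus_terms)
        variants: List = []
        if disease is not None:
            variants += _planted_variants(rng, disease, samples, pos0=5_000_000)
            truth_rows.append((cid, disease.gene))
        pool = [g for g in gene_pool if disease is None or g != disease.gene]
        variants += _noise_variants(rng, spec, samples, pool, pos0=10_000_000)

        vcf_path = outdir / "cases" / f"{cid}.vcf"
        write_vcf(vcf_path, variants, samples)
        ped_path = outdir / "cases" / f"{cid}.ped"
        with open(ped_path, "w") as fh:
            sex = "1" if rng.random() < 0.5 else "2"
            fh.write(f"{cid}\t{cid}_P\t{father or 0}\t{mother or 0}\t{sex}\t2\n")
            if mother:
                fh.write(f"{cid}\t{mother}\t0\t0\t2\t1\n")
            if father:
                fh.write(f"{cid}\t{father}\t0\t0\t1\t1\n")
        pheno_path = outdir / "cases" / f"{cid}.phenotypes.csv"
        with open(pheno_path, "w") as fh:
            fh.write("term_id\n")
            for t in terms:
                fh.write(f"{t}\n")
        cases_meta.append(
            {
                "id": cid,
                "stratum": stratum,
                "vcf": f"cases/{cid}.vcf",
                "ped": f"cases/{cid}.ped",
                "phenotypes": f"cases/{cid}.phenotypes.csv",
            }
        )

    with open(outdir / "truth.csv", "w") as fh:
        fh.write("case_id,diagnostic_gene\n")
        for cid, gene in truth_rows:
            fh.write(f"{cid},{gene}\n")

    manifest = {
        "spec": asdict(spec),
        "ontology": "ontology.json",
        "gene_annotations": "genes.tsv",
        "disease_annotations": "disease_pheno.tsv",
        "disease_genes": "disease_genes.tsv",
        "truth": "truth.csv",
        "cases": cases_meta,
    }
    with open(outdir / "cohort.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def generate(spec: FixtureSpec, outdir) -> Dict:
    """One-call generation: ontology + diseases + cohort files under outdir."""
    graph, _ = make_ontology(spec)
    diseases = make_diseases(spec, graph)
    return make_cohort(spec, graph, diseases, outdir)
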