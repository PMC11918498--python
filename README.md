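# varlr

Likelihood-ratio prioritization of candidate diagnostic genes in rare-disease
exome/genome cases.  Three independent evidence channels are scored per
(case, disease, gene) triple and combined into a calibrated posterior
diagnostic probability:

- **Phenotype** — patient ontology terms are ranked (information content for
  clinician-curated sets, occurrence counts for NLP-derived sets) and scored
  against per-disease frequency tables propagated up the "is a" DAG; the
  joint LR is maximized over incremental term subsets, which makes the score
  robust to large, noisy computational phenotype sets.
- **Genotype** — variants are filtered (artifact regions, quality/depth,
  proband allele, gnomAD frequency, nonexonic, synonymous; canonical-splice
  and ClinVar rescues), scored with pathogenicity heuristics over pluggable
  predictor annotations, and aggregated per gene under the disease's mode of
  inheritance (dominant: best variant; recessive: mean of the top two
  alleles).
- **Segregation** — observed trio/duo inheritance is compared with the
  expected mode of inheritance (de novo, transmission from an affected
  parent, compound het in trans / in cis, homozygous with carrier parents);
  the LR takes values 10 / 1 / 0.1, square-rooted when only one parent is
  available.

The composite score is `log10(LR_pheno) + c1*log10(LR_geno) +
c2*log10(LR_seg)` with learned exponents (defaults `c1=2.29`, `c2=3.69`).
Exponents can be re-learned with a greedy PR-AUC hill-climb over
cross-validation folds, and posteriors can be recalibrated against local
diagnostic / nondiagnostic score distributions.

## Inputs

| Input | Format |
| --- | --- |
| Ontology | OBO-graph JSON (`is_a` edges) or OBO flat file |
| Gene annotations | TSV `term_id<TAB>gene_id` |
| Disease phenotypes | TSV `disease_id<TAB>term_id<TAB>frequency` (decimal or `n/m`) |
| Disease genes | TSV `disease_id<TAB>gene_id<TAB>moi[<TAB>prevalence]` |
| Case variants | VCF 4.2 (annotations in INFO keys or a sidecar TSV) |
| Pedigree | 6-column PED |
| Phenotypes | CSV, one term ID per row, optional `count` column |
| Artifact regions | BED (0-based half-open) |

## CLI

```bash
# generate a fully synthetic labeled cohort (no downloads needed)
varlr simulate --out demo_cohort --seed 1 --cases 50

# score one case
varlr run --ontology demo_cohort/ontology.json \
          --gene-annotations demo_cohort/genes.tsv \
          --disease-annotations demo_cohort/disease_pheno.tsv \
          --disease-genes demo_cohort/disease_genes.tsv \
          --vcf demo_cohort/cases/CASE000.vcf \
          --ped demo_cohort/cases/CASE000.ped \
          --phenotypes demo_cohort/cases/CASE000.phenotypes.csv \
          --case-id CASE000 --out scored

# score a whole cohort, then evaluate against truth labels
varlr cohort --dir demo_cohort --out scored
varlr evaluate --scores-dir scored/cases --truth demo_cohort/truth.csv \
               --manifest demo_cohort/cohort.json --out metrics.json

# learn composite-score exponents on a labeled cohort
varlr optimize --dir demo_cohort --out weights.yaml
```

Per-case output is a TSV (`gene, disease, lr_pheno, lr_geno, lr_seg,
composite_log10, posterior, rank`) sorted by rank; cohort runs add a gene
summary TSV and a metrics JSON (PR AUC, mean diagnostic rank, top-N,
diagnostic recall, stratified by trio/duo/singleton).

## Library use

```python
from varlr import OntologyGraph, build_frequency_table, ancestral_closure
from varlr.pipeline import run_cohort
from varlr.fixtures import FixtureSpec, generate

generate(FixtureSpec(seed=1, n_cases=20), "cohort")
per_case, cohort, summary = run_cohort("cohort", outdir="scored")
```
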