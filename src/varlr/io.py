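"""Readers and writers for the interchange formats.

Coordinate conventions: VCF positions are 1-based; BED intervals are 0-based
half-open.  Conversions happen here, at the reader boundary, and nowhere else.
All TSV writers stamp a comment header with the tool version and a config
hash so outputs are traceable and byte-reproducible.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from cyvcf2 import VCF

from . import __version__
from .errors import OntologyError, PedigreeError
from .genotype import Variant
from .ontology import OntologyGraph
from .segregation import Pedigree

logger = logging.getLogger(__name__)

# default INFO keys carrying the variant annotations
DEFAULT_INFO_KEYS = {
    "gene": "GENE",
    "effect": "EFFECT",
    "gnomad": "GNOMAD",
    "cohort": "COHORT_AF",
    "clinvar": "CLNSIG",
    "score": "PSCORE",
}


# ---------------------------------------------------------------------------
# ontology


def load_obograph_json(path) -> Tuple:
    """Read an OBO-graph JSON file; returns (parents, root).

    Only ``is_a`` edges are used; every other predicate is ignored.  Exactly
    one root (a node that is never a subject of an is_a edge... i.e. has no
    parents) must exist.
    """
    with open(path) as fh:
        doc = json.load(fh)
    graphs = doc.get("graphs") or [doc]
    nodes, parents = set(), {}
    for g in graphs:
        for node in g.get("nodes", []):
            nodes.add(node["id"])
        for edge in g.get("edges", []):
            if edge.get("pred") != "is_a":
                continue
            parents.setdefault(edge["sub"], set()).add(edge["obj"])
            nodes.update((edge["sub"], edge["obj"]))
    roots = [n for n in nodes if not parents.get(n)]
    if len(roots) != 1:
        raise OntologyError(f"expected exactly one root term, found {sorted(roots)}")
    return parents, roots[0]


_OBO_ID = re.compile(r"^id:\s*(\S+)")
_OBO_ISA = re.compile(r"^is_a:\s*(\S+)")


def load_obo(path) -> Tuple:
    """Minimal OBO flat-file reader: [Term] stanzas, id: and is_a: tags only."""
    parents: Dict = {}
    nodes = set()
    current: Optional[str] = None
    in_term = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                in_term = line == "[Term]"
                current = None
                continue
            if not in_term:
                continue
            m = _OBO_ID.match(line)
            if m:
                current = m.group(1)
                nodes.add(current)
                continue
            m = _OBO_ISA.match(line)
            if m and current:
                parents.setdefault(current, set()).add(m.group(1))
                nodes.add(m.group(1))
    roots = [n for n in nodes if not parents.get(n)]
    if len(roots) != 1:
        raise OntologyError(f"expected exactly one root term, found {sorted(roots)}")
    return parents, roots[0]


def load_gene_annotations(path) -> List:
    """TSV ``term_id<TAB>gene_id`` -> list of (term, gene) pairs."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise OntologyError(f"malformed gene annotation line: {line!r}")
            pairs.append((fields[0], fields[1]))
    return pairs


def load_ontology(ontology_path, gene_annotation_path) -> OntologyGraph:
    """Load the DAG (OBO-graph JSON by extension, else OBO) plus gene sets."""
    path = Path(ontology_path)
    if path.suffix == ".json":
        parents, root = load_obograph_json(path)
    else:
        parents, root = load_obo(path)
    pairs = load_gene_annotations(gene_annotation_path)
    return OntologyGraph.build(parents, root, pairs)


def _parse_frequency(raw: str) -> float:
    """Decimal or 'n/m' fractional frequency annotation."""
    raw = raw.strip()
    if "/" in raw:
        n, m = raw.split("/", 1)
        m = float(m)
        if m <= 0:
            raise OntologyError(f"bad fractional frequency {raw!r}")
        return float(n) / m
    return float(raw)


def load_disease_annotations(path) -> Dict:
    """HPOA-style TSV ``disease_id<TAB>term_id<TAB>frequency``.

    Returns map disease -> {term: frequency}; frequency accepts decimals or
    'n/m' fractions.
    """
    out: Dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise OntologyError(f"malformed disease annotation line: {line!r}")
            disease, term, freq = fields[0], fields[1], _parse_frequency(fields[2])
            out.setdefault(disease, {})[term] = freq
    return out


def load_disease_genes(path) -> Dict:
    """TSV ``disease_id<TAB>gene_id<TAB>moi[<TAB>prevalence]``.

    Returns map disease -> dict(gene, moi, prevalence).  Prevalence defaults
    to None (callers substitute the configured default).
    """
    out: Dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise OntologyError(f"malformed disease-gene line: {line!r}")
            prevalence = float(fields[3]) if len(fields) > 3 and fields[3] else None
            out[fields[0]] = {
                "gene": fields[1],
                "moi": fields[2],
                "prevalence": prevalence,
            }
    return out


# ---------------------------------------------------------------------------
# case inputs


def load_ped(path) -> Pedigree:
    """Six-column PED; the proband is the affected individual with parents
    listed (falling back to the single affected individual)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"PED line has {len(fields)} columns: {line!r}")
            rows.append(fields)
    if not rows:
        raise PedigreeError("empty PED file")
    affected = {r[1]: r[5] == "2" for r in rows}
    candidates = [r for r in rows if r[5] == "2" and (r[2] != "0" or r[3] != "0")]
    if not candidates:
        candidates = [r for r in rows if r[5] == "2"]
    if not candidates:
        raise PedigreeError("no affected individual in PED; cannot identify proband")
    row = candidates[0]
    father = row[2] if row[2] != "0" else None
    mother = row[3] if row[3] != "0" else None
    return Pedigree(proband=row[1], father=father, mother=mother, affected=affected)


def load_phenotypes_csv(path) -> Tuple:
    """CSV with one term per row, optional second ``count`` column.

    Returns ``(terms, counts)`` where counts is None when no count column is
    present.
    """
    terms: List = []
    counts: Dict = {}
    have_counts = False
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            cell = row[0].strip()
            if cell.lower() in ("term_id", "term", "hpo_id"):
                continue
            terms.append(cell)
            if len(row) > 1 and row[1].strip():
                counts[cell] = int(row[1])
                have_counts = True
    return terms, (counts if have_counts else None)


def load_bed(path) -> List:
    """BED3 -> list of (chrom, start, end), 0-based half-open."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            regions.append((fields[0], int(fields[1]), int(fields[2])))
    return regions


def load_sidecar_annotations(path) -> Dict:
    """Sidecar TSV keyed on chrom:pos:ref:alt with annotation columns.

    Header: ``key  gene  effect  gnomad  cohort  clinvar  score`` (missing
    values empty).
    """
    out: Dict = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["key"]] = {
                "gene": row.get("gene") or "",
                "effect": row.get("effect") or "other_exonic",
                "gnomad": float(row["gnomad"]) if row.get("gnomad") else None,
                "cohort": float(row["cohort"]) if row.get("cohort") else None,
                "clinvar": (row.get("clinvar") or "").upper().startswith("P"),
                "score": float(row["score"]) if row.get("score") else None,
            }
    return out


def _gt_string(indices) -> str:
    a = [str(i) if i >= 0 else "." for i in indices[:2]]
    if len(a) == 1:
        a = a * 2
    return "/".join(a)


def read_vcf(
    path,
    info_keys: Optional[Mapping] = None,
    sidecar: Optional[Mapping] = None,
) -> List:
    """Parse a VCF into :class:`~varlr.genotype.Variant` records.

    Annotations come from INFO fields (key names configurable via
    ``info_keys``) or, when provided, a sidecar mapping keyed on
    chrom:pos:ref:alt which takes precedence.  Multi-allelic records are
    split per ALT.  Malformed records are skipped with a warning.
    """
    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: List = []
    for rec in vcf:
        try:
            gts = {s: _gt_string(rec.genotypes[i]) for i, s in enumerate(samples)}
            depths = rec.format("DP")
            depth = int(depths[0][0]) if depths is not None else 0
            for alt in rec.ALT or []:
                key = f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
                if sidecar is not None and key in sidecar:
                    ann = sidecar[key]
                    gene, effect = ann["gene"], ann["effect"]
                    gnomad, cohort = ann["gnomad"], ann["cohort"]
                    clinvar, score = ann["clinvar"], ann["score"]
                else:
                    gene = rec.INFO.get(keys["gene"]) or ""
                    effect = rec.INFO.get(keys["effect"]) or "other_exonic"
                    gnomad = rec.INFO.get(keys["gnomad"])
                    cohort = rec.INFO.get(keys["cohort"])
                    raw_clnsig = rec.INFO.get(keys["clinvar"]) or ""
                    clinvar = str(raw_clnsig).upper().startswith("P")
                    score = rec.INFO.get(keys["score"])
                variants.append(
                    Variant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                        depth=depth,
                        genotypes=gts,
                        func_effect=str(effect),
                        gene=str(gene),
                        gnomad_freq=float(gnomad) if gnomad is not None else None,
                        cohort_freq=float(cohort) if cohort is not None else None,
                        clinvar_pathogenic=bool(clinvar),
                        predictor_score=float(score) if score is not None else None,
                    )
                )
        except (ValueError, KeyError, IndexError) as exc:
            logger.warning("skipping malformed record at %s:%s (%s)", rec.CHROM, rec.POS, exc)
    return variants


# ---------------------------------------------------------------------------
# VCF writer (used by the fixture generator)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Functional effect class">
##INFO=<ID=GNOMAD,Number=1,Type=Float,Description="Max gnomAD subpopulation AF">
##INFO=<ID=COHORT_AF,Number=1,Type=Float,Description="Intracohort AF">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar clinical significance">
##INFO=<ID=PSCORE,Number=1,Type=Float,Description="Pathogenicity predictor score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_vcf(path, variants: Sequence, samples: Sequence) -> None:
    """Write plain-text VCF 4.2 with the annotation INFO keys this package reads."""
    chroms = sorted({v.chrom for v in variants}, key=str)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            info = [f"GENE={v.gene}", f"EFFECT={v.func_effect}"]
            if v.gnomad_freq is not None:
                info.append(f"GNOMAD={v.gnomad_freq:g}")
            if v.cohort_freq is not None:
                info.append(f"COHORT_AF={v.cohort_freq:g}")
            if v.clinvar_pathogenic:
                info.append("CLNSIG=Pathogenic")
            if v.predictor_score is not None:
                info.append(f"PSCORE={v.predictor_score:g}")
            cells = [
                v.chrom,
                str(v.pos),
                ".",
                v.ref,
                v.alt,
                f"{v.qual:g}",
                "PASS",
                ";".join(info),
                "GT:DP",
            ]
            for s in samples:
                gt = v.genotypes.get(s, "./.")
                cells.append(f"{gt}:{v.depth}")
            fh.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# output writers


def config_hash(config_dict: Mapping) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_tsv(path, rows: Sequence, columns: Sequence, cfg_hash: str = "") -> None:
    """Write a TSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# varlr={__version__} config={cfg_hash}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def read_tsv(path) -> List:
    """Read a TSV written by :func:`write_tsv` into a list of dicts."""
    with open(path) as fh:
        lines = [l for l in fh if not l.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return list(reader)


def load_truth_csv(path) -> Dict:
    """CSV ``case_id,diagnostic_gene`` -> map case -> set of genes."""
    out: Dict = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() == "case_id":
                continue
            out.setdefault(row[0].strip(), set()).add(row[1].strip())
    return out
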