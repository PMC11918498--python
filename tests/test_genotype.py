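import pytest

from varlr.errors import MissingSampleError
from varlr.genotype import (
    AD,
    AR,
    GenotypeConfig,
    Variant,
    aggregate_gene,
    compute_geno_lr,
    n_alt_alleles,
    preprocess_variants,
    score_pathogenicity,
)

CFG = GenotypeConfig()
P = "kid"


def mk(pos=100, ref="A", alt="G", qual=99.0, depth=30, gt="0/1", effect="nonsynonymous_snv",
       gene="GENE1", gnomad=None, cohort=None, clinvar=False, score=0.9, **extra_gts):
    gts = {P: gt}
    gts.update(extra_gts)
    return Variant(
        chrom="1", pos=pos, ref=ref, alt=alt, qual=qual, depth=depth,
        genotypes=gts, func_effect=effect, gene=gene, gnomad_freq=gnomad,
        cohort_freq=cohort, clinvar_pathogenic=clinvar, predictor_score=score,
    )


class TestPreprocess:
    def test_empty_input(self):
        kept, removed = preprocess_variants([], CFG, proband=P)
        assert kept == [] and removed == []

    def test_each_filter_trips_once(self):
        variants = [
            mk(pos=50),                                  # artifact region
            mk(pos=200, qual=5.0),                       # low quality
            mk(pos=300, depth=2),                        # low depth
            mk(pos=400, gt="0/0"),                       # proband lacks alt
            mk(pos=450, gt="./."),                       # proband uncalled
            mk(pos=500, gnomad=0.05),                    # common in gnomAD
            mk(pos=600, effect="intronic"),              # nonexonic
            mk(pos=650, effect="nonexonic"),             # nonexonic
            mk(pos=700, effect="synonymous"),            # synonymous
            mk(pos=800, effect="splice_canonical"),      # rescued from exonic filter
            mk(pos=900, effect="synonymous", clinvar=True),  # ClinVar rescue
            mk(pos=1000),                                # clean survivor
        ]
        regions = [("1", 40, 60)]  # 0-based half-open, covers pos 50
        kept, removed = preprocess_variants(variants, CFG, proband=P,
                                            artifact_regions=regions)
        assert len(kept) + len(removed) == 12
        assert len(kept) == 3  # independent hand count of the rule audit
        reasons = [r for _, r in removed]
        assert reasons == [
            "artifact_region", "low_quality", "low_depth", "no_proband_alt",
            "no_proband_alt", "common_gnomad", "nonexonic", "nonexonic",
            "synonymous",
        ]
        assert {v.pos for v in kept} == {800, 900, 1000}

    def test_clinvar_rescues_synonymous_but_not_plain(self):
        rescued, _ = preprocess_variants(
            [mk(effect="synonymous", clinvar=True)], CFG, proband=P)
        dropped, removed = preprocess_variants(
            [mk(effect="synonymous", clinvar=False)], CFG, proband=P)
        assert len(rescued) == 1
        assert dropped == [] and removed[0][1] == "synonymous"

    def test_clinvar_does_not_rescue_proband_alt_check(self):
        kept, removed = preprocess_variants(
            [mk(gt="0/0", clinvar=True)], CFG, proband=P)
        assert kept == [] and removed[0][1] == "no_proband_alt"

    def test_cohort_mode_extra_filters(self):
        cfg = GenotypeConfig(cohort_mode=True)
        kept, removed = preprocess_variants(
            [mk(qual=40.0), mk(pos=110, cohort=0.05), mk(pos=120, cohort=0.01)],
            cfg, proband=P)
        assert [r for _, r in removed] == ["cohort_quality", "cohort_frequency"]
        assert len(kept) == 1

    def test_idempotence(self):
        variants = [mk(pos=100), mk(pos=200, ref="CAG", alt="CG"),
                    mk(pos=300, effect="splice_canonical")]
        kept, _ = preprocess_variants(variants, CFG, proband=P)
        again, removed = preprocess_variants(kept, CFG, proband=P)
        assert removed == []
        assert [(v.pos, v.ref, v.alt) for v in again] == \
            [(v.pos, v.ref, v.alt) for v in kept]

    def test_normalization_trims_shared_bases(self):
        kept, _ = preprocess_variants([mk(pos=200, ref="CAG", alt="CG")], CFG, proband=P)
        v = kept[0]
        # shared suffix G trimmed
        assert (v.ref, v.alt) == ("CA", "C")
        kept, _ = preprocess_variants([mk(pos=300, ref="TTA", alt="TA")], CFG, proband=P)
        v = kept[0]
        assert (v.ref, v.alt, v.pos) == ("TT", "T", 300)

    def test_missing_proband_raises(self):
        with pytest.raises(MissingSampleError, match="kid"):
            preprocess_variants([Variant(chrom="1", pos=1, ref="A", alt="T",
                                         qual=99, depth=30, genotypes={"other": "0/1"})],
                                CFG, proband=P)

    def test_count_invariant_random_mix(self):
        variants = [mk(pos=100 + i,
                       qual=5.0 if i % 5 == 0 else 99.0,
                       gnomad=0.2 if i % 3 == 0 else None)
                    for i in range(30)]
        kept, removed = preprocess_variants(variants, CFG, proband=P)
        assert len(kept) + len(removed) == 30


class TestScorePathogenicity:
    @pytest.mark.parametrize("effect", ["frameshift", "startloss", "stoploss"])
    def test_lof_classes_scored_one(self, effect):
        s, reason = score_pathogenicity(mk(effect=effect, score=None), CFG)
        assert s == 1.0 and reason is None

    def test_nonsynonymous_uses_predictor(self):
        s, _ = score_pathogenicity(mk(score=0.83), CFG)
        assert s == 0.83

    def test_nonsynonymous_below_half_omitted(self):
        s, reason = score_pathogenicity(mk(score=0.49), CFG)
        assert s is None and reason == "below_threshold"

    def test_nonsynonymous_missing_score_omitted(self):
        s, reason = score_pathogenicity(mk(score=None), CFG)
        assert s is None and reason == "missing_predictor_score"

    def test_inframe_indel_default_half_when_scoring_disabled(self):
        v = mk(ref="A", alt="ATTT", effect="nonframeshift_indel", score=None)
        s, reason = score_pathogenicity(v, CFG)
        assert s == 0.5 and reason is None

    def test_inframe_indel_uses_predictor_when_enabled(self):
        cfg = GenotypeConfig(indel_scoring=True)
        v = mk(ref="A", alt="ATTT", effect="nonframeshift_indel", score=0.77)
        s, _ = score_pathogenicity(v, cfg)
        assert s == 0.77

    def test_splice_canonical_uses_predictor(self):
        s, _ = score_pathogenicity(mk(effect="splice_canonical", score=0.66), CFG)
        assert s == 0.66

    @pytest.mark.parametrize("effect", ["intronic", "other_exonic", "nonexonic"])
    def test_unscored_classes_omitted(self, effect):
        s, reason = score_pathogenicity(mk(effect=effect), CFG)
        assert s is None and reason == "unscored_class"

    def test_clinvar_floors_and_never_omits(self):
        s, reason = score_pathogenicity(mk(score=0.1, clinvar=True), CFG)
        assert s == CFG.clinvar_floor and reason is None
        s, _ = score_pathogenicity(mk(score=0.99, clinvar=True), CFG)
        assert s == 0.99  # floor, not cap
        s, reason = score_pathogenicity(mk(effect="intronic", clinvar=True), CFG)
        assert s == CFG.clinvar_floor and reason is None


class TestAggregateGene:
    def test_dominant_takes_max(self):
        scored = [(mk(pos=1), 0.9), (mk(pos=2), 0.6)]
        g = aggregate_gene(scored, AD, proband=P)
        assert g.agg_pathogenicity == 0.9
        assert [v.pos for v in g.variants] == [1]

    def test_recessive_single_het_omitted(self):
        assert aggregate_gene([(mk(), 0.9)], AR, proband=P) is None

    def test_recessive_mean_of_top_two(self):
        scored = [(mk(pos=1), 0.8), (mk(pos=2), 0.6), (mk(pos=3), 0.5)]
        g = aggregate_gene(scored, AR, proband=P)
        assert g.agg_pathogenicity == pytest.approx(0.7)
        assert {v.pos for v in g.variants} == {1, 2}

    def test_recessive_homozygous_counts_twice(self):
        g = aggregate_gene([(mk(gt="1/1"), 0.9)], AR, proband=P)
        assert g is not None
        assert g.agg_pathogenicity == pytest.approx(0.9)
        assert len(g.variants) == 1

    def test_recessive_hom_plus_het_top_two(self):
        scored = [(mk(pos=1, gt="0/1"), 0.9), (mk(pos=2, gt="1/1"), 0.6)]
        g = aggregate_gene(scored, AR, proband=P)
        assert g.agg_pathogenicity == pytest.approx((0.9 + 0.6) / 2)

    def test_empty_returns_none(self):
        assert aggregate_gene([], AD, proband=P) is None

    def test_unknown_moi(self):
        with pytest.raises(ValueError):
            aggregate_gene([(mk(), 0.9)], "XL", proband=P)


class TestComputeGenoLR:
    def test_novel_variant_uses_floor(self):
        g = aggregate_gene([(mk(gnomad=None), 1.0)], AD, proband=P)
        lr = compute_geno_lr(g, disease_freq=1e-4, config=CFG)
        assert lr == pytest.approx(1e-4 / 1e-6)

    def test_doubling_fpop_halves_lr(self):
        g1 = aggregate_gene([(mk(gnomad=1e-3), 0.8)], AD, proband=P)
        g2 = aggregate_gene([(mk(gnomad=2e-3), 0.8)], AD, proband=P)
        lr1 = compute_geno_lr(g1, 1e-4, CFG)
        lr2 = compute_geno_lr(g2, 1e-4, CFG)
        assert lr1 == pytest.approx(2 * lr2)

    def test_linear_in_aggregate(self):
        ga = aggregate_gene([(mk(gnomad=1e-3), 0.5)], AD, proband=P)
        gb = aggregate_gene([(mk(gnomad=1e-3), 1.0)], AD, proband=P)
        assert compute_geno_lr(ga, 1e-4, CFG) == pytest.approx(
            0.5 * compute_geno_lr(gb, 1e-4, CFG)
        )

    def test_nonpositive_disease_freq_rejected(self):
        g = aggregate_gene([(mk(), 0.9)], AD, proband=P)
        with pytest.raises(ValueError):
            compute_geno_lr(g, 0.0, CFG)

    def test_identical_across_diseases_sharing_gene(self):
        g = aggregate_gene([(mk(gnomad=2e-3), 0.9)], AD, proband=P)
        lrs = {compute_geno_lr(g, 1e-4, CFG) for _ in range(5)}
        assert len(lrs) == 1


class TestGTHelpers:
    @pytest.mark.parametrize("gt,n", [("0/0", 0), ("0/1", 1), ("1/1", 2),
                                      ("1|0", 1), ("./.", None), (None, None)])
    def test_n_alt_alleles(self, gt, n):
        assert n_alt_alleles(gt) == n

    def test_variant_validation(self):
        with pytest.raises(ValueError):
            Variant(chrom="1", pos=1, ref="A", alt="A")
        with pytest.raises(ValueError):
            Variant(chrom="1", pos=0, ref="A", alt="T")
        with pytest.raises(ValueError):
            Variant(chrom="1", pos=1, ref="A", alt="T", func_effect="bogus")
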