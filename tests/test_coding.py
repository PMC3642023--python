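"""Coding funnel: quality filter, functional classification by codon lookup,
rarity and deleteriousness filters, and the recessive gene model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famprior.coding import (
    classify_variant,
    classify_variants,
    deleteriousness_filter,
    filter_by_frequency,
    filter_by_quality,
    filter_coding_changes,
    recessive_gene_candidates,
    run_coding_funnel,
    shared_candidates,
)
from famprior.intervals import GenomicInterval
from famprior.variants import AnnotatedVariant, GeneModel, Variant


def V(pos, ref="A", alt="G", zyg="het", qual=100.0, chrom="chr1", end=None):
    return Variant(GenomicInterval(chrom, pos, end or pos), ref, alt, zyg, qual)


def AV(cls, gene=None, pos=100, zyg="het", maf=None, sift=None, polyphen=None, gerp=None):
    return AnnotatedVariant(
        variant=V(pos, zyg=zyg),
        function_class=cls,
        gene=gene,
        maf=maf or {},
        sift=sift,
        polyphen=polyphen,
        gerp=gerp,
    )


# A two-exon toy gene with a known coding sequence:
# exon1 101-130 (CDS 104-130), intron 131-200, exon2 201-230 (CDS 201-227).
# CDS reads ATG CGA then fifteen AAA codons then TGA (54 bp, 18 codons).
TOY_GENE = GeneModel(
    "TOY",
    "chr1",
    "+",
    exons=[GenomicInterval("chr1", 101, 130), GenomicInterval("chr1", 201, 230)],
    cds=[GenomicInterval("chr1", 104, 130), GenomicInterval("chr1", 201, 227)],
    cds_seq="ATG" + "CGA" + "AAA" * 15 + "TGA",
)

NC_GENE = GeneModel("NCG", "chr1", "+", exons=[GenomicInterval("chr1", 5001, 5400)])


class TestQualityFilter:
    def test_boundaries(self):
        kept, _ = filter_by_quality([V(1, zyg="het", qual=39.0)])
        assert kept == []  # heterozygous < 40 removed
        kept, _ = filter_by_quality([V(1, zyg="hom", qual=20.0)])
        assert len(kept) == 1  # homozygous 20 is not < 20

    def test_mixed_list(self):
        vs = [
            V(1, zyg="hom", qual=10),
            V(2, zyg="hom", qual=25),
            V(3, zyg="het", qual=39),
            V(4, zyg="het", qual=40),
            V(5, zyg="het", qual=90),
        ]
        kept, n_missing = filter_by_quality(vs)
        assert [v.pos for v in kept] == [2, 4, 5]
        assert n_missing == 0

    def test_missing_quality_counted(self):
        kept, n_missing = filter_by_quality([V(1, qual=None), V(2, qual=80)])
        assert [v.pos for v in kept] == [2]
        assert n_missing == 1


class TestClassification:
    @pytest.mark.parametrize(
        "variant,expected",
        [
            (V(107, ref="C", alt="T"), "stopgain"),  # CGA codon -> TGA
            (V(112, ref="A", alt="G"), "synonymous"),  # AAA -> AAG
            (V(110, ref="A", alt="C"), "nonsynonymous"),  # AAA -> CAA
            (V(226, ref="G", alt="C"), "stoploss"),  # TGA -> TCA
            (V(132, ref="A", alt="G"), "splicing"),  # 2 bp inside the intron
            (V(133, ref="A", alt="G"), "intronic"),  # 3 bp inside the intron
            (V(199, ref="A", alt="G"), "splicing"),  # 2 bp before exon 2
            (V(101, ref="A", alt="G"), "UTR"),  # exonic, outside CDS
            (V(50, ref="A", alt="G"), "upstream"),
            (V(231, ref="A", alt="G"), "downstream"),
            (V(20_000, ref="A", alt="G"), "intergenic"),
            (V(104, ref="ATG", alt="A", end=106), "frameshift"),
            (V(104, ref="ATGC", alt="A", end=107), "nonframeshift"),
            (V(5100, ref="A", alt="G"), "noncoding-gene"),
        ],
    )
    def test_classes_on_toy_gene(self, variant, expected):
        av = classify_variant(variant, [TOY_GENE, NC_GENE])
        assert av.function_class == expected

    def test_gene_assignment(self):
        assert classify_variant(V(110, ref="A", alt="C"), [TOY_GENE]).gene == "TOY"
        assert classify_variant(V(20_000), [TOY_GENE]).gene is None

    def test_minus_strand_codon(self):
        # CDS "ATGAAA" on the minus strand: genomic forward 1001-1006 is TTTCAT
        g = GeneModel(
            "MG",
            "chr1",
            "-",
            exons=[GenomicInterval("chr1", 1001, 1006)],
            cds=[GenomicInterval("chr1", 1001, 1006)],
            cds_seq="ATGAAA",
        )
        av = classify_variant(V(1006, ref="T", alt="C"), [g])  # ATG -> GTG, M->V
        assert av.function_class == "nonsynonymous"

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="reference mismatch"):
            classify_variant(V(107, ref="G", alt="T"), [TOY_GENE])


class TestCodingClassFilter:
    def test_eight_class_mix(self):
        classes = [
            "nonsynonymous",
            "stopgain",
            "splicing",
            "frameshift",
            "nonframeshift",
            "synonymous",
            "intronic",
            "intergenic",
        ]
        kept = filter_coding_changes([AV(c) for c in classes])
        assert len(kept) == 5
        assert all(v.function_class not in ("synonymous", "intronic", "intergenic") for v in kept)


class TestFrequencyFilter:
    def test_rare_variant_survives(self):
        v = AV("nonsynonymous", maf={"thousand_genomes": 0.0027})
        assert filter_by_frequency([v], ["thousand_genomes", "esp5400", "cg46"]) == [v]

    def test_boundary_is_strictly_greater(self):
        v = AV("nonsynonymous", maf={"cg46": 0.01})
        assert filter_by_frequency([v], ["cg46"]) == [v]

    def test_any_database_rule(self):
        v = AV("nonsynonymous", maf={"cg46": 0.05})
        assert filter_by_frequency([v], ["thousand_genomes", "esp5400", "cg46"]) == []

    def test_unknown_database_is_config_error(self):
        with pytest.raises(ValueError, match="unknown frequency database"):
            filter_by_frequency([], ["nope"], known_databases=["cg46"])


class TestRecessiveModel:
    def test_single_homozygote_qualifies(self):
        cand = recessive_gene_candidates([AV("nonsynonymous", gene="G1", zyg="hom")])
        assert set(cand) == {"G1"}

    def test_single_heterozygote_does_not(self):
        assert recessive_gene_candidates([AV("nonsynonymous", gene="G1")]) == {}

    def test_brute_force_over_toy_genes(self):
        rng = np.random.default_rng(7)
        variants = []
        for i in range(9):
            variants.append(
                AV(
                    "nonsynonymous",
                    gene=f"G{rng.integers(5)}",
                    pos=100 + i,
                    zyg="hom" if rng.random() < 0.3 else "het",
                )
            )
        expected = set()
        for g in {v.gene for v in variants}:
            vs = [v for v in variants if v.gene == g]
            homs = [v for v in vs if v.variant.zygosity == "hom"]
            hets = {v.key for v in vs if v.variant.zygosity == "het"}
            if homs or len(hets) >= 2:
                expected.add(g)
        assert set(recessive_gene_candidates(variants)) == expected

    @given(st.permutations(list(range(8))))
    @settings(deadline=None, max_examples=20, derandomize=True)
    def test_order_invariance(self, order):
        base = [
            AV("nonsynonymous", gene=f"G{i % 3}", pos=100 + i, zyg="het" if i % 2 else "hom")
            for i in range(8)
        ]
        shuffled = [base[i] for i in order]
        assert set(recessive_gene_candidates(shuffled)) == set(recessive_gene_candidates(base))

    def test_shared_candidates_intersection(self):
        a = {"A": [], "B": [], "C": []}
        b = {"B": [], "C": [], "D": []}
        assert shared_candidates(a, b) == {"B", "C"}
        assert shared_candidates(a, {}) == set()


class TestDeleteriousness:
    def test_benign_scores_removed(self):
        # a variant with SIFT 0.4 and PolyPhen 0.07 is not deleterious
        v = AV("nonsynonymous", sift=0.4, polyphen=0.07, gerp=2.5)
        assert deleteriousness_filter([v]) == []

    def test_concordantly_deleterious_retained(self):
        v = AV("nonsynonymous", sift=0.01, polyphen=0.95, gerp=3.1)
        assert deleteriousness_filter([v]) == [v]

    def test_unscored_frameshift_passes_by_default(self):
        v = AV("frameshift")
        assert deleteriousness_filter([v]) == [v]

    def test_missing_fails_when_required(self):
        v = AV("frameshift")
        assert deleteriousness_filter([v], missing_passes=False) == []

    def test_stricter_polyphen_threshold_is_subset(self):
        rng = np.random.default_rng(3)
        vs = [
            AV(
                "nonsynonymous",
                pos=100 + i,
                sift=float(rng.uniform(0, 0.1)),
                polyphen=float(rng.uniform(0.5, 1.0)),
                gerp=float(rng.uniform(1, 4)),
            )
            for i in range(50)
        ]
        strict = {v.key for v in deleteriousness_filter(vs, polyphen_min=0.85)}
        loose = {v.key for v in deleteriousness_filter(vs, polyphen_min=0.80)}
        assert strict <= loose


class TestFullFunnel:
    def test_planted_gene_recovered(self, sim_inputs):
        res = run_coding_funnel(
            sim_inputs["proband_variants"],
            sim_inputs["genes"],
            sim_inputs["freqs"],
            sim_inputs["databases"],
            sim_inputs["scores"],
        )
        assert sim_inputs["truth"].planted_gene in res.shared_genes
        planted = set(sim_inputs["truth"].planted_variant_keys)
        assert planted <= {v.key for v in res.shared_deleterious_variants}

    def test_report_is_monotone(self, sim_inputs):
        res = run_coding_funnel(
            sim_inputs["proband_variants"],
            sim_inputs["genes"],
            sim_inputs["freqs"],
            sim_inputs["databases"],
            sim_inputs["scores"],
        )
        for _, _, n_in, n_out in res.report.rows:
            assert n_out <= n_in

    def test_empty_input_gives_zero_report(self, sim_inputs):
        res = run_coding_funnel(
            {"p1": [], "p2": []},
            sim_inputs["genes"],
            sim_inputs["freqs"],
            sim_inputs["databases"],
            sim_inputs["scores"],
        )
        assert res.shared_genes == set()
        assert res.shared_deleterious_variants == []
        assert all(n_in == 0 and n_out == 0 for _, _, n_in, n_out in res.report.rows)

    def test_funnel_counts_match_manual_replay(self, sim_inputs):
        """The chained funnel reports exactly what sequential filtering yields."""
        from famprior.coding import attach_annotations

        res = run_coding_funnel(
            sim_inputs["proband_variants"],
            sim_inputs["genes"],
            sim_inputs["freqs"],
            sim_inputs["databases"],
            sim_inputs["scores"],
        )
        for sample, raw in sim_inputs["proband_variants"].items():
            stages = dict((s, (i, o)) for s, i, o in res.report.counts(sample))
            passed, _ = filter_by_quality(raw)
            assert stages["quality"] == (len(raw), len(passed))
            annotated = attach_annotations(
                classify_variants(passed, sim_inputs["genes"]),
                sim_inputs["freqs"],
                sim_inputs["scores"],
            )
            current = filter_coding_changes(annotated)
            assert stages["coding_classes"][1] == len(current)
            for db in sim_inputs["databases"]:
                nxt = filter_by_frequency(current, [db])
                assert stages[f"maf_{db}"] == (len(current), len(nxt))
                current = nxt
            cand = recessive_gene_candidates(current)
            assert set(cand) == set(res.per_proband_candidates[sample])
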