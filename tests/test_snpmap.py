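import numpy as np
import pytest
from hypothesis import given, strategies as st

from homeokit.models import (
    CallClass,
    CodingEffect,
    GeneModel,
    Genome,
    HomoeoSnp,
    Region,
    SnpCall,
)
from homeokit.simulate import emit_snp_calls, snp_truth_to_homoeosnps
from homeokit.snpmap import (
    Thresholds,
    annotate_effect,
    classify_call,
    identify_homoeologous_snps,
    summarize_effects,
)

from oracles import mutant_cds_translation


def call(freq, depth=20, contig="chr1", pos=100, ref="C", var="T"):
    return SnpCall(contig, pos, ref, var, depth, freq)


class TestClassifyCall:
    @pytest.mark.parametrize(
        "depth,freq,expected",
        [
            (20, 0.98, CallClass.HOMOGENIC),
            (20, 0.52, CallClass.HETEROGENIC),
            (5, 0.98, CallClass.AMBIGUOUS),  # below the depth floor of 8
            (20, 0.80, CallClass.AMBIGUOUS),  # between het window and homo cutoff
            (8, 0.90, CallClass.HOMOGENIC),  # both boundaries inclusive
            (8, 0.30, CallClass.HETEROGENIC),
            (8, 0.70, CallClass.HETEROGENIC),
        ],
    )
    def test_default_thresholds(self, depth, freq, expected):
        assert classify_call(call(freq, depth)) is expected

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            Thresholds(homo_freq=0.4)
        with pytest.raises(ValueError):
            Thresholds(het_low=0.8, het_high=0.7)

    @given(
        freq=st.floats(0, 1),
        depth=st.integers(0, 100),
        homo1=st.floats(0.75, 0.9),
        homo2=st.floats(0.91, 1.0),
    )
    def test_raising_homo_freq_never_adds_homogenic(self, freq, depth, homo1, homo2):
        c = call(freq, depth)
        low = classify_call(c, Thresholds(homo_freq=homo1))
        high = classify_call(c, Thresholds(homo_freq=homo2))
        if high is CallClass.HOMOGENIC:
            assert low is CallClass.HOMOGENIC

    @given(freq=st.floats(0, 1), depth=st.integers(0, 100))
    def test_widening_het_window_never_removes_heterogenic(self, freq, depth):
        c = call(freq, depth)
        narrow = classify_call(c, Thresholds(het_low=0.4, het_high=0.6))
        wide = classify_call(c, Thresholds(het_low=0.2, het_high=0.8))
        if narrow is CallClass.HETEROGENIC:
            assert wide is CallClass.HETEROGENIC


class TestIdentify:
    def test_definition_case(self):
        b = [call(0.98, 20)]
        h = [call(0.52, 30)]
        assert identify_homoeologous_snps(b, h) == [HomoeoSnp("chr1", 100, "C", "T")]

    def test_no_hybrid_call_means_no_snp(self):
        assert identify_homoeologous_snps([call(0.98)], []) == []

    def test_allele_mismatch_rejected(self):
        b = [call(0.98, var="T")]
        h = [call(0.52, var="G")]
        assert identify_homoeologous_snps(b, h) == []

    def test_duplicate_position_raises(self):
        dup = [call(0.98, var="T"), call(0.97, var="G")]
        with pytest.raises(ValueError, match="chr1:100"):
            identify_homoeologous_snps(dup, [])

    def test_output_sorted(self):
        b = [call(0.98, pos=300), call(0.98, pos=100)]
        h = [call(0.5, pos=300), call(0.5, pos=100)]
        snps = identify_homoeologous_snps(b, h)
        assert [s.pos for s in snps] == [100, 300]

    def test_round_trip_with_simulator(self, small_study, small_config):
        genome_a, genome_b, _, truth = small_study
        calls_b, calls_h = emit_snp_calls(genome_a, genome_b, truth, small_config)
        recovered = identify_homoeologous_snps(calls_b, calls_h)
        assert recovered == sorted(snp_truth_to_homoeosnps(truth))


# ---------------------------------------------------------------------------
# Effect annotation on a hand-built locus
#
# chr1 layout (1-based):
#   1-10   intergenic
#   gene g1 (+): exon1 11-25 (UTR 11-13, CDS 14-22: ATG TGG TTT),
#                intron 26-45, exon2 46-60 (CDS 46-48: TAA stop, UTR 49-60)

_G1_CDS = "ATGTGGTTT"
_G1_SEQ = (
    "ACGTACGTAC"  # 1-10
    + "GGG" + _G1_CDS + "TTT"  # exon1 11-25 (wait: 3+9+3 = 15 bases, 11..25)
    + "GTAAGTCCCCCCCCCCCCAG"  # intron 26-45 (20 bases)
    + "TAA" + "ACGTACGTACGT"  # exon2 46-60
    + "ACGTACGTAC"  # trailing intergenic
)


@pytest.fixture(scope="module")
def toy_locus():
    genome = Genome({"chr1": _G1_SEQ})
    gene = GeneModel(
        gene_id="g1",
        contig="chr1",
        start=11,
        end=60,
        strand="+",
        exons=((11, 25), (46, 60)),
        cds=((14, 22), (46, 48)),
    )
    return genome, [gene]


class TestAnnotateEffect:
    def snp(self, pos, genome, alt):
        return HomoeoSnp("chr1", pos, genome.base_at("chr1", pos), alt)

    def test_intergenic(self, toy_locus):
        genome, genes = toy_locus
        eff = annotate_effect(self.snp(5, genome, "T"), genes, genome)
        assert eff.region is Region.INTERGENIC
        assert eff.coding_effect is CodingEffect.NONE

    def test_utr(self, toy_locus):
        genome, genes = toy_locus
        eff = annotate_effect(self.snp(12, genome, "T"), genes, genome)
        assert eff.region is Region.UTR

    def test_synonymous_third_position(self, toy_locus):
        genome, genes = toy_locus
        # TTT -> TTC, codon 3 of the CDS (positions 20-22)
        eff = annotate_effect(self.snp(22, genome, "C"), genes, genome)
        assert eff.region is Region.EXON_CDS
        assert eff.coding_effect is CodingEffect.SYNONYMOUS

    def test_start_lost(self, toy_locus):
        genome, genes = toy_locus
        # ATG -> ATA at CDS positions 14-16
        eff = annotate_effect(self.snp(16, genome, "A"), genes, genome)
        assert eff.coding_effect is CodingEffect.START_LOST

    def test_stop_gained(self, toy_locus):
        genome, genes = toy_locus
        # TGG -> TGA at codon 2 (positions 17-19)
        eff = annotate_effect(self.snp(19, genome, "A"), genes, genome)
        assert eff.coding_effect is CodingEffect.STOP_GAINED

    def test_stop_lost(self, toy_locus):
        genome, genes = toy_locus
        # terminal TAA at 46-48 -> CAA
        eff = annotate_effect(self.snp(46, genome, "C"), genes, genome)
        assert eff.coding_effect is CodingEffect.STOP_LOST

    def test_splice_site_two_bases_into_intron(self, toy_locus):
        genome, genes = toy_locus
        for pos in (26, 27, 44, 45):
            eff = annotate_effect(self.snp(pos, genome, _other(genome, pos)), genes, genome)
            assert eff.region is Region.SPLICE_SITE, pos

    def test_intron_interior(self, toy_locus):
        genome, genes = toy_locus
        eff = annotate_effect(self.snp(30, genome, _other(genome, 30)), genes, genome)
        assert eff.region is Region.INTRON

    def test_reference_mismatch_raises(self, toy_locus):
        genome, genes = toy_locus
        base = genome.base_at("chr1", 22)
        wrong_ref = next(b for b in "ACGT" if b != base)
        alt = next(b for b in "ACGT" if b not in (wrong_ref,))
        with pytest.raises(ValueError, match="mismatch"):
            annotate_effect(HomoeoSnp("chr1", 22, wrong_ref, alt), genes, genome)

    def test_agrees_with_full_translation_oracle(self, small_study):
        """Coding-effect calls match a brute-force rebuild-and-translate oracle."""
        from homeokit.divergence import extract_cds_pair
        from homeokit.snpmap import _cds_offset
        from homeokit.models import revcomp

        genome_a, _, genes, truth = small_study
        rng = np.random.default_rng(0)
        snps = snp_truth_to_homoeosnps(truth)
        cds_snps = [
            (s, g)
            for s in snps
            for g in genes
            if g.contig == s.contig and any(lo <= s.pos <= hi for lo, hi in g.cds)
        ]
        sample = rng.choice(len(cds_snps), size=min(100, len(cds_snps)), replace=False)
        for i in sample:
            s, g = cds_snps[i]
            eff = annotate_effect(s, genes, genome_a)
            cds, _ = extract_cds_pair(g, genome_a, genome_a)
            offset = _cds_offset(g, s.pos)
            alt = s.allele_alt if g.strand == "+" else revcomp(s.allele_alt)
            ref_protein = mutant_cds_translation(cds, offset, cds[offset])
            alt_protein = mutant_cds_translation(cds, offset, alt)
            if eff.coding_effect is CodingEffect.SYNONYMOUS:
                assert alt_protein == ref_protein
            elif eff.coding_effect is CodingEffect.NONSYNONYMOUS:
                assert alt_protein != ref_protein
                assert alt_protein.count("*") == ref_protein.count("*")
            elif eff.coding_effect is CodingEffect.START_LOST:
                assert offset < 3
            elif eff.coding_effect is CodingEffect.STOP_GAINED:
                assert alt_protein.count("*") > ref_protein.count("*")
            elif eff.coding_effect is CodingEffect.STOP_LOST:
                assert alt_protein.count("*") < ref_protein.count("*")


def _other(genome, pos):
    base = genome.base_at("chr1", pos)
    return next(b for b in "ACGT" if b != base)


class TestSummarize:
    def test_empty(self):
        summary = summarize_effects([])
        assert summary["n_total"] == 0
        assert all(v == 0 for v in summary["by_region"].values())

    def test_tally(self, toy_locus):
        genome, genes = toy_locus
        effects = [
            annotate_effect(HomoeoSnp("chr1", 30, genome.base_at("chr1", 30), _other(genome, 30)), genes, genome),
            annotate_effect(HomoeoSnp("chr1", 22, "T", "C"), genes, genome),
            annotate_effect(HomoeoSnp("chr1", 5, genome.base_at("chr1", 5), _other(genome, 5)), genes, genome),
        ]
        summary = summarize_effects(effects)
        assert summary["by_region"]["INTRON"] == 1
        assert summary["by_region"]["EXON_CDS"] == 1
        assert summary["by_region"]["INTERGENIC"] == 1

    def test_gene_flags(self, toy_locus):
        genome, genes = toy_locus
        eff = annotate_effect(HomoeoSnp("chr1", 19, "G", "A"), genes, genome)  # stop gained
        summary = summarize_effects([eff])
        assert summary["gene_flags"]["g1"]["STOP_GAINED"] is True
        assert summary["gene_flags"]["g1"]["NONSYNONYMOUS"] is False
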