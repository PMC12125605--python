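"""Pileup variant calling and codon-effect annotation."""

import numpy as np
import pytest

from numtkit import mapcov, synthetic, variants
from numtkit.seqio import SeqRecord
from numtkit.variants import GeneModel, Variant, annotate_coding_effect, classify_codon_pair


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _reads_with_alt(ref, pos0, alt, n_alt, n_ref, read_len=150):
    """Reads covering 0-based pos0; n_alt carry `alt`, n_ref carry the reference."""
    reads = []
    for i in range(n_alt + n_ref):
        start = pos0 - 75 + (i % 30)
        window = list(ref[start : start + read_len])
        if i < n_alt:
            window[pos0 - start] = alt
        reads.append(SeqRecord(f"q{i}", "".join(window)))
    return reads


class TestPileup:
    def test_full_frequency_variant(self, rng):
        ref = _random_seq(rng, 2000)
        alt = "A" if ref[1000] != "A" else "C"
        idx = mapcov.build_index([SeqRecord("r", ref)])
        aln = mapcov.map_reads(_reads_with_alt(ref, 1000, alt, 100, 0), idx)
        (v,) = variants.pileup_variants(aln)
        assert (v.pos, v.ref_base, v.alt_base) == (1001, ref[1000], alt)
        assert v.frequency == pytest.approx(100.0)

    def test_minority_allele_below_min_freq_not_emitted(self, rng):
        ref = _random_seq(rng, 2000)
        alt = "A" if ref[1000] != "A" else "C"
        idx = mapcov.build_index([SeqRecord("r", ref)])
        aln = mapcov.map_reads(_reads_with_alt(ref, 1000, alt, 49, 51), idx)
        called = variants.pileup_variants(aln, min_freq=0.5)
        assert all(v.pos != 1001 for v in called)
        # at exactly half the covering reads the variant is emitted
        aln = mapcov.map_reads(_reads_with_alt(ref, 1000, alt, 50, 50), idx)
        assert any(v.pos == 1001 for v in variants.pileup_variants(aln, min_freq=0.5))

    def test_low_depth_not_emitted(self, rng):
        ref = _random_seq(rng, 2000)
        alt = "A" if ref[1000] != "A" else "C"
        idx = mapcov.build_index([SeqRecord("r", ref)])
        aln = mapcov.map_reads(_reads_with_alt(ref, 1000, alt, 5, 0), idx)
        assert variants.pileup_variants(aln, min_depth=10) == []


TABLE_CODON_PAIRS = [
    # (ref codon, alt codon, ref aa, alt aa, class)
    ("TGC", "GGC", "C", "G", "missense"),
    ("GTC", "ATC", "V", "I", "missense"),
    ("GGT", "AGT", "G", "S", "missense"),
    ("CGA", "TGA", "R", "*", "nonsense"),
    ("CCT", "CAT", "P", "H", "missense"),
    ("CTG", "CCG", "L", "P", "missense"),
    ("GAT", "GGT", "D", "G", "missense"),
    ("CAC", "CGC", "H", "R", "missense"),
    ("TGC", "GGC", "C", "G", "missense"),
    ("ACT", "GCT", "T", "A", "missense"),
    ("TCC", "CCC", "S", "P", "missense"),
]


class TestCodonEffects:
    @pytest.mark.parametrize("ref,alt,ref_aa,alt_aa,klass", TABLE_CODON_PAIRS)
    def test_observed_codon_pairs(self, ref, alt, ref_aa, alt_aa, klass):
        assert classify_codon_pair(ref, alt) == (ref_aa, alt_aa, klass)

    def test_exactly_one_nonsense_among_the_pairs(self):
        classes = [classify_codon_pair(r, a)[2] for r, a, *_ in TABLE_CODON_PAIRS]
        assert classes.count("nonsense") == 1

    def test_synonymous_pair(self):
        assert classify_codon_pair("CTG", "TTG") == ("L", "L", "synonymous")

    def test_plus_strand_annotation(self):
        #        123456789
        ref = SeqRecord("r", "AACGAGGTTGA" + "A")  # CDS 3..11: CGA GGT TGA
        gm = GeneModel("g", "r", 3, 11, "+")
        v = Variant("r", 3, "C", "T", 100, 100)
        eff = annotate_coding_effect(v, [gm], [ref])
        assert (eff.codon_index, eff.ref_codon, eff.alt_codon) == (1, "CGA", "TGA")
        assert eff.effect_class == "nonsense"

    def test_minus_strand_annotation(self):
        # genome = revcomp(CGA GGT GGG) laid at 2..10; coding codon 1 is CGA
        coding = "CGAGGTGGG"
        genome = "T" + str(SeqRecord("_", coding).reverse_complement().seq) + "TT"
        ref = SeqRecord("r", genome)
        gm = GeneModel("g", "r", 2, 10, "-")
        # coding position 1 (the C of CGA) sits at genome pos = cds_end = 10
        v = Variant("r", 10, genome[9], "A", 100, 100)  # G->A on genome = C->T coding
        eff = annotate_coding_effect(v, [gm], [ref])
        assert (eff.codon_index, eff.ref_codon, eff.alt_codon) == (1, "CGA", "TGA")
        assert eff.effect_class == "nonsense"

    def test_noncoding_position_returns_none(self):
        ref = SeqRecord("r", "A" * 30)
        gm = GeneModel("g", "r", 10, 18, "+")
        assert annotate_coding_effect(Variant("r", 2, "A", "G", 10, 10), [gm], [ref]) is None

    def test_cds_not_divisible_by_three_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("g", "r", 1, 7, "+")


class TestCompareStrains:
    def test_exact_recovery_on_clean_reads(self, clean_truth, clean_reads):
        frame = variants.compare_strains(
            clean_reads["A"],
            clean_truth.strain_b,
            clean_reads["B"],
            clean_truth.strain_a,
            gene_models=clean_truth.gene_models,
        )
        conf = frame[frame["confirmed"]]
        truth = {(s.chrom, s.pos, s.ref_base, s.alt_base) for s in clean_truth.snv_truth}
        called = {(r.ref_id, r.pos, r.ref_base, r.alt_base) for r in conf.itertuples()}
        assert called == truth
        cfg = clean_truth.config
        assert len(conf) == cfg.snv_total
        assert (conf["effect_class"] == "noncoding").sum() == cfg.snv_noncoding
        assert conf["effect_class"].isin(["missense", "nonsense"]).sum() == cfg.snv_nonsynonymous
        assert (conf["frequency"] == 100.0).all()

    def test_effect_classes_match_truth(self, clean_truth, clean_reads):
        frame = variants.compare_strains(
            clean_reads["A"],
            clean_truth.strain_b,
            clean_reads["B"],
            clean_truth.strain_a,
            gene_models=clean_truth.gene_models,
        )
        by_pos = {(s.chrom, s.pos): s.effect for s in clean_truth.snv_truth}
        for row in frame[frame["confirmed"]].itertuples():
            assert row.effect_class == by_pos[(row.ref_id, row.pos)]

    def test_zero_injected_snvs_gives_empty_table(self):
        cfg = synthetic.scaled_config(
            seed=17, error_rate=0.0, snv_total=0, snv_noncoding=0, snv_coding=0,
            snv_nonsynonymous=0,
        )
        truth = synthetic.generate_genome(cfg)
        reads = synthetic.simulate_reads(truth)
        frame = variants.compare_strains(
            reads["A"], truth.strain_b, reads["B"], truth.strain_a
        )
        assert frame.empty

    def test_one_direction_artifact_flagged_unconfirmed(self, rng):
        # identical assemblies, but one "strain" contributes alt reads at a
        # position where the reverse direction sees nothing: unconfirmed
        ref = _random_seq(rng, 3000)
        asm = [SeqRecord("r", ref)]
        alt = "A" if ref[1500] != "A" else "C"
        reads_b = _reads_with_alt(ref, 1500, alt, 30, 0)  # map to assembly A, all alt
        reads_a = _reads_with_alt(ref, 1500, "", 0, 30)  # reference-matching reads
        frame = variants.compare_strains(reads_a, asm, reads_b, asm)
        assert len(frame) == 1
        assert not frame.iloc[0]["confirmed"]
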