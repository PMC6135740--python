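"""TRENI calling: novelty, placement, junction ratios, enrichment."""

import numpy as np
import pandas as pd
import pytest

from rainbowseq import treni
from rainbowseq.io import ReadBlocks, RepeatFeature, TranscriptModel
from rainbowseq.simulate import SyntheticConfig, simulate_annotation_and_reads


def tx(tid, exons, strand="+", sc=None, gene="g1", novel=False):
    return TranscriptModel(tid, gene, "chr1", strand, exons,
                           start_codon=sc, is_novel=novel)


def rep(start, end, family="Alu", name=None):
    return RepeatFeature("chr1", start, end, "+",
                         name or f"{family}_{start}", family, "SINE")


REF = tx("ref1", [(1000, 1200), (2000, 2200), (3000, 3200)], sc=2050)


class TestFindNovel:
    def test_identical_chain_not_novel(self):
        cand = tx("c1", REF.exons, novel=True)
        assert treni.find_novel([cand], [REF]) == []

    def test_extra_5prime_exon_is_novel(self):
        cand = tx("c2", [(400, 500)] + REF.exons, gene="x")
        (n,) = treni.find_novel([cand], [REF])
        assert n.is_novel and n.gene_id == "g1"  # attributed by overlap

    def test_monoexonic_rules(self):
        inside = tx("m1", [(1050, 1150)])
        outside = tx("m2", [(5000, 5100)])
        out = {t.transcript_id for t in treni.find_novel([inside, outside],
                                                         [REF])}
        assert out == {"m2"}

    def test_synthetic_truth_recovered(self, annotation_data):
        transcripts, _, _, truth = annotation_data
        refs = [t for t in transcripts if not t.is_novel]
        cands = [t for t in transcripts if t.is_novel]
        novel = treni.find_novel(cands, refs)
        assert {t.transcript_id for t in novel} == set(truth.transcript_id)
        assert treni.find_novel(refs, refs) == []


class TestCallTreni:
    def test_overlap_threshold(self):
        novel = tx("n1", [(100, 300)], novel=True)
        assert treni.call_treni([novel], [rep(150, 200)])  # inside exon
        assert not treni.call_treni([novel], [rep(300, 400)])  # intronic
        # 9 bp is below the 10 bp default
        assert not treni.call_treni([novel], [rep(291, 400)])
        assert treni.call_treni([novel], [rep(290, 400)])
        assert treni.call_treni([], []) == []

    def test_multiple_repeats_recorded(self):
        novel = tx("n1", [(100, 600)], novel=True)
        (record,) = treni.call_treni([novel], [rep(100, 200),
                                               rep(400, 500, "B2")])
        assert len(record.repeat_hits) == 2


class TestPlacement:
    def test_plus_strand(self):
        t = tx("t", [(50, 250)], sc=200)
        assert treni.classify_placement(t, rep(100, 150)) == {"five_prime_utr"}
        assert treni.classify_placement(t, rep(200, 240)) == \
            {"downstream_of_start"}

    def test_minus_strand_flip(self):
        t = tx("t", [(50, 250)], strand="-", sc=200)
        assert treni.classify_placement(t, rep(100, 150)) == \
            {"downstream_of_start"}
        assert treni.classify_placement(t, rep(210, 240)) == {"five_prime_utr"}

    def test_straddle_contributes_both(self):
        t = tx("t", [(50, 250)], sc=200)
        assert treni.classify_placement(t, rep(180, 220)) == \
            {"five_prime_utr", "downstream_of_start"}

    def test_no_start_codon_empty(self):
        t = tx("t", [(50, 250)])
        assert treni.classify_placement(t, rep(100, 150)) == frozenset()


class TestJunctionRatio:
    HOST = tx("n1", [(100, 300), (1000, 1200), (2000, 2200)], sc=1050,
              novel=True)
    REF_EXONS = [(1000, 1200), (2000, 2200)]
    REPEAT = rep(100, 300)

    def make_reads(self, n_spliced, n_contained):
        reads = []
        for i in range(n_spliced):
            reads.append(ReadBlocks(f"s{i}", "chr1",
                                    [(150, 250), (1000, 1050)]))
        for i in range(n_contained):
            reads.append(ReadBlocks(f"c{i}", "chr1", [(120, 220)]))
        return reads

    def test_all_spliced(self):
        jr = treni.junction_ratio(self.REPEAT, self.HOST, self.REF_EXONS,
                                  self.make_reads(20, 0))
        assert jr == 1.0

    def test_half_spliced(self):
        jr = treni.junction_ratio(self.REPEAT, self.HOST, self.REF_EXONS,
                                  self.make_reads(10, 10))
        assert jr == 0.5

    def test_no_overlapping_reads_undefined(self):
        far = [ReadBlocks("x", "chr1", [(5000, 5100)])]
        assert treni.junction_ratio(self.REPEAT, self.HOST, self.REF_EXONS,
                                    far) is None

    def test_spliced_to_wrong_exon_not_counted(self):
        reads = [ReadBlocks("w", "chr1", [(150, 250), (2000, 2100)])]
        assert treni.junction_ratio(self.REPEAT, self.HOST, self.REF_EXONS,
                                    reads) == 0.0

    def test_nearest_exon_tie_break_3prime(self):
        r = rep(1500, 1600)
        exons = [(1000, 1400), (1700, 2100)]  # both 100 bp away
        assert treni.nearest_reference_exon(r, exons, "+") == (1700, 2100)
        assert treni.nearest_reference_exon(r, exons, "-") == (1000, 1400)


def test_jr_filter_boundary():
    r1, r2, r3 = rep(0, 10, name="a"), rep(20, 30, name="b"), rep(40, 50, name="c")
    kept = treni.jr_filter({r1: 0.9, r2: 0.8999, r3: None})
    assert kept == [r1]
    assert treni.jr_filter({}) == []


class TestFamilyEnrichment:
    def test_cross_product_oracle(self):
        fe = treni.enrichment_from_table("Alu", 30, 70, 100, 900)
        assert fe.odds_ratio == pytest.approx(27 / 7)
        assert fe.chi2_p < 0.01
        lo, hi = fe.ci95
        assert lo < 27 / 7 < hi

    def test_min_copies_suppression(self):
        fe = treni.enrichment_from_table("Alu", 19, 81, 100, 900)
        assert fe.odds_ratio is None and fe.ci95 is None and fe.chi2_p is None
        assert fe.in_treni_copies == 19

    def test_independence_gives_unit_or(self):
        fe = treni.enrichment_from_table("Alu", 30, 60, 100, 200,
                                         min_copies=1)
        assert fe.odds_ratio == pytest.approx(1.0)

    def test_partition_property(self, annotation_data):
        # every genome-wide copy lands in exactly one family's table, once
        _, repeats, _, _ = annotation_data
        treni_reps = set(repeats[:10])
        rows = treni.family_enrichment(repeats, treni_reps, min_copies=1)
        total = sum(r.in_treni_copies + r.out_treni_copies for r in rows)
        assert total == len(repeats)
        n_in = sum(r.in_treni_copies for r in rows)
        assert n_in == len(treni_reps)
        for r in rows:
            assert r.in_treni_copies + r.other_in == n_in
            assert (r.in_treni_copies + r.out_treni_copies + r.other_in
                    + r.other_out) == len(repeats)


def test_synthetic_recall_and_jr(annotation_data, small_config):
    transcripts, repeats, reads, truth = annotation_data
    refs = [t for t in transcripts if not t.is_novel]
    novel = treni.find_novel([t for t in transcripts if t.is_novel], refs)
    records = treni.call_treni(novel, repeats)
    by_id = {t.transcript_id: t for t in transcripts}
    records = treni.annotate_placements(records, by_id)

    called = {r.transcript_id for r in records}
    expected = set(truth[truth.is_treni].transcript_id)
    assert called == expected  # 100% precision and recall

    truth_map = truth.set_index("transcript_id")
    ref_exons = {}
    for t in refs:
        ref_exons.setdefault(t.gene_id, []).extend(t.exons)
    for record in records:
        row = truth_map.loc[record.transcript_id]
        assert set(record.placement) == {row.placement}
        (repeat, _), = record.repeat_hits
        jr = treni.junction_ratio(repeat, by_id[record.transcript_id],
                                  ref_exons[record.gene_id], reads)
        assert jr == pytest.approx(
            row.true_junction_fraction,
            abs=1.0 / small_config.reads_per_repeat)


def test_treni_lineage_tests_delegate(expr_data):
    cells, fpkm, truth = expr_data
    iso = fpkm.iloc[:80].copy()
    iso.index = [f"treni_{i}" for i in range(80)]
    tests, bg, comp = treni.treni_lineage_tests(iso, cells, "four_cell",
                                                seed=1)
    # identical call path as the gene-level test on a renamed matrix
    from rainbowseq import difftest
    gene_tests = difftest.test_features(fpkm.iloc[:80], cells, "four_cell")
    np.testing.assert_allclose(tests["p"].values, gene_tests["p"].values)
    assert comp.n_real == len(tests)
    with pytest.raises(ValueError):
        treni.treni_lineage_tests(pd.DataFrame(), cells, "four_cell")
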