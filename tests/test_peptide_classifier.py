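"""Ten-category peptide classification and the cross-annotation summary."""

import random

import pytest

from pgmap.annotation import parse_gff3
from pgmap.fixtures import PEPTIDE_CATEGORY_DEFAULTS, plant_peptides
from pgmap.models import Gene, GeneSet, PeptideLocus, Transcript
from pgmap.peptide_classes import (CATEGORIES, AnnotationIndex,
                                   NoveltySummary, classify_against_two,
                                   classify_peptide, round_half_up,
                                   summarize_novelty)

from conftest import locus_of


def loc(start, end, strand="+", chrom="chr1", frame=None):
    return PeptideLocus(peptide="A" * ((end - start) // 3), chrom=chrom,
                        strand=strand, frame=frame if frame is not None
                        else start % 3, start=start, end=end)


class TestToyClassification:
    """Against the two-exon toy gene (exons [1001,1600)+[2001,2600),
    CDS [1201,1600)+[2001,2400), strand +)."""

    @pytest.fixture()
    def idx(self, toy_gff3):
        return AnnotationIndex(parse_gff3(toy_gff3))

    def test_annotation_free_desert_is_intergenic(self, idx):
        assert classify_peptide(loc(5000, 5030), idx) == "intergenic"

    def test_locus_inside_intron(self, idx):
        assert classify_peptide(loc(1700, 1730), idx) == "intron"

    def test_cds_overlap_with_shifted_frame(self, idx):
        # CDS frame at 1300 has phase (1300-1201)%3=0; a peptide whose codon
        # grid starts at 1301 is out of frame by one base
        assert classify_peptide(loc(1301, 1331), idx) == "coding_out_of_frame"

    def test_in_frame_upstream_abutting_cds_is_nter_extension(self, idx):
        assert classify_peptide(loc(1171, 1201), idx) == "nter_extension"

    def test_in_frame_downstream_of_stop_is_cter_extension(self, idx):
        # CDS length (399+399) is divisible by 3, so the frame continues at 2400
        assert classify_peptide(loc(2400, 2430), idx) == "cter_extension"

    def test_wholly_within_utr5(self, idx):
        assert classify_peptide(loc(1050, 1080), idx) == "utr5"

    def test_wholly_within_utr3(self, idx):
        assert classify_peptide(loc(2450, 2480), idx) == "utr3"

    def test_crossing_transcript_start_is_exon5_extension(self, idx):
        assert classify_peptide(loc(989, 1019), idx) == "exon5_extension"

    def test_crossing_transcript_end_is_exon3_extension(self, idx):
        assert classify_peptide(loc(2590, 2620), idx) == "exon3_extension"

    def test_antisense_overlap_is_intergenic(self, idx):
        assert classify_peptide(loc(1700, 1730, strand="-"), idx) == "intergenic"


def test_noncoding_transcript_exon():
    t = Transcript(id="nc", chrom="chr1", strand="+", exons=[(100, 400)])
    gs = GeneSet([Gene(id="g", chrom="chr1", strand="+", transcripts=[t])])
    assert classify_peptide(loc(200, 230), gs) == "transcript_noncoding"


class TestTwoAnnotations:
    def test_region_genic_in_one_set_only(self, toy_gff3):
        gs_a = parse_gff3(toy_gff3)
        empty = GeneSet([])
        ca, cb = classify_against_two(loc(1700, 1730), gs_a, empty)
        assert (ca, cb) == ("intron", "intergenic")

    def test_identical_annotations_always_agree(self, toy_gff3, ref_fixture_no_edits):
        fix = ref_fixture_no_edits
        planted = plant_peptides(fix, {"intron": 3, "utr5": 2, "intergenic": 3}, 7)
        idx_a = AnnotationIndex(fix.ann_a)
        idx_b = AnnotationIndex(fix.ann_b)
        for p in planted:
            ca, cb = classify_against_two(locus_of(p), idx_a, idx_b)
            assert ca == cb == p.category

    def test_empty_second_set_is_always_intergenic(self, ref_fixture):
        planted = plant_peptides(ref_fixture, {"intron": 2, "utr3": 2}, 8)
        empty = AnnotationIndex(GeneSet([]))
        idx_a = AnnotationIndex(ref_fixture.ann_a)
        for p in planted:
            assert classify_against_two(locus_of(p), idx_a, empty)[1] == "intergenic"


def test_all_ten_categories_recovered_on_planted_fixture(ref_fixture):
    """Classification recovers 100% of planted ground-truth categories."""
    for ann, gs in (("a", ref_fixture.ann_a), ("b", ref_fixture.ann_b)):
        planted = plant_peptides(ref_fixture, PEPTIDE_CATEGORY_DEFAULTS,
                                 seed=91, annotation=ann)
        assert {p.category for p in planted} == set(CATEGORIES)
        idx = AnnotationIndex(gs)
        for p in planted:
            assert classify_peptide(locus_of(p), idx) == p.category


def test_classification_independent_of_gene_order_and_chrom_names(ref_fixture):
    planted = plant_peptides(ref_fixture, {"intron": 3, "coding_out_of_frame": 3}, 17)
    gs = ref_fixture.ann_a
    shuffled = GeneSet(genes=list(reversed(gs.genes)), source_label=gs.source_label)
    renamed = GeneSet(genes=[
        Gene(id=g.id, chrom="scaffold_" + g.chrom, strand=g.strand,
             transcripts=[Transcript(id=t.id, chrom="scaffold_" + t.chrom,
                                     strand=t.strand, exons=list(t.exons),
                                     cds=list(t.cds)) for t in g.transcripts])
        for g in gs.genes])
    for p in planted:
        l = locus_of(p)
        l2 = PeptideLocus(l.peptide, "scaffold_" + l.chrom, l.strand, l.frame,
                          l.start, l.end)
        assert classify_peptide(l, GeneSet(list(gs.genes))) \
            == classify_peptide(l, shuffled) == classify_peptide(l2, renamed)


class TestNoveltySummary:
    def test_published_crosstab_row_percentages(self):
        # row counts of a published 157k-peptide cross-tab, used as a frozen
        # worked example of the percentage/total arithmetic
        s = NoveltySummary.from_counts({"intergenic": (87_208, 3_949, 15_735)})
        assert s.row_total("intergenic") == 106_892
        assert s.percentages("intergenic") == (81.6, 3.7, 14.7)

    def test_single_agreeing_pair(self):
        s = summarize_novelty([("intron", "intron")])
        assert s.counts["intron"] == (1, 0, 0)
        assert s.percentages("intron") == (100.0, 0.0, 0.0)

    def test_disagreeing_pair_counts_in_both_rows(self):
        s = summarize_novelty([("intron", "intergenic")])
        assert s.counts["intron"] == (0, 1, 0)
        assert s.counts["intergenic"] == (0, 0, 1)
        assert s.row_total("intron") == s.row_total("intergenic") == 1

    def test_column_totals_sum_to_grand_total(self):
        rng = random.Random(2)
        pairs = [(rng.choice(CATEGORIES), rng.choice(CATEGORIES))
                 for _ in range(500)]
        s = summarize_novelty(pairs)
        assert sum(s.row_total(c) for c in CATEGORIES) == s.grand_total
        assert sum(s.column_totals) == s.grand_total

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            summarize_novelty([("intron", "weird")])
        with pytest.raises(ValueError):
            NoveltySummary.from_counts({"weird": (1, 0, 0)})


def test_rounding_is_half_up():
    assert round_half_up(11.75, 1) == 11.8
    assert round_half_up(0.25, 1) == 0.3
    assert round_half_up(1.4499, 1) == 1.4
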