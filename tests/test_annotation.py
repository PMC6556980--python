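"""Gene-model parsing, derived regions and interval lookup."""

import random

import pytest

from pgmap.annotation import (IntervalIndex, ParseError, derive_regions,
                              parse_gff3, parse_gtf, write_gff3)
from pgmap.models import (GeneSet, Transcript, ValidationError,
                          merge_intervals)

from conftest import TOY_GFF3


def test_parse_toy_gff3_structure(toy_gff3):
    gs = parse_gff3(toy_gff3, dialect="ncbi-like")
    assert len(gs) == 1
    (tx,) = list(gs.transcripts())
    assert tx.id == "T1" and tx.strand == "+"
    assert tx.exons == [(1001, 1600), (2001, 2600)]
    assert tx.cds == [(1201, 1600), (2001, 2400)]
    assert tx.biotype == "coding"


def test_cds_free_transcript_is_noncoding(tmp_path):
    text = "\n".join(l for l in TOY_GFF3.splitlines() if "\tCDS\t" not in l)
    p = tmp_path / "nc.gff3"
    p.write_text(text + "\n")
    (tx,) = list(parse_gff3(str(p)).transcripts())
    assert tx.biotype == "noncoding" and tx.cds == []


def test_out_of_order_exons_are_stored_sorted(tmp_path):
    lines = TOY_GFF3.splitlines()
    lines[3], lines[4] = lines[4], lines[3]  # swap the two exon rows
    p = tmp_path / "shuffled.gff3"
    p.write_text("\n".join(lines) + "\n")
    (tx,) = list(parse_gff3(str(p)).transcripts())
    assert tx.exons == sorted(tx.exons)


def test_orphan_parent_is_a_parse_error(tmp_path):
    p = tmp_path / "orphan.gff3"
    p.write_text(TOY_GFF3.replace("Parent=G1", "Parent=MISSING"))
    with pytest.raises(ParseError, match="MISSING"):
        parse_gff3(str(p))


def test_exon_outside_transcript_bounds_rejected(tmp_path):
    p = tmp_path / "oob.gff3"
    p.write_text(TOY_GFF3.replace("exon\t2002\t2600", "exon\t2002\t3600"))
    with pytest.raises(ValidationError):
        parse_gff3(str(p))


def test_overlapping_exons_rejected():
    with pytest.raises(ValidationError):
        Transcript(id="bad", chrom="c", strand="+",
                   exons=[(0, 100), (50, 150)])


def test_explicit_utr_features_override_derivation(tmp_path):
    text = TOY_GFF3 + (
        "chr1\ttoy\tfive_prime_UTR\t1002\t1150\t.\t+\t.\tParent=T1\n")
    p = tmp_path / "utr.gff3"
    p.write_text(text)
    (tx,) = list(parse_gff3(str(p), dialect="ensembl-like").transcripts())
    assert derive_regions(tx).utr5 == [(1001, 1150)]
    # the ncbi-like dialect ignores the explicit feature and derives instead
    (tx2,) = list(parse_gff3(str(p), dialect="ncbi-like").transcripts())
    assert derive_regions(tx2).utr5 == [(1001, 1201)]


class TestParseGtf:
    def _write(self, tmp_path, body):
        p = tmp_path / "asm.gtf"
        p.write_text(body)
        return str(p)

    def test_two_exon_transcript(self, tmp_path):
        body = (
            'chr1\tasm\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tasm\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n')
        gs = parse_gtf(self._write(tmp_path, body))
        (tx,) = list(gs.transcripts())
        assert tx.exons == [(100, 200), (300, 400)] and tx.cds == []

    def test_shared_gene_id_groups_transcripts(self, tmp_path):
        body = (
            'chr1\tasm\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tasm\texon\t101\t250\t.\t+\t.\tgene_id "g1"; transcript_id "t2";\n')
        gs = parse_gtf(self._write(tmp_path, body))
        assert len(gs.genes) == 1 and len(gs.genes[0].transcripts) == 2

    def test_empty_file_gives_empty_geneset(self, tmp_path):
        gs = parse_gtf(self._write(tmp_path, ""))
        assert len(gs) == 0

    def test_missing_transcript_id_is_an_error(self, tmp_path):
        body = 'chr1\tasm\texon\t101\t200\t.\t+\t.\tgene_id "g1";\n'
        with pytest.raises(Exception):
            parse_gtf(self._write(tmp_path, body))


class TestDeriveRegions:
    def toy(self, strand):
        return Transcript(id="T", chrom="c", strand=strand,
                          exons=[(1001, 1600), (2001, 2600)],
                          cds=[(1201, 1600), (2001, 2400)])

    def test_plus_strand_enumerated_by_hand(self):
        r = derive_regions(self.toy("+"))
        assert r.introns == [(1600, 2001)]
        assert r.utr5 == [(1001, 1201)]
        assert r.utr3 == [(2400, 2600)]

    def test_minus_strand_swaps_utrs(self):
        r = derive_regions(self.toy("-"))
        assert r.utr5 == [(2400, 2600)]
        assert r.utr3 == [(1001, 1201)]

    def test_single_exon_has_no_introns(self):
        t = Transcript(id="T", chrom="c", strand="+", exons=[(0, 300)],
                       cds=[(60, 240)])
        assert derive_regions(t).introns == []

    def test_frame_phase_walks_5prime_to_3prime(self):
        r = derive_regions(self.toy("+"))
        # first CDS base has phase 0; phase continues across the intron
        assert r.phase(1201) == 0
        assert r.phase(1202) == 1
        first_block_len = 1600 - 1201
        assert r.phase(2001) == first_block_len % 3
        rm = derive_regions(self.toy("-"))
        assert rm.phase(2399) == 0  # 5'-most CDS base on the minus strand
        assert rm.phase(2398) == 1

    def test_regions_tile_exons_for_coding_transcripts(self, ref_fixture):
        for t in ref_fixture.ann_a.transcripts():
            if not t.cds:
                continue
            r = derive_regions(t)
            tiled = merge_intervals(r.utr5 + r.utr3 + t.cds)
            assert tiled == merge_intervals(t.exons)

    def test_strand_flip_swaps_utr5_utr3(self, ref_fixture):
        for t in ref_fixture.ann_a.transcripts():
            if not t.cds:
                continue
            flipped = Transcript(id=t.id, chrom=t.chrom,
                                 strand="-" if t.strand == "+" else "+",
                                 exons=list(t.exons), cds=list(t.cds))
            r, rf = derive_regions(t), derive_regions(flipped)
            assert r.utr5 == rf.utr3 and r.utr3 == rf.utr5


def brute_force_query(gs: GeneSet, chrom, start, end, strand=None, mode="any"):
    hits = []
    for t in gs.transcripts():
        if t.chrom != chrom or t.end <= start or t.start >= end:
            continue
        if mode == "same" and t.strand != strand:
            continue
        if mode == "opposite" and t.strand == strand:
            continue
        hits.append(t)
    return sorted(hits, key=lambda t: (t.start, t.end, t.id))


def test_interval_index_equals_brute_force(ref_fixture):
    gs = ref_fixture.ann_a
    idx = IntervalIndex(gs)
    rng = random.Random(4)
    chroms = sorted(ref_fixture.genome)
    for _ in range(1000):
        chrom = rng.choice(chroms + ["chrUnknown"])
        start = rng.randrange(0, 49_000)
        end = start + rng.randrange(1, 3000)
        mode = rng.choice(["any", "same", "opposite"])
        strand = rng.choice("+-")
        got = idx.query(chrom, start, end, strand=strand, mode=mode)
        want = brute_force_query(gs, chrom, start, end, strand=strand, mode=mode)
        assert got == want


def test_interval_index_toy_queries(toy_gff3):
    idx = IntervalIndex(parse_gff3(toy_gff3))
    assert [t.id for t in idx.query("chr1", 1700, 1730)] == ["T1"]
    assert idx.query("chr1", 9000, 9100) == []
    assert idx.query("chr9", 1700, 1730) == []


def test_gff3_round_trip(ref_fixture, tmp_path):
    path = str(tmp_path / "rt.gff3")
    write_gff3(ref_fixture.ann_b, path, explicit_utrs=True)
    back = parse_gff3(path, dialect="ensembl-like")
    orig = {t.id: t for t in ref_fixture.ann_b.transcripts()}
    parsed = {t.id: t for t in back.transcripts()}
    assert orig.keys() == parsed.keys()
    for tid, t in orig.items():
        assert parsed[tid].exons == t.exons
        assert parsed[tid].cds == t.cds
        assert derive_regions(parsed[tid]).utr5 == derive_regions(t).utr5
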