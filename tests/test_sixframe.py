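"""Six-frame translation, segmentation, partitioning, decoys and the
genome-coordinate round trip."""

import math
import random

import pytest

from pgmap.models import DbBuildConfig, GenomeSequence, ValidationError
from pgmap.sixframe import (FRAMES, make_decoy, parse_segment_header,
                            read_fasta, reverse_complement, segment_frame,
                            segment_genome, segment_to_genomic, translate,
                            translate_six_frames, write_partitioned_fasta)


class TestTranslate:
    def test_forward_frame_with_stop(self):
        assert translate_six_frames("ATGAAATAG")[("+", 0)] == "MK*"

    def test_reverse_frame_manual_codons(self):
        # revcomp("ATGAAATAG") = "CTATTTCAT" -> CTA TTT CAT = L F H
        assert translate_six_frames("ATGAAATAG")[("-", 0)] == "LFH"

    def test_codon_containing_n_is_x(self):
        assert translate_six_frames("ATGNAA")[("+", 0)] == "MX"

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValidationError):
            translate_six_frames("")

    def test_frames_shift_and_drop_partial_codons(self):
        frames = translate_six_frames("ATGAAATAG")
        assert frames[("+", 1)] == translate("TGAAATAG")
        assert frames[("+", 2)] == translate("GAAATAG")
        assert len(frames[("+", 1)]) == 2  # 8 nt -> 2 codons


class TestSegmentation:
    def starts_ends(self, n, cfg):
        segs = segment_frame("A" * n, cfg)
        return [(s.aa_start, s.aa_start + len(s.aa_seq)) for s in segs]

    def test_exact_single_segment(self):
        assert self.starts_ends(600, DbBuildConfig()) == [(0, 600)]

    def test_step_is_seglen_minus_overlap(self):
        assert self.starts_ends(1200, DbBuildConfig()) == [
            (0, 600), (540, 1140), (1080, 1200)]

    def test_short_tail_segment_emitted(self):
        assert self.starts_ends(650, DbBuildConfig()) == [(0, 600), (540, 650)]

    def test_short_frame_single_full_segment(self):
        assert self.starts_ends(123, DbBuildConfig()) == [(0, 123)]

    @pytest.mark.parametrize("n", [30, 47, 48, 49, 95, 200])
    def test_every_short_substring_is_covered(self, n):
        """Any window up to the overlap length occurs intact in a segment."""
        cfg = DbBuildConfig(seg_len=48, overlap=12, per_file=10)
        rng = random.Random(n)
        frame = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))
        segs = [s.aa_seq for s in segment_frame(frame, cfg)]
        for w in range(1, cfg.overlap + 1):
            for i in range(n - w + 1):
                assert any(frame[i:i + w] in s for s in segs)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            DbBuildConfig(seg_len=60, overlap=60)


class TestPartitionedFasta:
    def segments(self, k):
        return [GenomeSequence(f"c{i}", "ATG" * 30) for i in range(k)]

    def make(self, tmp_path, n_segs, per_file):
        cfg = DbBuildConfig(seg_len=10, overlap=2, per_file=per_file)
        segs = list(segment_genome({"chr1": "ACGT" * 400}, cfg))[:n_segs]
        assert len(segs) == n_segs
        return write_partitioned_fasta(segs, cfg, str(tmp_path))

    @pytest.mark.parametrize("n,per,files", [(6, 6, 1), (7, 6, 2), (13, 6, 3)])
    def test_file_count_is_ceiling(self, tmp_path, n, per, files):
        assert len(self.make(tmp_path, n, per)) == files == math.ceil(n / per)

    def test_zero_segments_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            write_partitioned_fasta([], DbBuildConfig(), str(tmp_path))

    def test_header_round_trip_reproduces_sequences(self, tmp_path, ref_fixture):
        """Parsing any header and re-slicing the frame translation of the
        genome reproduces the stored segment exactly."""
        chrom = "chr1"
        seq = ref_fixture.genome[chrom]
        cfg = DbBuildConfig(seg_len=200, overlap=20, per_file=1000)
        segs = list(segment_genome({chrom: seq}, cfg))
        paths = write_partitioned_fasta(segs, cfg, str(tmp_path))
        frames = translate_six_frames(seq)
        n = 0
        for path in paths:
            for header, aa in read_fasta(path):
                c, strand, frame, aa_start = parse_segment_header(header)
                assert c == chrom
                assert frames[(strand, frame)][aa_start:aa_start + len(aa)] == aa
                n += 1
        assert n == len(segs)


class TestDecoy:
    def test_single_residue_entry_unchanged(self):
        assert make_decoy([("h", "AAAA")], seed=1)[0][1] == "AAAA"

    def test_same_seed_is_deterministic(self):
        entries = [("a", "ACDEFGHIKL"), ("b", "MNPQRSTVWY")]
        assert make_decoy(entries, 9) == make_decoy(entries, 9)

    def test_frozen_permutation_for_reference_seed(self):
        # frozen from a seeded Fisher-Yates shuffle oracle (random.Random(42))
        (_, decoy), = make_decoy([("h", "ACDEFGHIKLMNPQRSTVWY")], seed=42)
        assert decoy == "YGRFLQSWHPVMCNDTIKAE"

    def test_composition_and_length_preserved(self):
        entries = [("x", "MKVLAWWPK"), ("y", "GG")]
        for (h0, s0), (h1, s1) in zip(entries, make_decoy(entries, 3)):
            assert len(s0) == len(s1) and sorted(s0) == sorted(s1)
            assert h1.startswith("decoy|")

    def test_empty_database_rejected(self):
        with pytest.raises(ValidationError):
            make_decoy([], 1)


class TestGenomicProjection:
    def test_forward_frame0_definition(self):
        from pgmap.models import SixFrameSegment
        seg = SixFrameSegment("c", "+", 0, 0, "MK*")
        assert segment_to_genomic(seg, 0, 2, chrom_len=9) == (0, 6, "+", 0)

    def test_forward_frame1_offset_arithmetic(self):
        from pgmap.models import SixFrameSegment
        seg = SixFrameSegment("c", "+", 1, 0, "XX")
        assert segment_to_genomic(seg, 1, 1, chrom_len=9) == (4, 7, "+", 1)

    def test_offset_out_of_range(self):
        from pgmap.models import SixFrameSegment
        seg = SixFrameSegment("c", "+", 0, 0, "MK")
        with pytest.raises(ValueError):
            segment_to_genomic(seg, 1, 2, chrom_len=9)

    def test_round_trip_on_random_windows(self):
        """Translating the projected interval on the stated strand/frame
        reproduces the peptide, for every strand and frame."""
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGT") for _ in range(3000))
        frames = translate_six_frames(seq)
        cfg = DbBuildConfig(seg_len=100, overlap=10, per_file=10_000)
        for seg in segment_genome({"c": seq}, cfg):
            if len(seg.aa_seq) < 8:
                continue
            off = rng.randrange(0, len(seg.aa_seq) - 7)
            pep = seg.aa_seq[off:off + 7]
            s, e, strand, frame = segment_to_genomic(seg, off, 7, len(seq))
            nt = seq[s:e] if strand == "+" else reverse_complement(seq[s:e])
            assert translate(nt) == pep
            assert frames[(strand, frame)][seg.aa_start + off:
                                           seg.aa_start + off + 7] == pep
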