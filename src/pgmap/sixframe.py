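"""Partitioned six-frame translation search databases.

A whole genome is far too large to search directly with a spectrum-matching
engine, and E-values are calibrated against database size, so the genome's
six conceptual translations are cut into overlapping amino-acid segments
(default 600 aa with a 60 aa overlap, so any peptide up to the overlap length
is contained intact in at least one segment) and grouped into FASTA files of
a fixed number of entries (default 50 000).  Segment headers encode
(chromosome, strand, frame, amino-acid offset) so every peptide match can be
projected back onto genome coordinates exactly.
"""

from __future__ import annotations

import math
import os
import random
from typing import Iterable, Iterator

from Bio.Data.CodonTable import standard_dna_table

from .models import DbBuildConfig, GenomeSequence, SixFrameSegment, ValidationError

_CODON = dict(standard_dna_table.forward_table)
_CODON.update({c: "*" for c in standard_dna_table.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FRAMES: tuple[tuple[str, int], ...] = (
    ("+", 0), ("+", 1), ("+", 2), ("-", 0), ("-", 1), ("-", 2))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate with the standard code; '*' for stops, 'X' for any codon
    that is not plain A/C/G/T (trailing partial codon dropped)."""
    return "".join(_CODON.get(nt[i:i + 3], "X")
                   for i in range(0, len(nt) - len(nt) % 3, 3))


def translate_six_frames(seq: GenomeSequence | str) -> dict[tuple[str, int], str]:
    """All six conceptual translations, keyed by (strand, frame).

    frame is the offset of the first translated base on the reading strand
    (the forward sequence for '+', the reverse complement for '-').
    """
    s = seq.sequence if isinstance(seq, GenomeSequence) else seq
    if not s:
        raise ValidationError("cannot translate an empty sequence")
    rc = reverse_complement(s)
    out = {}
    for strand, frame in FRAMES:
        src = s if strand == "+" else rc
        out[(strand, frame)] = translate(src[frame:])
    return out


def segment_frame(frame_aa: str, cfg: DbBuildConfig,
                  chrom_id: str = "", strand: str = "+",
                  frame: int = 0) -> list[SixFrameSegment]:
    """Cut one frame translation into overlapping segments.

    Starts step by seg_len - overlap; the final (possibly short) segment is
    emitted whenever it extends coverage, so every substring of length
    <= overlap occurs intact in at least one segment.
    """
    step = cfg.seg_len - cfg.overlap
    segments = []
    start = 0
    n = len(frame_aa)
    while True:
        end = min(start + cfg.seg_len, n)
        segments.append(SixFrameSegment(chrom_id=chrom_id, strand=strand,
                                        frame=frame, aa_start=start,
                                        aa_seq=frame_aa[start:end]))
        if end >= n:
            break
        start += step
    return segments


def segment_genome(genome: dict[str, str] | Iterable[GenomeSequence],
                   cfg: DbBuildConfig) -> Iterator[SixFrameSegment]:
    """All segments of all six frames of every chromosome, in stable order."""
    if isinstance(genome, dict):
        genome = [GenomeSequence(c, s) for c, s in genome.items()]
    for chrom in genome:
        frames = translate_six_frames(chrom)
        for strand, frame in FRAMES:
            yield from segment_frame(frames[(strand, frame)], cfg,
                                     chrom.chrom_id, strand, frame)


def parse_segment_header(header: str) -> tuple[str, str, int, int]:
    """Invert the ``sf|chrom|strand|frame|aa_start`` header grammar."""
    parts = header.split("|")
    if len(parts) != 5 or parts[0] != "sf":
        raise ValueError(f"not a six-frame segment header: {header!r}")
    _, chrom, strand, frame, aa_start = parts
    if strand not in "+-":
        raise ValueError(f"bad strand in header {header!r}")
    return chrom, strand, int(frame), int(aa_start)


def write_partitioned_fasta(segments: Iterable[SixFrameSegment],
                            cfg: DbBuildConfig, outdir: str,
                            prefix: str = "sixframe") -> list[str]:
    """Write segments into FASTA files of cfg.per_file entries each.

    Returns the list of file paths (``<prefix>_partNNN.fasta``).
    """
    segments = list(segments)
    if not segments:
        raise ValidationError("no segments to write")
    os.makedirs(outdir, exist_ok=True)
    n_files = math.ceil(len(segments) / cfg.per_file)
    paths = []
    for i in range(n_files):
        path = os.path.join(outdir, f"{prefix}_part{i + 1:03d}.fasta")
        with open(path, "w") as fh:
            for seg in segments[i * cfg.per_file:(i + 1) * cfg.per_file]:
                fh.write(f">{seg.header}\n{seg.aa_seq}\n")
        paths.append(path)
    return paths


def read_fasta(path: str) -> list[tuple[str, str]]:
    """(header, sequence) pairs of a FASTA file."""
    from Bio import SeqIO
    return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]


def make_decoy(entries: Iterable[tuple[str, str]], seed: int) -> list[tuple[str, str]]:
    """Randomized decoy database: an independent uniform permutation of the
    residues of each entry.  Length and residue multiset are preserved
    per entry; output is deterministic for a given seed."""
    entries = list(entries)
    if not entries:
        raise ValidationError("cannot build a decoy from zero entries")
    rng = random.Random(seed)
    out = []
    for header, seq in entries:
        residues = list(seq)
        rng.shuffle(residues)
        out.append((f"decoy|{header}", "".join(residues)))
    return out


def segment_to_genomic(seg: SixFrameSegment, pep_aa_offset: int, pep_len: int,
                       chrom_len: int) -> tuple[int, int, str, int]:
    """Project a peptide occurrence inside a segment onto genome coordinates.

    Returns (nt_start, nt_end, strand, frame), half-open on the forward
    strand.  Reverse-strand coordinates are mirrored from the chromosome end
    because frames are numbered on the reverse complement.
    """
    if pep_aa_offset < 0 or pep_aa_offset + pep_len > len(seg.aa_seq):
        raise ValueError("peptide offset/length outside segment")
    read_start = 3 * (seg.aa_start + pep_aa_offset) + seg.frame
    nt_len = 3 * pep_len
    if seg.strand == "+":
        return read_start, read_start + nt_len, "+", seg.frame
    nt_end = chrom_len - read_start
    return nt_end - nt_len, nt_end, "-", seg.frame


def frame_position_to_genomic(strand: str, frame: int, aa_pos: int,
                              aa_len: int, chrom_len: int) -> tuple[int, int]:
    """Genomic half-open interval of aa_len residues starting at amino-acid
    offset aa_pos of a full frame translation."""
    seg = SixFrameSegment(chrom_id="", strand=strand, frame=frame,
                          aa_start=aa_pos, aa_seq="X" * aa_len)
    s, e, _, _ = segment_to_genomic(seg, 0, aa_len, chrom_len)
    return s, e


def extract_peptide_nt(genome_seq: str, start: int, end: int, strand: str) -> str:
    """Reading-strand nucleotides of a genomic interval."""
    nt = genome_seq[start:end]
    return nt if strand == "+" else reverse_complement(nt)
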