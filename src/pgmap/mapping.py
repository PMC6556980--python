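"""Exact peptide-to-genome mapping via six-frame translation.

Peptides are located by exact string match inside the full-chromosome frame
translations (never the 600-aa search segments, so segment boundaries cannot
hide an occurrence).  Matching is literal character equality: a stop ('*')
in the translation can never equal a peptide residue, so matches are
stop-free by construction, and 'X' only matches an explicit 'X'.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .models import GenomeSequence, PeptideLocus
from .sixframe import FRAMES, frame_position_to_genomic, translate_six_frames


@dataclass
class MapResult:
    """Loci of every peptide plus the genome-wide locus count (0 allowed)."""

    loci: list[PeptideLocus]
    n_loci: dict[str, int]

    def unmapped(self) -> list[str]:
        return sorted(p for p, n in self.n_loci.items() if n == 0)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def map_peptides(peptides: Iterable[str],
                 genome: Mapping[str, str]) -> MapResult:
    """Every exact occurrence of every peptide in any of the six frames of
    any chromosome, with genome coordinates and total locus counts.
    """
    peptides = sorted(set(peptides))
    for p in peptides:
        if not p or "*" in p:
            raise ValueError(f"invalid peptide {p!r}")
    raw: list[tuple] = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        frames = translate_six_frames(GenomeSequence(chrom, seq))
        for strand, frame in FRAMES:
            aa = frames[(strand, frame)]
            for pep in peptides:
                for pos in _find_all(aa, pep):
                    s, e = frame_position_to_genomic(strand, frame, pos,
                                                     len(pep), len(seq))
                    raw.append((pep, chrom, strand, frame, s, e))
    counts = {p: 0 for p in peptides}
    for pep, *_ in raw:
        counts[pep] += 1
    loci = [PeptideLocus(peptide=pep, chrom=chrom, strand=strand, frame=frame,
                         start=s, end=e, n_loci_total=counts[pep])
            for pep, chrom, strand, frame, s, e in
            sorted(raw, key=lambda r: (r[0], r[1], r[4], r[5], r[2], r[3]))]
    return MapResult(loci=loci, n_loci=counts)


def filter_unique_locus(loci: Iterable[PeptideLocus]) -> list[PeptideLocus]:
    """Keep only peptides that map to exactly one genomic location."""
    return [l for l in loci if l.n_loci_total == 1]


def flag_annotated(peptides: Iterable[str],
                   protein_sets: Mapping[str, Mapping[str, str]]
                   ) -> tuple[dict[str, set[str]], set[str]]:
    """Partition peptides into annotated vs novel.

    A peptide is annotated iff it is an exact substring of any protein in
    any of the given sets (keyed by source label, e.g. the two annotation
    pipelines).  Returns (annotated peptide -> set of source labels, novel
    peptide set).
    """
    annotated: dict[str, set[str]] = {}
    peptides = sorted(set(peptides))
    for label, proteins in protein_sets.items():
        joined = "$".join(proteins.values())  # '$' never occurs in a peptide
        for pep in peptides:
            if pep in joined:
                annotated.setdefault(pep, set()).add(label)
    novel = {p for p in peptides if p not in annotated}
    return annotated, novel


def write_locus_bed(loci: Iterable[PeptideLocus], path: str) -> None:
    """BED-like TSV: chrom, start, end, peptide, n_loci_total, strand, frame."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tpeptide\tn_loci_total\tstrand\tframe\n")
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.peptide}\t"
                     f"{l.n_loci_total}\t{l.strand}\t{l.frame}\n")
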