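"""Core domain types for the proteogenomic toolkit.

Coordinate convention: every interval held in memory is 0-based, half-open,
on the forward genome strand.  GFF3/GTF (1-based, inclusive) are converted at
parse and write boundaries only.  5'/3' always refer to the transcript's own
orientation, so on the minus strand "5'" means genomically rightmost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

Interval = tuple[int, int]

VALID_NT = set("ACGTN")
AA_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


class ValidationError(ValueError):
    """Raised when a parsed object violates a structural invariant."""


def _check_sorted_disjoint(ivs: list[Interval], what: str) -> None:
    for (s, e) in ivs:
        if not (0 <= s < e):
            raise ValidationError(f"{what}: empty or negative interval [{s},{e})")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValidationError(f"{what}: intervals overlap or are unsorted: "
                                  f"[{s1},{e1}) vs [{s2},{e2})")


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted disjoint list."""
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Intersection of two interval lists (each assumed sorted disjoint)."""
    out = []
    a, b = list(a), list(b)
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> list[Interval]:
    """Set difference a \\ b, both sorted disjoint."""
    out = []
    b = list(b)
    for s, e in a:
        cur = s
        for bs, be in b:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def span_len(ivs: Iterable[Interval]) -> int:
    return sum(e - s for s, e in ivs)


@dataclass
class GenomeSequence:
    """A single chromosome/contig: uppercase A, C, G, T, N."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.chrom_id}: empty sequence")
        bad = set(self.sequence) - VALID_NT
        if bad:
            raise ValidationError(f"{self.chrom_id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Transcript:
    """A transcript as a set of exon intervals plus optional CDS intervals.

    biotype is derived: coding iff cds is non-empty.
    """

    id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    gene_id: str = ""
    # Explicit UTR features from annotation dialects that carry them; when
    # non-empty they override exon-minus-CDS derivation.
    explicit_utr5: list[Interval] = field(default_factory=list)
    explicit_utr3: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.id}: strand must be '+' or '-'")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        if not self.exons:
            raise ValidationError(f"{self.id}: transcript has no exons")
        _check_sorted_disjoint(self.exons, f"{self.id} exons")
        _check_sorted_disjoint(self.cds, f"{self.id} CDS")
        # CDS must be a subset of the exon union
        if self.cds:
            leftover = subtract_intervals(self.cds, self.exons)
            if leftover:
                raise ValidationError(f"{self.id}: CDS outside exons at {leftover}")

    @property
    def biotype(self) -> str:
        return "coding" if self.cds else "noncoding"

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[Interval]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def intron_chain(self) -> tuple[Interval, ...]:
        return tuple(self.introns())


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (min(t.start for t in self.transcripts),
                max(t.end for t in self.transcripts))


@dataclass
class GeneSet:
    """A collection of genes from one annotation source."""

    genes: list[Gene] = field(default_factory=list)
    source_label: str = ""

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes:
            yield from g.transcripts

    def __len__(self) -> int:
        return len(self.genes)

    def validate(self) -> None:
        for g in self.genes:
            if not g.transcripts:
                raise ValidationError(f"gene {g.id} has no transcripts")
            for t in g.transcripts:
                if t.chrom != g.chrom:
                    raise ValidationError(f"{t.id}: chrom differs from parent gene")


@dataclass
class RegionSet:
    """Derived functional regions of one transcript.

    cds_frames maps each CDS block to the reading-frame phase (0/1/2) of its
    5'-most base, walking the CDS 5'->3' in transcript orientation; phase()
    resolves the phase of any individual CDS base.
    """

    transcript: Transcript
    introns: list[Interval]
    utr5: list[Interval]
    utr3: list[Interval]
    cds_frames: list[tuple[int, int, int]]  # (start, end, phase at 5'-most base)

    def phase(self, pos: int) -> int | None:
        """Reading-frame phase of genomic position pos, or None if not CDS."""
        for s, e, p0 in self.cds_frames:
            if s <= pos < e:
                if self.transcript.strand == "+":
                    return (p0 + (pos - s)) % 3
                return (p0 + (e - 1 - pos)) % 3
        return None


@dataclass(frozen=True)
class SixFrameSegment:
    """A window of one frame's conceptual translation.

    frame is the offset (0/1/2) of the first translated base counted on the
    reading strand: the forward sequence for '+', the reverse complement
    for '-'.  aa_start is the 0-based amino-acid offset of this window within
    the full frame translation, which makes genome coordinates recoverable.
    """

    chrom_id: str
    strand: str
    frame: int
    aa_start: int
    aa_seq: str

    @property
    def header(self) -> str:
        return f"sf|{self.chrom_id}|{self.strand}|{self.frame}|{self.aa_start}"


@dataclass
class DbBuildConfig:
    """Parameters of the partitioned six-frame search database."""

    seg_len: int = 600
    overlap: int = 60
    per_file: int = 50_000
    decoy_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.seg_len):
            raise ValidationError("require 0 <= overlap < seg_len")
        if self.per_file < 1:
            raise ValidationError("per_file must be >= 1")


@dataclass
class PSM:
    """One peptide-spectrum match as emitted by a search engine."""

    spectrum_id: str
    peptide: str
    evalue: float
    engine: str
    search_space: str  # {protein, genome}
    partition: str
    is_decoy: bool
    tissue: str

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValidationError(f"{self.spectrum_id}: E-value must be > 0")
        if not self.peptide or "*" in self.peptide:
            raise ValidationError(f"{self.spectrum_id}: invalid peptide {self.peptide!r}")


@dataclass
class PeptideHit:
    """Peptide-level aggregate of accepted PSMs within one tissue."""

    peptide: str
    tissue: str
    spectra: set[str]
    engines: set[str]
    best_evalue: float
    is_decoy: bool = False

    @property
    def n_spectra(self) -> int:
        return len(self.spectra)


@dataclass(frozen=True)
class PeptideLocus:
    """One exact genomic placement of a peptide via six-frame translation."""

    peptide: str
    chrom: str
    strand: str
    frame: int
    start: int
    end: int
    n_loci_total: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start != 3 * len(self.peptide):
            raise ValidationError(
                f"{self.peptide}: interval length {self.end - self.start} "
                f"!= 3 x peptide length")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)
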