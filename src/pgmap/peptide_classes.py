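"""Annotation-relative classification of novel single-locus peptides.

Each peptide locus is placed into exactly one of ten categories per
annotation set, by the first matching rule in a fixed priority order
(most CDS-proximal wins):

  coding_out_of_frame > nter_extension > cter_extension > utr5 > utr3
  > exon5_extension > exon3_extension > transcript_noncoding > intron
  > intergenic

Only same-strand gene overlap counts; a peptide antisense to every
overlapping gene is intergenic.  Classifying the same loci against two
independent annotation sets yields a cross-tabulated novelty summary
(per category: both sets agree on the category / first set only / second
set only, with row percentages and grand totals).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .annotation import IntervalIndex, derive_regions
from .models import (GeneSet, PeptideLocus, RegionSet, Transcript,
                     intersect_intervals, subtract_intervals)

CATEGORIES = (
    "coding_out_of_frame",
    "nter_extension",
    "cter_extension",
    "utr5",
    "utr3",
    "exon5_extension",
    "exon3_extension",
    "transcript_noncoding",
    "intron",
    "intergenic",
)
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}

# Display order of the summary table (generic last row = intergenic first,
# as the field's reports usually lead with the dominant class).
TABLE_ORDER = (
    "intergenic", "intron", "transcript_noncoding", "coding_out_of_frame",
    "nter_extension", "cter_extension", "utr5", "utr3",
    "exon5_extension", "exon3_extension",
)


def round_half_up(x: float | Decimal, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


class AnnotationIndex:
    """A GeneSet with derived regions and an interval index, ready for
    repeated classification queries."""

    def __init__(self, gs: GeneSet):
        self.geneset = gs
        self.index = IntervalIndex(gs)
        self.regions: dict[str, RegionSet] = {
            t.id: derive_regions(t) for t in gs.transcripts()}


def _pep_phase(locus: PeptideLocus, pos: int) -> int:
    """Reading-frame phase of genomic position pos within the peptide's own
    codon grid (phase counted 5'->3' along the peptide)."""
    if locus.strand == "+":
        return (pos - locus.start) % 3
    return (locus.end - 1 - pos) % 3


def _transcript_categories(locus: PeptideLocus, t: Transcript,
                           r: RegionSet) -> set[str]:
    """All category rules this transcript satisfies for the locus."""
    cats: set[str] = set()
    s, e = locus.start, locus.end
    iv = [(s, e)]

    if t.cds:
        cds_len = sum(be - bs for bs, be in t.cds)
        overlapping = intersect_intervals(iv, t.cds)
        if overlapping:
            # phase offset is constant within a CDS block, so one base per
            # block decides in-frame vs out-of-frame for the whole block
            in_frame = all(_pep_phase(locus, bs) == r.phase(bs)
                           for bs, _ in overlapping)
            if not in_frame:
                cats.add("coding_out_of_frame")
        c0, c1 = t.cds[0][0], t.cds[-1][1]
        if t.strand == "+":
            if s < c0 <= e and (c0 - s) % 3 == 0:
                cats.add("nter_extension")
            if s <= c1 < e and (c1 - s) % 3 == cds_len % 3:
                cats.add("cter_extension")
        else:
            if s <= c1 < e and (e - c1) % 3 == 0:
                cats.add("nter_extension")
            if s < c0 <= e and (e - c0) % 3 == cds_len % 3:
                cats.add("cter_extension")
        if not subtract_intervals(iv, r.utr5):
            cats.add("utr5")
        if not subtract_intervals(iv, r.utr3):
            cats.add("utr3")

    five_end = t.start if t.strand == "+" else t.end
    three_end = t.end if t.strand == "+" else t.start
    if s < five_end < e:
        cats.add("exon5_extension")
    if s < three_end < e:
        cats.add("exon3_extension")

    if t.biotype == "noncoding" and not subtract_intervals(iv, t.exons):
        cats.add("transcript_noncoding")
    if intersect_intervals(iv, r.introns):
        cats.add("intron")
    return cats


def classify_peptide(locus: PeptideLocus, ann: AnnotationIndex | GeneSet) -> str:
    """Category of a single-locus peptide relative to one annotation set."""
    if isinstance(ann, GeneSet):
        ann = AnnotationIndex(ann)
    hits = ann.index.query(locus.chrom, locus.start, locus.end,
                           strand=locus.strand, mode="same")
    if not hits:
        return "intergenic"
    cats: set[str] = set()
    for t in hits:
        cats |= _transcript_categories(locus, t, ann.regions[t.id])
    if not cats:
        # inside a gene span but matching no specific rule (e.g. an exonic
        # in-frame overlap that upstream filtering should have removed):
        # fall back to the least specific genic call
        return "intron"
    return min(cats, key=_PRIORITY.__getitem__)


def classify_against_two(locus: PeptideLocus, ann_a: AnnotationIndex | GeneSet,
                         ann_b: AnnotationIndex | GeneSet) -> tuple[str, str]:
    """Independent classification against each of two annotation sets."""
    return classify_peptide(locus, ann_a), classify_peptide(locus, ann_b)


@dataclass
class NoveltySummary:
    """Cross-annotation novelty cross-tab.

    Per category: ``both`` = peptides assigned that category by both sets,
    ``a_only`` / ``b_only`` = by exactly one set; row total and row
    percentages (half-up, 1 decimal); grand totals per column.
    """

    counts: dict[str, tuple[int, int, int]]
    label_a: str = "A"
    label_b: str = "B"

    def row_total(self, cat: str) -> int:
        return sum(self.counts.get(cat, (0, 0, 0)))

    def percentages(self, cat: str) -> tuple[float, float, float]:
        both, a, b = self.counts.get(cat, (0, 0, 0))
        tot = both + a + b
        if tot == 0:
            return (0.0, 0.0, 0.0)
        return tuple(round_half_up(Decimal(100 * n) / Decimal(tot), 1)
                     for n in (both, a, b))

    @property
    def column_totals(self) -> tuple[int, int, int]:
        cols = [0, 0, 0]
        for cat in CATEGORIES:
            for i, n in enumerate(self.counts.get(cat, (0, 0, 0))):
                cols[i] += n
        return tuple(cols)

    @property
    def grand_total(self) -> int:
        return sum(self.column_totals)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in TABLE_ORDER:
            both, a, b = self.counts.get(cat, (0, 0, 0))
            pb, pa, pb2 = self.percentages(cat)
            rows.append({"category": cat, "both": both,
                         f"{self.label_a}_only": a, f"{self.label_b}_only": b,
                         "total": self.row_total(cat),
                         "pct_both": pb, f"pct_{self.label_a}": pa,
                         f"pct_{self.label_b}": pb2})
        cb, ca, cb2 = self.column_totals
        rows.append({"category": "total", "both": cb,
                     f"{self.label_a}_only": ca, f"{self.label_b}_only": cb2,
                     "total": self.grand_total,
                     "pct_both": float("nan"),
                     f"pct_{self.label_a}": float("nan"),
                     f"pct_{self.label_b}": float("nan")})
        return pd.DataFrame(rows)

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int, int]],
                    **kw) -> "NoveltySummary":
        unknown = set(counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        return cls(counts=dict(counts), **kw)


def summarize_novelty(pairs: Iterable[tuple[str, str]],
                     label_a: str = "A", label_b: str = "B") -> NoveltySummary:
    """Build the cross-annotation summary from (category_A, category_B) pairs.

    A peptide counts in a category's ``both`` column when the two sets agree
    on that category; otherwise it contributes to the ``a_only`` column of
    its A category and the ``b_only`` column of its B category.
    """
    counts = {c: [0, 0, 0] for c in CATEGORIES}
    for ca, cb in pairs:
        if ca not in _PRIORITY or cb not in _PRIORITY:
            raise ValueError(f"unknown category in pair ({ca!r}, {cb!r})")
        if ca == cb:
            counts[ca][0] += 1
        else:
            counts[ca][1] += 1
            counts[cb][2] += 1
    return NoveltySummary(counts={c: tuple(v) for c, v in counts.items()},
                          label_a=label_a, label_b=label_b)


def classify_all(loci: Sequence[PeptideLocus], ann_a: GeneSet | AnnotationIndex,
                 ann_b: GeneSet | AnnotationIndex) -> list[tuple[PeptideLocus, str, str]]:
    if isinstance(ann_a, GeneSet):
        ann_a = AnnotationIndex(ann_a)
    if isinstance(ann_b, GeneSet):
        ann_b = AnnotationIndex(ann_b)
    return [(l, *classify_against_two(l, ann_a, ann_b)) for l in loci]
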