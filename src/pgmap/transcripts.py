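"""Classification of assembled transcripts against reference gene models,
novel-transcript (CXT) identifiers, exon/tissue-specificity statistics and
coordinate-based miRNA name transfer.

Transcript-model identity is anchored on splice junctions: two transcripts
match when their ordered intron chains are identical (terminal-exon ends may
differ freely, since annotations are routinely missing true 5'/3' termini).
A transcript that shares structure with a model but has a different chain is
a novel isoform, refined to a pure 5'- or 3'-end difference when the chains
align contiguously and differ on one side only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import pandas as pd

from .annotation import IntervalIndex
from .models import (GeneSet, Interval, Transcript, intersect_intervals,
                     subtract_intervals)
from .peptide_classes import round_half_up

TRANSCRIPT_CATEGORIES = (
    "matches_annotated",
    "novel_isoform",
    "five_prime_difference",
    "three_prime_difference",
    "intronic",
    "intergenic",
)

NOVEL_CATEGORIES = TRANSCRIPT_CATEGORIES[1:]


def _chain_side_diff(ct: tuple[Interval, ...], cr: tuple[Interval, ...]
                     ) -> tuple[str, list[Interval]] | None:
    """(side, extra introns) when one chain is a contiguous sub-chain of the
    other with extra introns on a single genomic side; None otherwise."""
    if not ct or not cr:
        return None
    short, long_ = (ct, cr) if len(ct) <= len(cr) else (cr, ct)
    for off in range(len(long_) - len(short) + 1):
        if tuple(long_[off:off + len(short)]) == tuple(short):
            leading, trailing = off > 0, off + len(short) < len(long_)
            if leading and trailing:
                return None
            if leading:
                return "left", list(long_[:off])
            if trailing:
                return "right", list(long_[off + len(short):])
    return None


def classify_transcript(tx: Transcript, gs: GeneSet | IntervalIndex) -> str:
    """One of the six transcript categories, relative to one reference set."""
    index = gs if isinstance(gs, IntervalIndex) else IntervalIndex(gs)
    refs = index.query(tx.chrom, tx.start, tx.end, strand=tx.strand,
                       mode="same")
    if not refs:
        return "intergenic"

    chain_t = tx.intron_chain()
    if chain_t:
        if any(r.intron_chain() == chain_t for r in refs):
            return "matches_annotated"
    else:
        # single-exon vs single-exon: compared by exon overlap, no chains
        if any(r.n_exons == 1 and
               intersect_intervals(tx.exons, r.exons) for r in refs):
            return "matches_annotated"

    shared = [r for r in refs
              if (set(chain_t) & set(r.intron_chain()))
              or intersect_intervals(tx.exons, r.exons)]
    if shared:
        sides = set()
        for r in shared:
            if not (set(chain_t) & set(r.intron_chain())):
                sides.add("mixed")
                continue
            diff = _chain_side_diff(chain_t, r.intron_chain())
            if diff is None:
                sides.add("mixed")
                continue
            side, extras = diff
            # a pure end difference requires the extra introns to lie
            # outside the span of the transcript that lacks them; an extra
            # intron inside the other model's body is an isoform change
            other_lo = max(tx.start, r.start)
            other_hi = min(tx.end, r.end)
            if side == "left" and all(e <= other_lo for _, e in extras):
                sides.add("left")
            elif side == "right" and all(s >= other_hi for s, _ in extras):
                sides.add("right")
            else:
                sides.add("mixed")
        if sides == {"left"}:
            return ("five_prime_difference" if tx.strand == "+"
                    else "three_prime_difference")
        if sides == {"right"}:
            return ("three_prime_difference" if tx.strand == "+"
                    else "five_prime_difference")
        return "novel_isoform"

    for r in refs:
        introns = r.introns()
        if introns and not subtract_intervals(tx.exons, introns):
            return "intronic"
    # span overlap without exonic contact or intron containment
    if any(intersect_intervals(tx.exons, [r.span]) for r in refs):
        return "novel_isoform"
    return "intergenic"


def classify_transcripts(txs: Iterable[Transcript],
                         gs: GeneSet | IntervalIndex) -> dict[str, str]:
    index = gs if isinstance(gs, IntervalIndex) else IntervalIndex(gs)
    return {t.id: classify_transcript(t, index) for t in txs}


def assign_cxt_ids(novel_txs: Iterable[Transcript],
                   prefix: str = "CXT") -> dict[str, str]:
    """Deterministic ``CXT.N`` identifiers in (chrom, start, end) order.

    Stable across reruns and input shuffles.
    """
    ordered = sorted(novel_txs, key=lambda t: (t.chrom, t.start, t.end, t.id))
    return {t.id: f"{prefix}.{i + 1}" for i, t in enumerate(ordered)}


def exon_stats(txs: Sequence[Transcript],
               grouping: Mapping[str, str] | None = None) -> dict[str, float]:
    """Mean exons per transcript, per group (1-decimal reporting).

    ``grouping`` maps transcript id -> group label; transcripts without a
    label go to 'all'.  Groups that end up empty are omitted with a warning.
    """
    grouping = grouping or {}
    groups: dict[str, list[int]] = {}
    for t in txs:
        groups.setdefault(grouping.get(t.id, "all"), []).append(t.n_exons)
    wanted = set(grouping.values()) or {"all"}
    for g in sorted(wanted - set(groups)):
        warnings.warn(f"exon_stats: group {g!r} has no transcripts; omitted")
    return {g: round_half_up(sum(v) / len(v), 1)
            for g, v in sorted(groups.items())}


@dataclass
class TissueSpecificity:
    """Distribution of the number of tissues each product was detected in."""

    histogram: dict[int, int]
    n_products: int

    @property
    def fraction_single(self) -> float:
        return self.histogram.get(1, 0) / self.n_products

    @property
    def pct_single(self) -> float:
        return round_half_up(100 * self.fraction_single, 1)


def presence_matrix(abundance: pd.DataFrame,
                    threshold: float = 0.0) -> pd.DataFrame:
    """Boolean detection matrix from a product-by-tissue abundance table.

    A product is detected in a tissue when abundance > threshold (default 0;
    the cutoff is a user decision, not baked in).  Rows detected nowhere are
    rejected.
    """
    if abundance.shape[1] < 1:
        raise ValueError("presence matrix needs at least one tissue column")
    m = abundance > threshold
    empty = m.index[~m.any(axis=1)]
    if len(empty):
        raise ValueError(f"products detected in no tissue: {list(empty[:5])}...")
    return m


def tissue_specificity(matrix: pd.DataFrame) -> TissueSpecificity:
    """Histogram of #tissues per product and the single-tissue fraction."""
    if matrix.shape[1] < 1:
        raise ValueError("presence matrix needs at least one tissue column")
    per_product = matrix.sum(axis=1).astype(int)
    if (per_product == 0).any():
        raise ValueError("presence matrix rows with all-false cells are not allowed")
    hist = per_product.value_counts().sort_index()
    return TissueSpecificity(histogram={int(k): int(v) for k, v in hist.items()},
                             n_products=int(len(per_product)))


# ------------------------------------------------------------------ miRNA

@dataclass(frozen=True)
class NamedInterval:
    name: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class MirnaAssignment:
    prediction: NamedInterval
    name: str
    source: str  # mature | primary | novel


def transfer_mirna_names(predicted: Sequence[NamedInterval],
                         known_mature: Sequence[NamedInterval],
                         known_primary: Sequence[NamedInterval],
                         mature_tolerance: int = 5,
                         novel_prefix: str = "novel-mir") -> list[MirnaAssignment]:
    """Transfer known miRNA names onto predictions by coordinate.

    A prediction takes a known mature miR's name when both interval ends are
    within ``mature_tolerance`` nucleotides (same chrom and strand); among
    several qualifying matures the nearest by |dstart|+|dend| wins, ties by
    lexicographic name.  Failing that, any >= 1 bp overlap with a known
    primary transcript transfers the primary's name (largest overlap, ties
    lexicographic).  Everything else keeps a novel identifier, numbered in
    coordinate order.
    """
    out: list[MirnaAssignment] = []
    novel: list[int] = []
    for i, p in enumerate(predicted):
        matures = [(abs(p.start - k.start) + abs(p.end - k.end), k.name)
                   for k in known_mature
                   if k.chrom == p.chrom and k.strand == p.strand
                   and abs(p.start - k.start) <= mature_tolerance
                   and abs(p.end - k.end) <= mature_tolerance]
        if matures:
            out.append(MirnaAssignment(p, min(matures)[1], "mature"))
            continue
        primaries = [(-(min(p.end, k.end) - max(p.start, k.start)), k.name)
                     for k in known_primary
                     if k.chrom == p.chrom and k.strand == p.strand
                     and min(p.end, k.end) - max(p.start, k.start) >= 1]
        if primaries:
            out.append(MirnaAssignment(p, min(primaries)[1], "primary"))
            continue
        out.append(MirnaAssignment(p, "", "novel"))
        novel.append(i)
    order = sorted(novel, key=lambda i: (predicted[i].chrom, predicted[i].start,
                                         predicted[i].end, predicted[i].name))
    for n, i in enumerate(order):
        out[i].name = f"{novel_prefix}-{n + 1}"
    return out
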