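"""Parsing reference annotations into strand-aware gene models.

Two annotation dialects are supported, mirroring the two gene-prediction
pipelines commonly used for the same genome:

* ``ncbi-like``  — gene/mRNA/exon/CDS features; UTRs derived as exon - CDS.
* ``ensembl-like`` — additionally carries explicit five_prime_UTR /
  three_prime_UTR features, which take precedence over derivation.

All parsing goes through gffutils; coordinates are converted to 0-based
half-open on the way in and back to 1-based inclusive on the way out.
"""

from __future__ import annotations

import os
from collections import defaultdict

import gffutils
from intervaltree import IntervalTree

from .models import (Gene, GeneSet, Interval, RegionSet, Transcript,
                     ValidationError, merge_intervals, subtract_intervals)

DIALECTS = ("ncbi-like", "ensembl-like")
_TX_TYPES = ("mRNA", "transcript")


class ParseError(ValueError):
    """Raised when an annotation file is structurally malformed."""


def _nonempty(path: str) -> bool:
    with open(path) as fh:
        return any(line.strip() and not line.startswith("#") for line in fh)


def parse_gff3(path: str, dialect: str = "ncbi-like") -> GeneSet:
    """Parse a GFF3 file into a :class:`GeneSet`.

    Parameters
    ----------
    path:
        GFF3 file with gene / mRNA-or-transcript / exon / CDS features and
        ``Parent`` links.
    dialect:
        ``ncbi-like`` or ``ensembl-like``; only the latter honours explicit
        UTR features.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not _nonempty(path):
        return GeneSet(genes=[], source_label=dialect)
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    _check_orphan_parents(db)

    genes: list[Gene] = []
    for gf in db.features_of_type("gene", order_by="start"):
        gene = Gene(id=gf.id, chrom=gf.seqid, strand=gf.strand)
        for tf in db.children(gf, level=1):
            if tf.featuretype not in _TX_TYPES:
                continue
            tx_bounds = (tf.start - 1, tf.end)
            exons, cds, u5, u3 = [], [], [], []
            for child in db.children(tf, level=1):
                iv = (child.start - 1, child.end)
                if child.featuretype == "exon":
                    if iv[0] < tx_bounds[0] or iv[1] > tx_bounds[1]:
                        raise ValidationError(
                            f"exon {iv} outside transcript {tf.id} bounds {tx_bounds}")
                    exons.append(iv)
                elif child.featuretype == "CDS":
                    cds.append(iv)  # GFF3 phase column ignored; recomputed
                elif child.featuretype == "five_prime_UTR":
                    u5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    u3.append(iv)
            if not exons:
                continue
            tx = Transcript(id=tf.id, chrom=tf.seqid, strand=tf.strand,
                            exons=exons, cds=cds, gene_id=gf.id)
            if dialect == "ensembl-like":
                tx.explicit_utr5 = sorted(u5)
                tx.explicit_utr3 = sorted(u3)
            gene.transcripts.append(tx)
        if gene.transcripts:
            genes.append(gene)
    gs = GeneSet(genes=genes, source_label=dialect)
    gs.validate()
    return gs


def _check_orphan_parents(db: gffutils.FeatureDB) -> None:
    known = {f.id for f in db.all_features()}
    for f in db.all_features():
        for pid in f.attributes.get("Parent", []):
            if pid not in known:
                raise ParseError(
                    f"feature {f.id or f.featuretype} at {f.seqid}:{f.start} "
                    f"references unknown Parent {pid!r}")


def parse_gtf(path: str) -> GeneSet:
    """Parse assembled-transcript GTF (exon features only) into a GeneSet.

    Transcripts are grouped by ``gene_id``; no CDS is expected.
    """
    if not _nonempty(path):
        return GeneSet(genes=[], source_label="gtf")
    db = gffutils.create_db(path, ":memory:", force_gff=False,
                            disable_infer_genes=True,
                            disable_infer_transcripts=True,
                            merge_strategy="create_unique", keep_order=True)
    by_tx: dict[str, list] = defaultdict(list)
    tx_meta: dict[str, tuple[str, str, str]] = {}
    for f in db.features_of_type("exon", order_by="start"):
        tids = f.attributes.get("transcript_id", [])
        if not tids:
            raise ParseError(f"exon at {f.seqid}:{f.start} lacks transcript_id")
        gids = f.attributes.get("gene_id", [""])
        tid = tids[0]
        by_tx[tid].append((f.start - 1, f.end))
        tx_meta[tid] = (f.seqid, f.strand, gids[0] or tid)

    by_gene: dict[str, list[Transcript]] = defaultdict(list)
    for tid, exons in by_tx.items():
        chrom, strand, gid = tx_meta[tid]
        by_gene[gid].append(Transcript(id=tid, chrom=chrom, strand=strand,
                                       exons=exons, gene_id=gid))
    genes = [Gene(id=gid, chrom=txs[0].chrom, strand=txs[0].strand,
                  transcripts=sorted(txs, key=lambda t: (t.start, t.end, t.id)))
             for gid, txs in sorted(by_gene.items())]
    gs = GeneSet(genes=genes, source_label="gtf")
    gs.validate()
    return gs


def derive_regions(t: Transcript) -> RegionSet:
    """Derive introns, UTRs and CDS reading-frame phases for one transcript.

    Introns are the gaps between consecutive exons.  For coding transcripts
    the exonic sequence 5' of the CDS (in transcript orientation) is the
    5' UTR, and symmetrically for the 3' UTR; explicit UTR features on the
    transcript override the derivation.  Frame phase is assigned 0,1,2,...
    walking the concatenated CDS 5'->3' in transcript orientation.
    """
    introns = t.introns()
    if not t.cds:
        return RegionSet(t, introns, [], [], [])

    cds_min = t.cds[0][0]
    cds_max = t.cds[-1][1]
    utr_all = subtract_intervals(merge_intervals(t.exons), t.cds)
    left = [iv for iv in utr_all if iv[1] <= cds_min]
    right = [iv for iv in utr_all if iv[0] >= cds_max]
    if t.strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right, left
    if t.explicit_utr5:
        utr5 = list(t.explicit_utr5)
    if t.explicit_utr3:
        utr3 = list(t.explicit_utr3)

    blocks = t.cds if t.strand == "+" else list(reversed(t.cds))
    frames = []
    acc = 0
    for s, e in blocks:
        frames.append((s, e, acc % 3))
        acc += e - s
    frames.sort()
    return RegionSet(t, introns, utr5, utr3, frames)


class IntervalIndex:
    """Fast transcript-overlap lookup over one or two gene sets.

    Answers are required to be identical to a brute-force scan of all
    transcript spans; the tree is purely an acceleration structure.
    """

    def __init__(self, gs: GeneSet):
        self.geneset = gs
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for tx in gs.transcripts():
            self._trees[tx.chrom].addi(tx.start, tx.end, tx)

    def query(self, chrom: str, start: int, end: int,
              strand: str | None = None, mode: str = "any") -> list[Transcript]:
        """Transcripts whose span overlaps [start, end) on ``chrom``.

        mode: 'any' ignores strand; 'same'/'opposite' filter relative to the
        ``strand`` argument.  Unknown chromosomes yield an empty list.
        """
        if mode not in ("any", "same", "opposite"):
            raise ValueError(f"unknown strand mode {mode!r}")
        if mode != "any" and strand not in ("+", "-"):
            raise ValueError("strand required for same/opposite mode")
        hits = [iv.data for iv in self._trees.get(chrom, IntervalTree()).overlap(start, end)]
        if mode == "same":
            hits = [t for t in hits if t.strand == strand]
        elif mode == "opposite":
            hits = [t for t in hits if t.strand != strand]
        return sorted(hits, key=lambda t: (t.start, t.end, t.id))


def build_interval_index(gs: GeneSet) -> IntervalIndex:
    return IntervalIndex(gs)


# ---------------------------------------------------------------- writers

def _gff3_attrs(**kv: str) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items() if v)


def write_gff3(gs: GeneSet, path: str, explicit_utrs: bool = False) -> None:
    """Write a GeneSet as GFF3 (1-based inclusive on the way out).

    With ``explicit_utrs`` the derived UTRs are emitted as
    five_prime_UTR/three_prime_UTR features (ensembl-like dialect).
    """
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(gs.genes, key=lambda g: (g.chrom, g.span)):
            gs_, ge_ = g.span
            fh.write(f"{g.chrom}\tpgmap\tgene\t{gs_ + 1}\t{ge_}\t.\t{g.strand}\t.\t"
                     f"{_gff3_attrs(ID=g.id)}\n")
            for t in g.transcripts:
                ftype = "mRNA" if t.cds else "transcript"
                fh.write(f"{t.chrom}\tpgmap\t{ftype}\t{t.start + 1}\t{t.end}\t.\t"
                         f"{t.strand}\t.\t{_gff3_attrs(ID=t.id, Parent=g.id)}\n")
                for s, e in t.exons:
                    fh.write(f"{t.chrom}\tpgmap\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                             f"{_gff3_attrs(Parent=t.id)}\n")
                regions = derive_regions(t)
                for (s, e, p0) in regions.cds_frames:
                    # GFF3 phase = bases to skip to reach a codon start
                    phase = (3 - p0) % 3
                    fh.write(f"{t.chrom}\tpgmap\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t"
                             f"{phase}\t{_gff3_attrs(Parent=t.id)}\n")
                if explicit_utrs and t.cds:
                    for s, e in regions.utr5:
                        fh.write(f"{t.chrom}\tpgmap\tfive_prime_UTR\t{s + 1}\t{e}\t.\t"
                                 f"{t.strand}\t.\t{_gff3_attrs(Parent=t.id)}\n")
                    for s, e in regions.utr3:
                        fh.write(f"{t.chrom}\tpgmap\tthree_prime_UTR\t{s + 1}\t{e}\t.\t"
                                 f"{t.strand}\t.\t{_gff3_attrs(Parent=t.id)}\n")


def write_gtf(gs: GeneSet, path: str) -> None:
    """Write exon-level GTF (assembled-transcript style)."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        for g in sorted(gs.genes, key=lambda g: (g.chrom, g.span)):
            for t in g.transcripts:
                for s, e in t.exons:
                    attrs = f'gene_id "{t.gene_id or g.id}"; transcript_id "{t.id}";'
                    fh.write(f"{t.chrom}\tpgmap\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                             f"{attrs}\n")
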