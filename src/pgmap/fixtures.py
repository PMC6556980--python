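"""Self-contained synthetic inputs with ground-truth labels.

The generator emulates the study conditions of a dual-annotation
proteogenomic survey at desk scale: a small random genome (default two
50 kb chromosomes), ten-ish genes with exons/introns/CDS/UTRs, a second
annotation dialect derived from the first by controlled edits (dropped
genes, trimmed termini, explicit UTR features), peptides planted so that
their unique genomic locus satisfies exactly one classification rule,
simulated PSM tables with known accept/reject outcomes, assembled
transcripts covering every transcript category, and a presence matrix with
a known single-tissue fraction.  Everything is reproducible from
(seed, parameters) alone.
"""

from __future__ import annotations

import copy
import json
import os
import random
from dataclasses import dataclass, field

import pandas as pd

from .annotation import derive_regions, write_gff3, write_gtf
from .mapping import _find_all
from .models import (AA_RESIDUES, Gene, GeneSet, GenomeSequence, Interval,
                     Transcript, intersect_intervals, merge_intervals,
                     subtract_intervals)
from .psm import PSM_COLUMNS
from .sixframe import FRAMES, reverse_complement, translate, translate_six_frames
from .transcripts import NamedInterval

_NON_STOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"}
    - {"TAA", "TAG", "TGA"})

PEPTIDE_CATEGORY_DEFAULTS = {
    "intergenic": 6, "intron": 6, "transcript_noncoding": 4,
    "coding_out_of_frame": 4, "nter_extension": 3, "cter_extension": 3,
    "utr5": 3, "utr3": 3, "exon5_extension": 3, "exon3_extension": 3,
}

TISSUES = ["adipose", "cerebellum", "heart", "kidney", "liver", "lung",
           "muscle", "spleen"]


class FixtureError(RuntimeError):
    pass


@dataclass
class ReferenceFixture:
    seed: int
    genome: dict[str, str]
    ann_a: GeneSet
    ann_b: GeneSet
    proteins_a: dict[str, str]
    proteins_b: dict[str, str]
    truth: dict = field(default_factory=dict)


@dataclass
class PlantedPeptide:
    peptide: str
    chrom: str
    strand: str
    frame: int
    start: int
    end: int
    category: str
    annotation: str
    n_loci: int = 1


class _FrameCache:
    """Cached six-frame translations for genome-wide occurrence counting."""

    def __init__(self, genome: dict[str, str]):
        self.frames = {c: translate_six_frames(GenomeSequence(c, s))
                       for c, s in genome.items()}

    def count(self, peptide: str) -> int:
        return sum(len(_find_all(self.frames[c][(st, f)], peptide))
                   for c in self.frames for st, f in FRAMES)


def _window_peptide(genome: dict[str, str], chrom: str, strand: str,
                    start: int, end: int) -> tuple[str, int]:
    """(peptide, frame) of a codon-grid window on the given strand."""
    seq = genome[chrom]
    nt = seq[start:end]
    if strand == "+":
        return translate(nt), start % 3
    return translate(reverse_complement(nt)), (len(seq) - end) % 3


# -------------------------------------------------------------- reference

def generate_reference(seed: int, n_chroms: int = 2, chrom_len: int = 50_000,
                       n_genes: int = 10, n_noncoding: int = 2,
                       dialect_edits: bool = True) -> ReferenceFixture:
    """Random genome plus two annotation dialects over shared gene models.

    Gene structures follow a deterministic exon-count/strand cycle
    (2,3,4,4 exons; alternating strands) so that every downstream category
    sampler always finds a suitable gene; lengths and sequence are
    seed-driven.  Dialect B drops two genes, trims the terminal exons of two
    more and carries explicit UTR features.
    """
    if n_chroms <= 0 or chrom_len <= 0 or n_genes < 0 or n_noncoding < 0:
        raise FixtureError("n_chroms and chrom_len must be positive; "
                           "gene counts non-negative")
    rng = random.Random(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    genome = {c: [rng.choice("ACGT") for _ in range(chrom_len)] for c in chroms}

    exon_cycle = [2, 3, 4, 4]
    genes: list[Gene] = []
    cursors = {c: 1200 for c in chroms}
    total = n_genes + n_noncoding
    for gi in range(total):
        chrom = chroms[gi % n_chroms]
        strand = "+" if gi % 2 == 0 else "-"
        coding = gi < n_genes
        n_exons = exon_cycle[gi % 4] if coding else rng.choice([1, 2])
        exons: list[Interval] = []
        pos = cursors[chrom]
        for ei in range(n_exons):
            elen = rng.randrange(250, 420)
            exons.append((pos, pos + elen))
            pos += elen
            if ei < n_exons - 1:
                pos += rng.randrange(250, 600)
        if pos > chrom_len - 1200:
            raise FixtureError(
                f"infeasible packing: gene {gi} would end at {pos} "
                f"on {chrom} of length {chrom_len}")
        cursors[chrom] = pos + rng.randrange(1800, 2600)

        gid, tid = f"G{gi + 1:03d}", f"T{gi + 1:03d}"
        cds: list[Interval] = []
        if coding:
            u_left = rng.randrange(100, 140)
            u_right = rng.randrange(100, 140)
            cds_start = exons[0][0] + u_left
            cds_end = exons[-1][1] - u_right
            blocks = intersect_intervals([(cds_start, cds_end)], exons)
            excess = sum(e - s for s, e in blocks) % 3
            if excess:
                s, e = blocks[-1]
                blocks[-1] = (s, e - excess)
            cds = blocks
        tx = Transcript(id=tid, chrom=chrom, strand=strand, exons=exons,
                        cds=cds, gene_id=gid)
        genes.append(Gene(id=gid, chrom=chrom, strand=strand, transcripts=[tx]))

    # overwrite CDS bases with stop-free codons and record the proteins
    proteins: dict[str, str] = {}
    for g in genes:
        t = g.transcripts[0]
        if not t.cds:
            continue
        n_codons = sum(e - s for s, e in t.cds) // 3
        coding_nt = "".join(rng.choice(_NON_STOP_CODONS) for _ in range(n_codons))
        genomic_nt = coding_nt if t.strand == "+" else reverse_complement(coding_nt)
        off = 0
        for s, e in t.cds:
            genome[t.chrom][s:e] = list(genomic_nt[off:off + (e - s)])
            off += e - s
        proteins[t.id] = translate(coding_nt)
    genome_str = {c: "".join(v) for c, v in genome.items()}

    ann_a = GeneSet(genes=genes, source_label="ncbi-like")
    dropped, trimmed = [], []
    if dialect_edits:
        coding_ids = [g.id for g in genes if g.transcripts[0].cds]
        dropped = coding_ids[2:3] + coding_ids[5:6]
        trimmed = [g for g in coding_ids[1:2] + coding_ids[6:7]
                   if g not in dropped]
    genes_b: list[Gene] = []
    for g in genes:
        if g.id in dropped:
            continue
        gb = copy.deepcopy(g)
        if g.id in trimmed:
            t = gb.transcripts[0]
            (s0, e0), (sn, en) = t.exons[0], t.exons[-1]
            t.exons[0] = (s0 + 60, e0)
            t.exons[-1] = (sn, en - 60)
        for t in gb.transcripts:
            t.id += ".b"
            r = derive_regions(t)
            t.explicit_utr5, t.explicit_utr3 = r.utr5, r.utr3
        genes_b.append(gb)
    ann_b = GeneSet(genes=genes_b, source_label="ensembl-like")
    proteins_b = {t.id: proteins[t.id[:-2]] for g in genes_b
                  for t in g.transcripts if t.cds}

    truth = {"seed": seed, "n_chroms": n_chroms, "chrom_len": chrom_len,
             "n_genes": n_genes, "n_noncoding": n_noncoding,
             "dropped_in_b": dropped, "trimmed_in_b": trimmed}
    return ReferenceFixture(seed=seed, genome=genome_str, ann_a=ann_a,
                            ann_b=ann_b, proteins_a=proteins,
                            proteins_b=proteins_b, truth=truth)


# ---------------------------------------------------------------- peptides

def _gene_free_gaps(fix: ReferenceFixture, margin: int = 60) -> dict[str, list[Interval]]:
    spans: dict[str, list[Interval]] = {c: [] for c in fix.genome}
    for gs in (fix.ann_a, fix.ann_b):
        for g in gs.genes:
            s, e = g.span
            spans[g.chrom].append((max(0, s - margin), e + margin))
    return {c: subtract_intervals([(100, len(fix.genome[c]) - 100)],
                                  merge_intervals(spans[c]))
            for c in fix.genome}


def plant_peptides(fix: ReferenceFixture, category_counts: dict[str, int],
                   seed: int, annotation: str = "a",
                   aa_len_range: tuple[int, int] = (8, 12),
                   max_tries: int = 400) -> list[PlantedPeptide]:
    """Peptides whose unique genomic locus satisfies exactly one category
    rule of the chosen annotation set, guaranteed single-locus and novel
    (absent from both protein sets) by rejection sampling."""
    rng = random.Random(seed)
    gs = fix.ann_a if annotation == "a" else fix.ann_b
    cache = _FrameCache(fix.genome)
    coding = [t for t in gs.transcripts() if t.cds]
    noncoding = [t for t in gs.transcripts() if not t.cds]
    gaps = _gene_free_gaps(fix)
    all_proteins = "$".join(list(fix.proteins_a.values())
                            + list(fix.proteins_b.values()))

    regions = {t.id: derive_regions(t) for t in gs.transcripts()}

    def propose(cat: str, L: int):
        nt = 3 * L
        if cat == "intergenic":
            opts = [(c, iv) for c, ivs in gaps.items() for iv in ivs
                    if iv[1] - iv[0] > nt + 2]
            c, (s0, e0) = rng.choice(opts)
            s = rng.randrange(s0, e0 - nt)
            return c, rng.choice("+-"), s, s + nt
        if cat == "intron":
            opts = [(t, iv) for t in coding for iv in t.introns()
                    if iv[1] - iv[0] > nt + 12]
            t, (i0, i1) = rng.choice(opts)
            s = rng.randrange(i0 + 3, i1 - nt - 3)
            return t.chrom, t.strand, s, s + nt
        if cat == "transcript_noncoding":
            opts = [(t, iv) for t in noncoding for iv in t.exons
                    if iv[1] - iv[0] > nt + 6]
            t, (x0, x1) = rng.choice(opts)
            s = rng.randrange(x0 + 1, x1 - nt - 1)
            return t.chrom, t.strand, s, s + nt
        if cat == "coding_out_of_frame":
            opts = [(t, b) for t in coding
                    for b in regions[t.id].cds_frames if b[1] - b[0] > nt + 7]
            t, (bs, be, p0) = rng.choice(opts)
            if t.strand == "+":
                s = rng.randrange(bs, be - nt - 1)
                if (p0 + s - bs) % 3 == 0:
                    s += 1
                return t.chrom, t.strand, s, s + nt
            e = rng.randrange(bs + nt + 1, be)
            if (p0 + be - e) % 3 == 0:
                e -= 1
            return t.chrom, t.strand, e - nt, e
        if cat in ("nter_extension", "cter_extension"):
            # abut the CDS terminus or overlap it by j in-frame codons (the
            # CDS side is stop-free by construction, which keeps rejection
            # rates low); the extension side stays inside the terminal exon
            t = rng.choice(coding)
            c0, c1 = t.cds[0][0], t.cds[-1][1]
            left_end = (cat == "nter_extension") == (t.strand == "+")
            if left_end:
                max_j = min(L - 1, (t.cds[0][1] - c0) // 3 - 1)
                j = rng.randrange(0, max(max_j, 0) + 1)
                e = c0 + 3 * j
                return t.chrom, t.strand, e - nt, e
            max_j = min(L - 1, (c1 - t.cds[-1][0]) // 3 - 1)
            j = rng.randrange(0, max(max_j, 0) + 1)
            s = c1 - 3 * j
            return t.chrom, t.strand, s, s + nt
        if cat in ("utr5", "utr3"):
            side = cat
            opts = []
            for t in coding:
                r = regions[t.id]
                for (u0, u1) in (r.utr5 if side == "utr5" else r.utr3):
                    # stay 3 nt clear of the CDS terminus so the terminal
                    # extension rules cannot fire
                    c0, c1 = t.cds[0][0], t.cds[-1][1]
                    lo, hi = u0, u1
                    if u1 <= c0:
                        hi = min(hi, c0 - 3)
                    if u0 >= c1:
                        lo = max(lo, c1 + 3)
                    if hi - lo > nt + 2:
                        opts.append((t, lo, hi))
            t, lo, hi = rng.choice(opts)
            s = rng.randrange(lo, hi - nt)
            return t.chrom, t.strand, s, s + nt
        if cat in ("exon5_extension", "exon3_extension"):
            t = rng.choice(coding)
            five_end = t.start if t.strand == "+" else t.end
            three_end = t.end if t.strand == "+" else t.start
            boundary = five_end if cat == "exon5_extension" else three_end
            inside = rng.randrange(3, nt - 2)
            if boundary == t.start:
                s = boundary - (nt - inside)
            else:
                s = boundary - inside
            return t.chrom, t.strand, s, s + nt
        raise ValueError(f"unknown category {cat!r}")

    planted: list[PlantedPeptide] = []
    for cat, want in category_counts.items():
        if cat not in PEPTIDE_CATEGORY_DEFAULTS:
            raise ValueError(f"unknown category {cat!r}")
        got = 0
        tries = 0
        while got < want:
            tries += 1
            if tries > max_tries * max(want, 1):
                raise FixtureError(f"category {cat!r} not realizable in this "
                                   f"reference (exhausted sampling budget)")
            L = rng.randrange(*aa_len_range)
            try:
                chrom, strand, s, e = propose(cat, L)
            except IndexError:
                raise FixtureError(f"category {cat!r} not realizable: no "
                                   f"suitable region in the reference")
            pep, frame = _window_peptide(fix.genome, chrom, strand, s, e)
            if set(pep) - AA_RESIDUES:
                continue
            if pep in all_proteins or cache.count(pep) != 1:
                continue
            if any(p.peptide == pep for p in planted):
                continue
            planted.append(PlantedPeptide(peptide=pep, chrom=chrom,
                                          strand=strand, frame=frame,
                                          start=s, end=e, category=cat,
                                          annotation=annotation))
            got += 1
    return planted


def plant_multilocus_peptides(fix: ReferenceFixture, n: int,
                              seed: int) -> list[PlantedPeptide]:
    """Plant peptides occurring at exactly two genomic sites.

    Mutates ``fix.genome`` (copies the nucleotides of an intergenic window
    into a second gene-free window), so call this *before* planting the
    single-locus peptides.
    """
    rng = random.Random(seed)
    out = []
    for _ in range(n):
        for _try in range(400):
            gaps = _gene_free_gaps(fix)
            L = rng.randrange(8, 12)
            nt = 3 * L
            opts = [(c, iv) for c, ivs in gaps.items() for iv in ivs
                    if iv[1] - iv[0] > 2 * nt + 40]
            c, (g0, g1) = rng.choice(opts)
            s1 = rng.randrange(g0, g1 - 2 * nt - 20)
            s2 = rng.randrange(s1 + nt + 10, g1 - nt)
            s1 -= s1 % 3  # keep frame 0 so both copies share a codon grid
            s2 -= s2 % 3
            seq = fix.genome[c]
            window = seq[s1:s1 + nt]
            pep = translate(window)
            if set(pep) - AA_RESIDUES:
                continue
            fix.genome[c] = seq[:s2] + window + seq[s2 + nt:]
            cache = _FrameCache(fix.genome)
            if cache.count(pep) != 2:
                fix.genome[c] = seq  # revert: accidental extra copies
                continue
            out.append(PlantedPeptide(peptide=pep, chrom=c, strand="+",
                                      frame=s1 % 3, start=s1, end=s1 + nt,
                                      category="multilocus", annotation="a",
                                      n_loci=2))
            break
        else:
            raise FixtureError("could not plant a two-locus peptide")
    return out


# ------------------------------------------------------------------- PSMs

def simulate_psms(planted: list[PlantedPeptide], seed: int,
                  evalue_accept: tuple[float, float] = (1e-6, 1e-3),
                  n_reject_evalue: int = 10,
                  n_reject_single: int = 10) -> tuple[pd.DataFrame, dict]:
    """PSM table for planted peptides with known accept/reject outcomes.

    Every planted peptide receives two accepted spectra (one engine), one of
    them duplicated across a second partition with a worse E-value to
    exercise best-per-spectrum selection.  Rejection rows are added: random
    peptides failing the E-value threshold, and single-spectrum/
    single-engine identifications that the spectral-count rule removes.
    """
    rng = random.Random(seed)
    rows = []
    spec_no = 0

    def loguni(lo: float, hi: float) -> float:
        import math
        return 10 ** rng.uniform(math.log10(lo), math.log10(hi))

    def rand_pep() -> str:
        return "".join(rng.choice(sorted(AA_RESIDUES)) for _ in range(9))

    expected_accept = set()
    for p in planted:
        tissue = TISSUES[spec_no % len(TISSUES)]
        expected_accept.add((tissue, p.peptide))
        for k in range(2):
            spec_no += 1
            sid = f"spec{spec_no:05d}"
            e1 = loguni(*evalue_accept)
            rows.append([sid, p.peptide, e1, "engineA", "genome", "part001",
                         0, tissue])
            if k == 0:
                # same spectrum, second partition, strictly worse E-value:
                # must lose the best-per-spectrum selection
                rows.append([sid, p.peptide, min(e1 * 10, 0.01), "engineA",
                             "genome", "part002", 0, tissue])
    rejected_evalue, rejected_single = [], []
    for _ in range(n_reject_evalue):
        spec_no += 1
        pep = rand_pep()
        tissue = TISSUES[spec_no % len(TISSUES)]
        rows.append([f"spec{spec_no:05d}", pep, rng.uniform(0.011, 0.5),
                     "engineA", "genome", "part001", 0, tissue])
        rejected_evalue.append((tissue, pep))
    for _ in range(n_reject_single):
        spec_no += 1
        pep = rand_pep()
        tissue = TISSUES[spec_no % len(TISSUES)]
        rows.append([f"spec{spec_no:05d}", pep, loguni(*evalue_accept),
                     "engineA", "genome", "part001", 0, tissue])
        rejected_single.append((tissue, pep))
    df = pd.DataFrame(rows, columns=PSM_COLUMNS)
    df = df.sample(frac=1.0, random_state=seed).reset_index(drop=True)
    truth = {"expected_accept": expected_accept,
             "rejected_evalue": rejected_evalue,
             "rejected_single": rejected_single}
    return df, truth


def simulate_null_psms(n_pairs: int, seed: int,
                       evalue_range: tuple[float, float] = (1e-6, 1.0)
                       ) -> pd.DataFrame:
    """Null fixture: equal numbers of target and decoy peptides, two spectra
    each, E-values drawn iid from one log-uniform law.  After identical
    filtering the decoy/target ratio estimates 100% FDR up to binomial
    sampling error."""
    import math
    rng = random.Random(seed)
    residues = sorted(AA_RESIDUES)
    lo, hi = (math.log10(evalue_range[0]), math.log10(evalue_range[1]))
    rows = []
    spec = 0
    for i in range(n_pairs):
        for is_decoy in (0, 1):
            pep = "".join(rng.choice(residues) for _ in range(10))
            for _ in range(2):
                spec += 1
                rows.append([f"n{spec:06d}", pep, 10 ** rng.uniform(lo, hi),
                             "engineA", "genome",
                             "decoy001" if is_decoy else "part001",
                             is_decoy, "null"])
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


# -------------------------------------------------------------- transcripts

def generate_transcript_fixture(fix: ReferenceFixture, seed: int,
                                per_category: int = 2
                                ) -> tuple[GeneSet, dict[str, str]]:
    """Assembled transcripts with one known category each, vs annotation A."""
    rng = random.Random(seed)
    ref_txs = [t for t in fix.ann_a.transcripts()]
    multi = [t for t in ref_txs if t.n_exons >= 2]
    three_plus = [t for t in ref_txs if t.n_exons >= 3]
    four_plus = [t for t in ref_txs if t.n_exons >= 4]
    gaps = _gene_free_gaps(fix)
    txs: list[Transcript] = []
    truth: dict[str, str] = {}
    n = 0

    def add(exons, chrom, strand, category):
        nonlocal n
        n += 1
        tid = f"ASM{n:03d}"
        txs.append(Transcript(id=tid, chrom=chrom, strand=strand,
                              exons=exons, gene_id=tid + "_g"))
        truth[tid] = category

    for _ in range(per_category):
        t = rng.choice(multi)
        exons = list(t.exons)
        exons[0] = (exons[0][0] - 30, exons[0][1])
        exons[-1] = (exons[-1][0], exons[-1][1] + 30)
        add(exons, t.chrom, t.strand, "matches_annotated")

        # drop the terminal exon of a >=3-exon model on one side; which
        # side is 5' depends on the strand (genomic left = 5' only on '+')
        t = rng.choice([t for t in three_plus if t.strand == "+"])
        add(list(t.exons[1:]), t.chrom, t.strand, "five_prime_difference")
        t = rng.choice([t for t in three_plus if t.strand == "-"])
        add(list(t.exons[:-1]), t.chrom, t.strand, "five_prime_difference")
        t = rng.choice([t for t in three_plus if t.strand == "+"])
        add(list(t.exons[:-1]), t.chrom, t.strand, "three_prime_difference")
        t = rng.choice([t for t in three_plus if t.strand == "-"])
        add(list(t.exons[1:]), t.chrom, t.strand, "three_prime_difference")

        # skip an internal exon: shares flanking introns, chain differs
        t = rng.choice(four_plus)
        exons = [t.exons[0], t.exons[1], t.exons[3]]
        add(exons, t.chrom, t.strand, "novel_isoform")

        opts = [(t, iv) for t in ref_txs for iv in t.introns()
                if iv[1] - iv[0] >= 360]
        t, (i0, i1) = rng.choice(opts)
        s = rng.randrange(i0 + 50, i1 - 300)
        add([(s, s + 250)], t.chrom, t.strand, "intronic")

        opts = [(c, iv) for c, ivs in gaps.items() for iv in ivs
                if iv[1] - iv[0] > 700]
        c, (g0, g1) = rng.choice(opts)
        s = rng.randrange(g0, g1 - 600)
        add([(s, s + 200), (s + 380, s + 580)], c, rng.choice("+-"),
            "intergenic")
    gs = GeneSet(genes=[Gene(id=t.gene_id, chrom=t.chrom, strand=t.strand,
                             transcripts=[t]) for t in txs],
                 source_label="assembled")
    return gs, truth


# ----------------------------------------------------------- other layers

def generate_presence_matrix(n_products: int = 200, n_tissues: int = 13,
                             single_fraction: float = 0.98,
                             seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Boolean product-by-tissue matrix with an exact single-tissue count."""
    rng = random.Random(seed)
    n_single = round(n_products * single_fraction)
    cols = [f"tissue{i + 1}" for i in range(n_tissues)]
    data = []
    for i in range(n_products):
        row = [False] * n_tissues
        if i < n_single:
            row[rng.randrange(n_tissues)] = True
        else:
            k = rng.randrange(2, n_tissues + 1)
            for j in rng.sample(range(n_tissues), k):
                row[j] = True
        data.append(row)
    df = pd.DataFrame(data, columns=cols,
                      index=[f"P{i + 1:04d}" for i in range(n_products)])
    return df, {"fraction_single": n_single / n_products}


def generate_mirna_fixture(fix: ReferenceFixture, seed: int,
                           n_known: int = 6) -> dict:
    """Known mature/primary miRNA intervals plus predictions with known
    expected name assignments."""
    rng = random.Random(seed)
    gaps = _gene_free_gaps(fix)
    opts = [(c, iv) for c, ivs in gaps.items() for iv in ivs
            if iv[1] - iv[0] > 400]
    known_mature, known_primary, predicted, expected = [], [], [], {}
    for i in range(n_known):
        c, (g0, g1) = rng.choice(opts)
        s = rng.randrange(g0 + 20, g1 - 250)
        strand = rng.choice("+-")
        mname, pname = f"mir-{i + 1}", f"mir-{i + 1}-primary"
        known_primary.append(NamedInterval(pname, c, s, s + 150, strand))
        known_mature.append(NamedInterval(mname, c, s + 30, s + 52, strand))
        if i % 3 == 0:
            ds, de = rng.randrange(-5, 6), rng.randrange(-5, 6)
            pid = f"pred{i + 1}"
            predicted.append(NamedInterval(pid, c, s + 30 + ds, s + 52 + de,
                                           strand))
            expected[pid] = (mname, "mature")
        elif i % 3 == 1:
            pid = f"pred{i + 1}"
            # outside the mature +/-5 window but overlapping the primary
            predicted.append(NamedInterval(pid, c, s + 100, s + 160, strand))
            expected[pid] = (pname, "primary")
        else:
            pid = f"pred{i + 1}"
            predicted.append(NamedInterval(pid, c, s + 200, s + 222, strand))
            expected[pid] = (None, "novel")
    return {"known_mature": known_mature, "known_primary": known_primary,
            "predicted": predicted, "expected": expected}


# -------------------------------------------------------------- bundle I/O

def write_genome_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_protein_fasta(proteins: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for pid in sorted(proteins):
            fh.write(f">{pid}\n{proteins[pid]}\n")


def write_mirna_bed(intervals: list[NamedInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_mirna_bed(path: str) -> list[NamedInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            c, s, e, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            out.append(NamedInterval(name, c, int(s), int(e), strand))
    return out


def make_fixture_bundle(outdir: str, seed: int,
                        category_counts: dict[str, int] | None = None) -> dict:
    """Generate and write the complete toy data set plus truth.json.

    Emits genome FASTA, both annotation GFF3 dialects, both protein FASTA
    sets, a PSM TSV, assembled-transcript GTF, abundance TSV, miRNA BED
    files and the serialized ground truth.
    """
    os.makedirs(outdir, exist_ok=True)
    counts = category_counts or PEPTIDE_CATEGORY_DEFAULTS
    fix = generate_reference(seed)
    multil = plant_multilocus_peptides(fix, 2, seed + 1)
    planted = plant_peptides(fix, counts, seed + 2, annotation="a")
    psm_df, psm_truth = simulate_psms(planted + multil, seed + 3)
    asm, tx_truth = generate_transcript_fixture(fix, seed + 4)
    pres, pres_truth = generate_presence_matrix(seed=seed + 5)
    mirna = generate_mirna_fixture(fix, seed + 6)

    write_genome_fasta(fix.genome, os.path.join(outdir, "genome.fa"))
    write_gff3(fix.ann_a, os.path.join(outdir, "annotation_a.gff3"))
    write_gff3(fix.ann_b, os.path.join(outdir, "annotation_b.gff3"),
               explicit_utrs=True)
    write_protein_fasta(fix.proteins_a, os.path.join(outdir, "proteins_a.fasta"))
    write_protein_fasta(fix.proteins_b, os.path.join(outdir, "proteins_b.fasta"))
    psm_df.to_csv(os.path.join(outdir, "psms.tsv"), sep="\t", index=False)
    write_gtf(asm, os.path.join(outdir, "transcripts.gtf"))
    pres.astype(int).to_csv(os.path.join(outdir, "abundance.tsv"), sep="\t")
    write_mirna_bed(mirna["known_mature"],
                    os.path.join(outdir, "mirna_known_mature.bed"))
    write_mirna_bed(mirna["known_primary"],
                    os.path.join(outdir, "mirna_known_primary.bed"))
    write_mirna_bed(mirna["predicted"],
                    os.path.join(outdir, "mirna_predicted.bed"))

    truth = {
        "reference": fix.truth,
        "peptides": [vars(p) for p in planted],
        "multilocus_peptides": [vars(p) for p in multil],
        "psm": {k: sorted(map(list, v)) for k, v in psm_truth.items()},
        "transcripts": tx_truth,
        "presence": pres_truth,
        "mirna_expected": {k: list(v) for k, v in mirna["expected"].items()},
    }
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
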