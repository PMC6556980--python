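# Methods

This note records the model behind each stage, the parameter choices, and
the places where the design was genuinely open.

## Coordinates and gene models

All in-memory intervals are 0-based half-open on the forward genome strand;
GFF3/GTF 1-based inclusive coordinates are converted only at I/O
boundaries. 5' and 3' always refer to transcript orientation, so on the
minus strand "5'" is genomically rightmost.

Two annotation dialects are modelled. The *ncbi-like* dialect carries
gene/mRNA/exon/CDS features and UTRs are derived as exon − CDS, split at
the CDS span into a 5' and a 3' part by strand. The *ensembl-like* dialect
may carry explicit `five_prime_UTR`/`three_prime_UTR` features, which
override derivation when present. The CDS phase column of GFF3 is ignored
and reading-frame phases are recomputed from CDS geometry (phase k mod 3
walking the concatenated CDS 5'→3'), so there is a single source of truth.
Overlapping exons within one transcript are rejected rather than merged:
on synthetic input that is always a generator bug, and failing loudly is
worth more than tolerance. The two gene sets are kept fully independent;
no cross-annotation locus merging is attempted.

Interval lookup uses an interval tree keyed by chromosome, but the tree is
only an acceleration structure: tests require its answers to equal a
brute-force scan on randomized queries, including unknown chromosomes
(empty result, not an error).

## Six-frame database

Frames are numbered 0/1/2 as the offset of the first translated base on
the *reading* strand — the forward sequence for `+`, the reverse
complement for `-`. This convention makes the coordinate arithmetic
symmetric: a peptide at amino-acid offset *a* of frame *f* occupies
`[3a+f, 3a+f+3L)` on the forward strand and the mirror image from the
chromosome end on the reverse strand.

Translation uses the standard genetic code; stop codons are kept as `*`
(matching never crosses them, since `*` equals no residue) and any codon
containing a non-ACGT base becomes `X`, which matches only a literal `X`.

Segmentation starts at 0 and steps by `seg_len − overlap` (default
600 − 60 = 540 aa); the final short segment is emitted whenever it extends
coverage, with no minimum length, which guarantees that every substring up
to the overlap length occurs intact in at least one segment (checked
exhaustively in the tests). Partition files hold `per_file` segments
(default 50 000); the decoy is an independent uniform permutation of each
entry's residues, seeded, preserving per-entry length and composition.
Reversal decoys were rejected because randomization is the stated model
and a shuffle has no palindrome artifacts.

## PSM filtering and FDR

The acceptance threshold is E ≤ 0.01, *inclusive*. Within each
(decoy-status, tissue, spectrum) group — pooling all database partitions
and both the protein and genome search spaces — only the lowest-E-value
PSM survives; ties break to the lexicographically smallest peptide, then
partition, making the filter deterministic, idempotent and independent of
input row order. Peptide-level hits then require ≥ 2 spectra, or 1
spectrum identified by ≥ 2 distinct engine labels. The engine field is a
free label rather than an enumeration of specific programs. The
single-spectrum rule is applied *after* combining protein and genome
search results; the opposite order is defensible but changes only
borderline peptides, and one order had to be fixed.

FDR is the plain ratio `100 · accepted decoys / accepted targets`,
reported to two decimals, with decoys passed through the identical
accept/spectral-count path first. The estimator was chosen over
`2d/(t+d)` as the simplest one consistent with a decoy search "done
exactly as" the target search and with an attainable 0.00% lower bound.
Its calibration is tested on a null simulation in which target and decoy
PSMs are drawn from one log-uniform E-value law over [1e-6, 1], two
spectra per peptide, equal counts: the estimate must be ≈ 100% within
binomial sampling error (n = 10 000 PSMs gives ≈ 1100 accepted per arm, a
relative sd of ≈ 4%, and the test allows ± 13 points).

Peptide equality is exact string match; isoleucine/leucine are not
collapsed. That is testable and deterministic; a collapse flag would be a
one-line change and deliberately is not a default.

## Peptide mapping and classification

Novel peptides (not an exact substring of any protein in either annotated
proteome) are located by exact search against *full-chromosome* frame
translations, not against the 600-aa segments — segment boundaries are a
search-engine artifact and must not be able to hide occurrences. The
search is a per-peptide scan over cached frame translations, verified
against a naive per-frame substring oracle; every reported locus must
round-trip (translating the interval on the stated strand/frame
reproduces the peptide). Junction-spanning peptides cannot be found by
genomic six-frame matching and are out of scope. Only peptides with
exactly one genome-wide locus are classified.

Classification applies the first matching rule in a fixed priority order,
most CDS-proximal first:

1. **coding_out_of_frame** — overlaps ≥ 1 CDS base on the same strand with
   mismatched frame phase (a fully in-frame overlap is an annotated
   peptide and is removed upstream; if one reaches the classifier anyway
   it falls through to the least specific genic call).
2. **nter_extension / cter_extension** — on the transcript's strand, in
   the CDS reading frame (the peptide's codon grid continues the CDS
   grid), abutting or overlapping the CDS start/stop terminus.
3. **utr5 / utr3** — wholly within the (explicit or derived) UTR exonic
   intervals.
4. **exon5_extension / exon3_extension** — crossing the transcript's
   5'-/3'-most boundary, partly inside, partly outside the span, without
   CDS frame contiguity.
5. **transcript_noncoding** — wholly within exons of a noncoding
   transcript.
6. **intron** — overlapping an intron of a same-strand transcript.
7. **intergenic** — no same-strand gene overlap at all. Antisense-only
   overlap is intergenic; the category list has no antisense row and
   adding one was out of scope.

When several transcripts overlap a locus, each contributes its candidate
categories and the highest-priority one wins, which makes the result
independent of gene order and chromosome naming.

The cross-annotation summary counts, per category c, peptides with
A = B = c in the "both" column and disagreeing peptides once in the A-only
column of their A category and once in the B-only column of their B
category. This is one declared reading of a "found by both / one
pipeline" cross-tab; under it the A-only and B-only column totals are
necessarily equal on any input. Row percentages are cell/row-total,
rounded half-up to one decimal — half-up, not banker's, because that is
how such tables are conventionally printed.

## Transcript classification

Transcript-model identity is anchored on splice junctions: tolerance 0 on
every intron boundary, unlimited slack on terminal-exon ends, because
annotations are routinely missing true termini while junctions are
well-determined. An exact intron-chain match (same strand) is
`matches_annotated`; single-exon transcripts, having no chain, match
single-exon models by exon overlap. A transcript sharing ≥ 1 intron or
≥ 1 bp of same-strand exonic overlap but differing is a `novel_isoform`,
refined to `five_prime_difference`/`three_prime_difference` when the two
chains align as contiguous sub-chains differing on one genomic side only
*and* the extra introns lie outside the other transcript's body — an
extra intron inside the model's span splits an exon and is an isoform
change, not an end correction. Which side is 5' follows the strand. A
transcript whose exons sit wholly inside introns of a same-strand model is
`intronic`; with no same-strand exon overlap at all it is `intergenic`.
Novel transcripts get `CXT.N` identifiers assigned in (chrom, start, end)
order, stable under input shuffling.

Exon statistics are arithmetic means per group at one decimal. The
presence matrix is thresholded at abundance > 0 by default — the cutoff is
a user parameter, since imposing one silently would hide low-expression
products.

## miRNA name transfer

A prediction inherits a known mature miR's name when both interval ends
are within ±5 nt on the same chromosome and strand; among several
qualifying matures the nearest by |Δstart| + |Δend| wins, ties broken by
lexicographic name. Failing that, ≥ 1 bp overlap with a known primary
transcript transfers the primary's name (largest overlap, ties
lexicographic). Everything else keeps a `novel-mir-N` identifier numbered
in coordinate order. Hairpin prediction and target prediction are external
concerns and out of scope.

## Synthetic data

The generator emulates a dual-annotation survey at desk scale: by default
two 50 kb chromosomes, ten coding and two noncoding genes, peptides of
7–25 aa planted in each category, ≤ 500 peptides — the whole suite runs in
seconds. Gene structures follow a deterministic cycle (2,3,4,4 exons;
alternating strands) so that every category sampler always finds a
suitable gene; exon/intron/UTR lengths, sequence and placements are
seed-driven, and everything is byte-reproducible from (seed, parameters).
CDS regions are overwritten with stop-free codons so annotated proteins
are well defined; terminal-extension peptide windows may overlap the CDS
terminus by whole codons, which keeps their rejection rate low without
biasing the category. Planted peptides are guaranteed novel (absent from
both proteomes) and single-locus by rejection sampling against the whole
genome; two-locus peptides are planted by copying an intergenic window,
before single-locus planting, since the copy mutates the genome.

Dialect B is derived from A by dropping two genes, trimming the terminal
exons of two more by 60 nt, and writing explicit UTR features — enough to
exercise every cross-annotation disagreement pattern.

What the fixtures do *not* emulate: real mass spectra and search-engine
score distributions (E-values are drawn from simple laws), sequence
repeats and homology (random genomes make multi-locus peptides
vanishingly rare unless planted), splice-site motifs, and read-level
RNA-seq. Passing tests therefore demonstrate the correctness of the
filtering, mapping, classification and summary *logic* under its stated
definitions — not end-to-end performance on real archived spectra, which
would require the original raw data and search engines.

## Numerical and degenerate-input choices

E-value threshold comparisons are inclusive (≤). Percentages use decimal
half-up rounding via `decimal.Decimal`, never binary-float `round`.
Empty GTF/GFF3 files parse to empty gene sets; an unknown chromosome in a
query returns an empty result; a zero-target FDR is an error rather than
0/0; an empty segment list refuses to write a database; noncoding
transcripts have empty UTR/frame tables rather than sentinel values.
Problem sizes in the acceptance script (50 kb chromosomes, 10 000-PSM
null, 200-product presence matrix) were chosen as the defaults of the
fixture generator; they are large enough for the binomial tolerances
stated above and small enough to run interactively.
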