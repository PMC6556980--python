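"""Build a partitioned six-frame translation search database.

A genome is translated in all six reading frames; each frame is cut into
600-aa segments with a 60-aa overlap (so any tryptic-scale peptide is
contained intact in at least one segment) and grouped into FASTA files of
a fixed number of entries.  One file is shuffled per-entry into a decoy
database for FDR estimation.
"""

import tempfile

from pgmap.fixtures import generate_reference
from pgmap.models import DbBuildConfig
from pgmap.sixframe import (make_decoy, read_fasta, segment_genome,
                            write_partitioned_fasta)

fix = generate_reference(seed=1)  # two 50 kb chromosomes
cfg = DbBuildConfig(seg_len=600, overlap=60, per_file=500, decoy_seed=1)

segments = list(segment_genome(fix.genome, cfg))
outdir = tempfile.mkdtemp()
paths = write_partitioned_fasta(segments, cfg, outdir)
decoy = make_decoy(read_fasta(paths[0]), seed=cfg.decoy_seed)

print(f"genome: {sum(map(len, fix.genome.values()))} nt "
      f"over {len(fix.genome)} chromosomes")
print(f"segments: {len(segments)} across {len(paths)} FASTA file(s)")
print(f"example header: {segments[0].header}")
print(f"decoy entries: {len(decoy)} (per-entry residue shuffles)")
# The header encodes chrom|strand|frame|aa-offset, so every peptide hit in
# a segment can be projected back to exact genome coordinates.
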