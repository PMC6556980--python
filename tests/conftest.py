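import pytest

from pgmap.fixtures import generate_reference
from pgmap.models import PeptideLocus

TOY_GFF3 = """\
##gff-version 3
chr1\ttoy\tgene\t1002\t2600\t.\t+\t.\tID=G1
chr1\ttoy\tmRNA\t1002\t2600\t.\t+\t.\tID=T1;Parent=G1
chr1\ttoy\texon\t1002\t1600\t.\t+\t.\tParent=T1
chr1\ttoy\texon\t2002\t2600\t.\t+\t.\tParent=T1
chr1\ttoy\tCDS\t1202\t1600\t.\t+\t0\tParent=T1
chr1\ttoy\tCDS\t2002\t2400\t.\t+\t0\tParent=T1
"""


@pytest.fixture
def toy_gff3(tmp_path):
    """One coding gene on chr1 '+': exons [1001,1600)+[2001,2600),
    CDS [1201,1600)+[2001,2400) in 0-based half-open coordinates."""
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3)
    return str(path)


@pytest.fixture(scope="session")
def ref_fixture():
    """Default-scale synthetic reference (two 50 kb chromosomes, two
    annotation dialects, ground truth)."""
    return generate_reference(seed=11)


@pytest.fixture(scope="session")
def ref_fixture_no_edits():
    """Same reference but with identical annotation dialects."""
    return generate_reference(seed=11, dialect_edits=False)


def locus_of(planted) -> PeptideLocus:
    return PeptideLocus(peptide=planted.peptide, chrom=planted.chrom,
                        strand=planted.strand, frame=planted.frame,
                        start=planted.start, end=planted.end,
                        n_loci_total=planted.n_loci)
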