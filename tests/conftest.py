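import numpy as np
import pytest

from rnavatar.transcripts import TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(11)


def build_toy_transcript(strand: str = "+") -> TranscriptModel:
    """Three-exon transcript whose first exon (57 nt) ends in a G run spanning
    the donor boundary (...AGG | GTAAGT), with consensus acceptor motifs."""
    rs = np.random.default_rng(7)
    bases = "ACGT"
    genome = list(rs.choice(list(bases), size=3000))
    exons = [(1000, 1057), (1257, 1377), (1677, 1827)]
    genome[1054:1057] = list("AGG")
    genome[1057:1063] = list("GTAAGT")
    genome[1240:1257] = list("TTTCTTTCTTTTCTCAG"[-17:])
    genome[1374:1377] = list("CAG")
    genome[1377:1383] = list("GTAAGT")
    genome[1660:1677] = list("TTTCTTTCTTTTCTCAG"[-17:])
    seq = "".join(genome)
    if strand == "+":
        return TranscriptModel(
            transcript_id="TOY", strand="+", exons=tuple(exons),
            cds_start=0, cds_end=324, chrom="chr1", genome=seq,
        )
    # genomic mirror: reverse-complement contig, flipped exon coordinates
    from rnavatar.transcripts import revcomp

    L = len(seq)
    mirrored = [(L - e, L - s) for s, e in exons]
    return TranscriptModel(
        transcript_id="TOY_RC", strand="-", exons=tuple(mirrored),
        cds_start=0, cds_end=324, chrom="chr1", genome=revcomp(seq),
    )


@pytest.fixture
def toy_transcript():
    return build_toy_transcript("+")
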