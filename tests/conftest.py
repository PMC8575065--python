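import numpy as np
import pytest

from orfkit import synthetic_fixtures as sf
from orfkit.sequence_io import GenomeSequence, TranscriptModel


@pytest.fixture(scope="session")
def bundle():
    """One deterministic synthetic fixture shared across the session."""
    return sf.generate(sf.FixtureSpec(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_exon_tx(seq, strand="+", chrom="chr1", tid="t1", biotype="protein_coding",
                   cds_span=None):
    """A one-exon transcript covering the whole toy chromosome."""
    genome = {chrom: GenomeSequence(chrom, seq)}
    t = TranscriptModel(
        transcript_id=tid, gene_id=tid, chrom_id=chrom, strand=strand,
        exons=((0, len(seq)),), biotype=biotype, cds_span=cds_span,
    )
    return t, genome


def random_transcript(rng, max_len=2000, chrom="chrR"):
    """A random transcript: possibly minus strand, possibly two-exon."""
    n = int(rng.integers(30, max_len + 1))
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
    strand = "+" if rng.random() < 0.5 else "-"
    if rng.random() < 0.5 or n < 60:
        exons = ((0, n),)
    else:
        cut = int(rng.integers(10, n - 10))
        gap = int(rng.integers(20, 50))
        seq = seq[:cut] + "".join("ACGT"[i] for i in rng.integers(0, 4, gap)) + seq[cut:]
        first, second = (0, cut), (cut + gap, n + gap)
        exons = (first, second) if strand == "+" else (second, first)
    genome = {chrom: GenomeSequence(chrom, seq)}
    t = TranscriptModel(
        transcript_id="trand", gene_id="trand", chrom_id=chrom, strand=strand,
        exons=exons, biotype="other",
    )
    return t, genome
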