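"""Three-frame ORF enumeration on spliced transcripts.

An ORF here is a mature-mRNA span from an allowed start codon to the first
in-frame stop codon.  The small-ORF regime of interest caps peptide length
at 100 aa (stop codon excluded from the count); candidates sharing a
genomic stop site are collapsed to the longest, and duplicate peptide
sequences are removed — the standard prediction-assembly pipeline for
building a non-canonical search space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .sequence_io import (
    STOP_CODONS,
    TranscriptModel,
    spliced_sequence,
    translate,
    tx_to_genome,
)

__all__ = ["OrfRecord", "scan_orfs", "collapse_shared_stops", "dedupe_sequences",
           "NEAR_COGNATE_STARTS"]

#: NTG near-cognate start set usable when upstream TIS evidence allows non-AUG starts
NEAR_COGNATE_STARTS = frozenset({"ATG", "CTG", "GTG", "TTG"})


@dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF anchored on one transcript.

    ``tx_start``/``tx_end`` span start codon through stop codon inclusive
    (0-based half-open, transcript-relative).  ``genome_stop_key`` is
    ``(chrom, strand, genomic coordinate of the last base of the stop
    codon)`` — a genomic notion, so the same physical ORF reached via
    different transcripts compares equal.
    """

    orf_id: str
    transcript_id: str
    frame: int
    tx_start: int
    tx_end: int
    genome_stop_key: tuple
    peptide: str
    start_codon: str
    source: str = "scan"

    def __post_init__(self) -> None:
        if (self.tx_end - self.tx_start) != 3 * (len(self.peptide) + 1):
            raise ValueError(f"{self.orf_id}: interval/peptide length mismatch")
        if "*" in self.peptide:
            raise ValueError(f"{self.orf_id}: internal stop in peptide")


def scan_orfs(
    t: TranscriptModel,
    genome,
    start_codons: Iterable = ("ATG",),
    min_len_aa: int = 2,
    max_len_aa: Optional[int] = None,
    source: str = "scan",
) -> list:
    """Enumerate every start->first-in-frame-stop ORF in all three frames.

    Candidates without an in-frame stop before the transcript end are
    excluded, as are candidates whose codons contain N (conservative
    treatment of assembly gaps).  Non-AUG starts still yield peptides
    beginning with initiator Met.  Nested starts sharing a stop each
    produce a record; see :func:`collapse_shared_stops`.
    """
    starts = {c.upper() for c in start_codons}
    seq = spliced_sequence(t, genome)
    records = []
    for frame in range(3):
        pending = []  # start offsets since last stop, this frame
        for p in range(frame, len(seq) - 2, 3):
            codon = seq[p:p + 3]
            if codon in STOP_CODONS:
                for s in pending:
                    rec = _make_record(t, seq, s, p + 3, frame, source,
                                       min_len_aa, max_len_aa)
                    if rec is not None:
                        records.append(rec)
                pending = []
            elif codon in starts:
                pending.append(p)
        # pending starts at transcript end lack an in-frame stop: dropped
    return records


def _make_record(t, seq, tx_start, tx_end, frame, source, min_len_aa, max_len_aa):
    orf_nt = seq[tx_start:tx_end]
    n_aa = len(orf_nt) // 3 - 1
    if n_aa < min_len_aa or (max_len_aa is not None and n_aa > max_len_aa):
        return None
    if "N" in orf_nt:
        return None
    peptide = translate(orf_nt[:-3])
    if orf_nt[:3] != "ATG":
        # initiator Met convention for near-cognate starts
        peptide = "M" + peptide[1:]
    if "*" in peptide:
        return None  # cannot happen for first-stop scans; defensive
    stop_key = (t.chrom_id, t.strand, tx_to_genome(t, tx_end - 1))
    orf_id = f"{t.transcript_id}|f{frame}|{tx_start}-{tx_end}"
    return OrfRecord(
        orf_id=orf_id,
        transcript_id=t.transcript_id,
        frame=frame,
        tx_start=tx_start,
        tx_end=tx_end,
        genome_stop_key=stop_key,
        peptide=peptide,
        start_codon=orf_nt[:3],
        source=source,
    )


def collapse_shared_stops(orfs: Iterable) -> list:
    """Keep only the longest candidate per distinct genomic stop site.

    Ties on peptide length are broken by the 5'-most start (smallest
    ``tx_start``), then lexicographic ``orf_id`` — deterministic for any
    input order.  Output preserves first-seen stop-key order.
    """
    best = {}
    order = []
    for rec in orfs:
        key = rec.genome_stop_key
        if key not in best:
            best[key] = rec
            order.append(key)
        else:
            cur = best[key]
            if (-len(rec.peptide), rec.tx_start, rec.orf_id) < (
                -len(cur.peptide), cur.tx_start, cur.orf_id
            ):
                best[key] = rec
    return [best[k] for k in order]


def dedupe_sequences(orfs: Iterable) -> list:
    """One record per distinct peptide string; first occurrence wins."""
    seen = set()
    out = []
    for rec in orfs:
        if rec.peptide not in seen:
            seen.add(rec.peptide)
            out.append(rec)
    return out
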