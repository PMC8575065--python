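"""Genomic-context categorization of non-canonical ORFs.

Each identified ORF is assigned exactly one category by a fixed-priority
decision cascade — the least-novel explanation wins:

1. **isoform** — shares its genomic stop site (and hence reading frame)
   with an annotated CDS while differing in sequence/structure;
2. **uORF** — entirely within the 5'UTR exons of a coding transcript;
3. **dORF** — entirely within the 3'UTR exons;
4. **ncRNA** — hosted on a transcript of non-coding biotype;
5. **altORF** — overlapping a coding transcript's exons otherwise (the
   typical case overlaps the CDS in a different frame or with a distinct
   stop); an ORF straddling a CDS boundary falls here, not in uORF/dORF;
6. **intergenic** — no exonic overlap with any same-strand transcript.

Frame comparison is splice-aware and performed per genomic base, because
transcript-relative frames are meaningless across different isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .orf_discovery import OrfRecord
from .sequence_io import TranscriptModel, genome_to_tx, project_to_genome

__all__ = ["ProjectedOrf", "CategoryCall", "project_orf", "categorize", "annotate_set",
           "CATEGORIES"]

CATEGORIES = ("isoform", "uORF", "dORF", "ncRNA", "altORF", "intergenic")


@dataclass(frozen=True)
class ProjectedOrf:
    """An ORF in genomic coordinates: sorted half-open blocks plus strand.

    ``stop_key`` is ``(chrom, strand, genomic coordinate of the last base
    of the stop codon)``, matching :class:`~orfkit.orf_discovery.OrfRecord`.
    """

    orf_id: str
    chrom: str
    strand: str
    blocks: tuple
    stop_key: tuple

    def __post_init__(self) -> None:
        blocks = tuple(sorted((int(s), int(e)) for s, e in self.blocks))
        if not blocks or any(e <= s for s, e in blocks):
            raise ValueError(f"{self.orf_id}: bad blocks")
        object.__setattr__(self, "blocks", blocks)

    @property
    def span_nt(self) -> int:
        return sum(e - s for s, e in self.blocks)

    def phase_of(self, gpos: int) -> int:
        """Codon phase (0/1/2) of a genomic base within this ORF."""
        ordered = self.blocks if self.strand == "+" else self.blocks[::-1]
        offset = 0
        for s, e in ordered:
            if s <= gpos < e:
                local = gpos - s if self.strand == "+" else e - 1 - gpos
                return (offset + local) % 3
            offset += e - s
        raise ValueError(f"{gpos} not inside ORF {self.orf_id}")


@dataclass(frozen=True)
class CategoryCall:
    orf_id: str
    category: str
    evidence: tuple
    frame_relation: str = "not_applicable"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category != "intergenic" and not self.evidence:
            raise ValueError(f"{self.orf_id}: non-intergenic call requires evidence")


def project_orf(orf: OrfRecord, transcript: TranscriptModel) -> ProjectedOrf:
    """Project a transcript-anchored ORF onto the genome."""
    if transcript.transcript_id != orf.transcript_id:
        raise ValueError("transcript does not match ORF")
    blocks = project_to_genome(transcript, orf.tx_start, orf.tx_end)
    return ProjectedOrf(
        orf_id=orf.orf_id,
        chrom=transcript.chrom_id,
        strand=transcript.strand,
        blocks=blocks,
        stop_key=orf.genome_stop_key,
    )


# ---------------------------------------------------------------------------
# interval helpers (fixture-scale annotation: plain scans are adequate)
# ---------------------------------------------------------------------------


def _overlaps(blocks_a: Sequence, blocks_b: Sequence) -> bool:
    for s1, e1 in blocks_a:
        for s2, e2 in blocks_b:
            if s1 < e2 and s2 < e1:
                return True
    return False


def _contained_in(blocks: Sequence, container: Sequence) -> bool:
    """True when every base of ``blocks`` lies inside ``container``."""
    for s, e in blocks:
        pos = s
        while pos < e:
            hit = next(((cs, ce) for cs, ce in container if cs <= pos < ce), None)
            if hit is None:
                return False
            pos = min(e, hit[1])
    return True


def _utr_blocks(t: TranscriptModel, which: str) -> tuple:
    if t.cds_span is None:
        return ()
    a, b = t.cds_span
    if which == "5p":
        return project_to_genome(t, 0, a) if a > 0 else ()
    return project_to_genome(t, b, t.spliced_length) if b < t.spliced_length else ()


def _cds_blocks(t: TranscriptModel) -> tuple:
    if t.cds_span is None:
        return ()
    return project_to_genome(t, *t.cds_span)


def _cds_stop_key(t: TranscriptModel) -> tuple:
    a, b = t.cds_span
    from .sequence_io import tx_to_genome

    return (t.chrom_id, t.strand, tx_to_genome(t, b - 1))


def _cds_phase_of(t: TranscriptModel, gpos: int) -> int:
    return (genome_to_tx(t, gpos) - t.cds_span[0]) % 3


def _frame_relation(orf: ProjectedOrf, t: TranscriptModel) -> str:
    """Compare codon phase of ORF vs annotated CDS on shared exonic bases."""
    cds = _cds_blocks(t)
    for s, e in orf.blocks:
        for cs, ce in cds:
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                return (
                    "same"
                    if orf.phase_of(lo) == _cds_phase_of(t, lo)
                    else "different"
                )
    return "not_applicable"


def categorize(orf: ProjectedOrf, annotation: Iterable) -> CategoryCall:
    """Assign one genomic-context category via the priority cascade.

    Only same-strand, same-chromosome exonic overlap counts; an ORF
    overlapping several genes is judged by the highest-priority rule that
    fires across all overlaps, with all supporting transcript ids listed
    as evidence.
    """
    candidates = [
        t
        for t in annotation
        if t.chrom_id == orf.chrom
        and t.strand == orf.strand
        and _overlaps(orf.blocks, t.exons)
    ]
    if not candidates:
        return CategoryCall(orf.orf_id, "intergenic", (), "not_applicable")

    coding = [t for t in candidates if t.is_coding]
    noncoding = [t for t in candidates if not t.is_coding]

    iso = sorted(
        t.transcript_id for t in coding if _cds_stop_key(t) == orf.stop_key
    )
    if iso:
        return CategoryCall(orf.orf_id, "isoform", tuple(iso), "same")

    up = sorted(
        t.transcript_id
        for t in coding
        if _utr_blocks(t, "5p") and _contained_in(orf.blocks, _utr_blocks(t, "5p"))
    )
    if up:
        return CategoryCall(orf.orf_id, "uORF", tuple(up), "not_applicable")

    down = sorted(
        t.transcript_id
        for t in coding
        if _utr_blocks(t, "3p") and _contained_in(orf.blocks, _utr_blocks(t, "3p"))
    )
    if down:
        return CategoryCall(orf.orf_id, "dORF", tuple(down), "not_applicable")

    if noncoding:
        return CategoryCall(
            orf.orf_id, "ncRNA",
            tuple(sorted(t.transcript_id for t in noncoding)), "not_applicable",
        )

    # remaining: overlaps coding transcript exons without satisfying 1-3
    relations = {t.transcript_id: _frame_relation(orf, t) for t in coding}
    overlap_cds = [tid for tid, rel in relations.items() if rel != "not_applicable"]
    if overlap_cds:
        rel = (
            "different"
            if any(relations[tid] == "different" for tid in overlap_cds)
            else "same"
        )
        return CategoryCall(orf.orf_id, "altORF", tuple(sorted(overlap_cds)), rel)
    return CategoryCall(
        orf.orf_id, "altORF",
        tuple(sorted(t.transcript_id for t in coding)), "not_applicable",
    )


def annotate_set(orfs: Iterable, annotation: Sequence):
    """Categorize a set of projected ORFs; returns (calls table, counts).

    The table is ordered by orf_id (deterministic regardless of input or
    annotation record order); ``counts`` is a Series over all categories.
    """
    annotation = list(annotation)
    calls = sorted(
        (categorize(o, annotation) for o in orfs), key=lambda c: c.orf_id
    )
    table = pd.DataFrame(
        {
            "orf_id": [c.orf_id for c in calls],
            "category": [c.category for c in calls],
            "evidence": [";".join(c.evidence) for c in calls],
            "frame_relation": [c.frame_relation for c in calls],
        }
    )
    counts = pd.Series(
        {cat: int((table["category"] == cat).sum()) if len(table) else 0
         for cat in CATEGORIES},
        name="n_orfs",
    )
    return table, counts
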