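"""Sequence and annotation I/O plus small-molecule-free sequence utilities.

This module is the coordinate and provenance backbone of the toolkit:

* FASTA reading/writing (delegated to Biopython) with a provenance-carrying
  header dialect ``>{source}|{accession} {description}`` used by the
  assembled search database, where ``source`` is one of
  ``ref | predA | predB | crap | host``.
* GFF3-style annotation reading (delegated to gffutils).  Input coordinates
  are 1-based inclusive; everything internal is 0-based half-open.
  Conversion happens only at the I/O boundary.
* Spliced-transcript sequence extraction, translation (standard genetic
  code only), reverse complement, restriction-site scanning and the
  in-frame tag-insert check used to verify knock-in constructs such as the
  11-aa HiBit tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeSequence",
    "TranscriptModel",
    "ProteinEntry",
    "TagCheckReport",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "write_annotation",
    "spliced_sequence",
    "tx_to_genome",
    "genome_to_tx",
    "project_to_genome",
    "reverse_complement",
    "translate",
    "clean_nucleotides",
    "find_restriction_sites",
    "check_tag_insert",
    "format_header",
    "parse_header",
]

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: mapping between internal source names and FASTA header prefixes
SOURCE_TO_PREFIX = {
    "reference": "ref",
    "predA": "predA",
    "predB": "predB",
    "contaminant": "crap",
    "host": "host",
}
PREFIX_TO_SOURCE = {v: k for k, v in SOURCE_TO_PREFIX.items()}

#: sources excluded from database composition statistics
CONTAMINANT_SOURCES = frozenset({"contaminant", "host"})


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (e.g. sequence before any header)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """A single chromosome/contig, uppercase over {A,C,G,T,N}."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.chrom_id:
            raise ValueError("chromosome id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise ValueError(f"{self.chrom_id}: empty sequence")
        bad = set(self.sequence) - NT_ALPHABET
        if bad:
            raise ValueError(f"{self.chrom_id}: characters outside ACGTN: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: the coordinate frame for ORF discovery.

    ``exons`` are genomic 0-based half-open intervals ordered 5'->3' in
    transcript orientation (genomically descending on the minus strand).
    ``cds_span`` is the transcript-relative half-open interval of the
    annotated CDS *including* its stop codon.
    """

    transcript_id: str
    gene_id: str
    chrom_id: str
    strand: str
    exons: tuple
    biotype: str = "protein_coding"
    cds_span: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons or any(e <= s for s, e in exons):
            raise ValueError(f"{self.transcript_id}: empty or inverted exon")
        genomic = sorted(exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.cds_span is not None:
            a, b = self.cds_span
            if not (0 <= a < b <= self.spliced_length):
                raise ValueError(f"{self.transcript_id}: cds_span outside transcript")
            if (b - a) % 3:
                raise ValueError(f"{self.transcript_id}: cds_span length not divisible by 3")
            object.__setattr__(self, "cds_span", (int(a), int(b)))

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None


@dataclass(frozen=True)
class ProteinEntry:
    """One database sequence with provenance.

    ``sources`` is a non-empty frozenset over
    {reference, predA, predB, contaminant, host}.
    """

    accession: str
    peptide: str
    sources: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        if not self.accession or any(c.isspace() for c in self.accession):
            raise ValueError(f"bad accession {self.accession!r}")
        bad = set(self.peptide) - AA_ALPHABET
        if bad:
            raise ValueError(f"{self.accession}: nonstandard residues {sorted(bad)}")
        sources = frozenset(self.sources)
        if not sources or sources - set(SOURCE_TO_PREFIX):
            raise ValueError(f"{self.accession}: bad sources {set(self.sources)}")
        object.__setattr__(self, "sources", sources)

    @property
    def length_class(self) -> str:
        """'small' for <=100 aa, 'large' for >100 aa."""
        return "small" if len(self.peptide) <= 100 else "large"

    @property
    def is_contaminant(self) -> bool:
        return bool(self.sources & CONTAMINANT_SOURCES)


@dataclass(frozen=True)
class TagCheckReport:
    insert_is_inframe: bool
    tag_peptide: str
    restriction_hits: tuple
    tagged_peptide: str = ""
    reason: str = ""

    @property
    def tag_length(self) -> int:
        return len(self.tag_peptide)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list:
    """Read a FASTA file into ``[(id, description, sequence), ...]``.

    Sequences are uppercase-normalized and record order is preserved.
    Duplicate ids are returned as-is but reported with a warning.  A
    sequence line before any header raises :class:`FastaParseError` naming
    the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path.name}:{lineno}: sequence data before any '>' header"
                )
            break
    records = []
    seen = set()
    dups = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append((rec.id, desc, str(rec.seq).upper()))
        if rec.id in seen:
            dups.add(rec.id)
        seen.add(rec.id)
    if dups:
        warnings.warn(f"duplicate FASTA ids in {path.name}: {sorted(dups)}")
    return records


def write_fasta(records: Iterable, path, width: int = 60) -> None:
    """Write ``(id, description, sequence)`` triples (or ProteinEntry) as FASTA."""
    seqrecs = []
    for rec in records:
        if isinstance(rec, ProteinEntry):
            rid, desc, seq = entry_to_fasta_fields(rec)
        else:
            rid, desc, seq = rec
        seqrecs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def format_header(entry: ProteinEntry) -> str:
    """Dialected header line (without '>') for a database entry."""
    rid, desc, _ = entry_to_fasta_fields(entry)
    return f"{rid} {desc}".strip()


def entry_to_fasta_fields(entry: ProteinEntry) -> tuple:
    prio = ["reference", "predA", "predB", "contaminant", "host"]
    primary = min(entry.sources, key=prio.index)
    rid = f"{SOURCE_TO_PREFIX[primary]}|{entry.accession}"
    desc = entry.description
    if len(entry.sources) > 1:
        tag = "sources=" + ",".join(sorted(entry.sources))
        desc = f"{desc} {tag}".strip() if tag not in desc else desc
    return rid, desc, entry.peptide


def parse_header(header_id: str, description: str = "") -> tuple:
    """Parse a dialected id into ``(sources, accession, description)``.

    Multi-source membership is recovered from a ``sources=...`` token in the
    description when present, else from the prefix alone.
    """
    if "|" not in header_id:
        raise ValueError(f"not a dialected header id: {header_id!r}")
    prefix, accession = header_id.split("|", 1)
    if prefix not in PREFIX_TO_SOURCE:
        raise ValueError(f"unknown source prefix {prefix!r} in {header_id!r}")
    sources = {PREFIX_TO_SOURCE[prefix]}
    clean_desc = []
    for token in description.split():
        if token.startswith("sources="):
            sources.update(token[len("sources="):].split(","))
        else:
            clean_desc.append(token)
    return frozenset(sources), accession, " ".join(clean_desc)


# ---------------------------------------------------------------------------
# annotation (GFF3-style)
# ---------------------------------------------------------------------------

_NCRNA_HINTS = ("ncrna", "lncrna", "lincrna", "mirna", "snorna", "snrna", "rrna", "trna")


def _normalize_biotype(raw: Optional[str], has_cds: bool) -> str:
    if raw is None:
        return "protein_coding" if has_cds else "ncRNA"
    low = raw.lower()
    if low == "protein_coding":
        return "protein_coding"
    if "pseudogene" in low:
        return "pseudogene"
    if any(h in low for h in _NCRNA_HINTS) or "non_coding" in low or "noncoding" in low:
        return "ncRNA"
    return "other"


def read_annotation(path, genome: Optional[Mapping] = None) -> list:
    """Read GFF3-style annotation into :class:`TranscriptModel` objects.

    Input coordinates are 1-based inclusive and converted here to 0-based
    half-open.  Any feature with direct exon children is treated as a
    transcript.  The transcript-relative ``cds_span`` is computed from CDS
    children and includes the stop codon as annotated; a CDS whose length
    is not divisible by 3 is dropped with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genome = _genome_mapping(genome) if genome is not None else None
    transcripts = []
    for feat in db.all_features():
        exon_feats = list(db.children(feat.id, featuretype="exon", level=1))
        if not exon_feats:
            continue
        exons = sorted((f.start - 1, f.end) for f in exon_feats)
        if genome is not None:
            chrom = genome.get(feat.seqid)
            if chrom is None:
                raise ValueError(f"{feat.id}: unknown chromosome {feat.seqid}")
            if exons[-1][1] > len(chrom) or exons[0][0] < 0:
                raise ValueError(f"{feat.id}: exon outside chromosome bounds")
        if feat.strand == "-":
            exons = exons[::-1]
        attrs = feat.attributes
        raw_bt = None
        for key in ("biotype", "transcript_biotype", "gene_biotype"):
            if key in attrs:
                raw_bt = attrs[key][0]
                break
        cds_feats = list(db.children(feat.id, featuretype="CDS", level=1))
        gene_id = attrs["Parent"][0] if "Parent" in attrs else feat.id
        t = TranscriptModel(
            transcript_id=feat.id,
            gene_id=gene_id,
            chrom_id=feat.seqid,
            strand=feat.strand,
            exons=tuple(exons),
            biotype=_normalize_biotype(raw_bt, bool(cds_feats)),
            cds_span=None,
        )
        if cds_feats:
            tx_positions = []
            for f in cds_feats:
                tx_positions.append(genome_to_tx(t, f.start - 1))
                tx_positions.append(genome_to_tx(t, f.end - 1))
            a, b = min(tx_positions), max(tx_positions) + 1
            if (b - a) % 3:
                warnings.warn(
                    f"{feat.id}: CDS length {b - a} not divisible by 3; cds_span dropped"
                )
            else:
                t = TranscriptModel(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    chrom_id=t.chrom_id,
                    strand=t.strand,
                    exons=t.exons,
                    biotype=t.biotype,
                    cds_span=(a, b),
                )
        transcripts.append(t)
    return transcripts


def write_annotation(transcripts: Sequence[TranscriptModel], path) -> None:
    """Export transcripts back to GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for t in transcripts:
        g_exons = sorted(t.exons)
        start, end = g_exons[0][0] + 1, g_exons[-1][1]
        lines.append(
            "\t".join(
                [
                    t.chrom_id, "orfkit", "transcript", str(start), str(end), ".",
                    t.strand, ".",
                    f"ID={t.transcript_id};Parent={t.gene_id};biotype={t.biotype}",
                ]
            )
        )
        for s, e in g_exons:
            lines.append(
                "\t".join(
                    [t.chrom_id, "orfkit", "exon", str(s + 1), str(e), ".", t.strand,
                     ".", f"Parent={t.transcript_id}"]
                )
            )
        if t.cds_span is not None:
            blocks = project_to_genome(t, *t.cds_span)
            offset = 0
            rows = []
            ordered = blocks if t.strand == "+" else blocks[::-1]
            for s, e in ordered:
                phase = (3 - offset % 3) % 3
                rows.append((s, e, phase))
                offset += e - s
            for s, e, phase in sorted(rows):
                lines.append(
                    "\t".join(
                        [t.chrom_id, "orfkit", "CDS", str(s + 1), str(e), ".",
                         t.strand, str(phase), f"Parent={t.transcript_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# coordinate plumbing
# ---------------------------------------------------------------------------


def _genome_mapping(genome) -> Mapping:
    if isinstance(genome, Mapping):
        return genome
    if isinstance(genome, GenomeSequence):
        return {genome.chrom_id: genome}
    return {g.chrom_id: g for g in genome}


def spliced_sequence(t: TranscriptModel, genome) -> str:
    """Exonic sequence in transcript orientation (minus strand revcomp'd)."""
    genome = _genome_mapping(genome)
    chrom = genome.get(t.chrom_id)
    if chrom is None:
        raise ValueError(f"{t.transcript_id}: missing chromosome {t.chrom_id}")
    parts = []
    for s, e in t.exons:
        if e > len(chrom):
            raise ValueError(f"{t.transcript_id}: exon [{s},{e}) beyond chromosome end")
        piece = chrom.sequence[s:e]
        parts.append(piece if t.strand == "+" else reverse_complement(piece))
    return "".join(parts)


def tx_to_genome(t: TranscriptModel, pos: int) -> int:
    """Genomic coordinate of transcript-relative base ``pos``."""
    if not 0 <= pos < t.spliced_length:
        raise ValueError(f"transcript position {pos} out of range")
    offset = pos
    for s, e in t.exons:
        length = e - s
        if offset < length:
            return s + offset if t.strand == "+" else e - 1 - offset
        offset -= length
    raise AssertionError("unreachable")


def genome_to_tx(t: TranscriptModel, gpos: int) -> int:
    """Transcript-relative coordinate of genomic base ``gpos`` (must be exonic)."""
    offset = 0
    for s, e in t.exons:
        if s <= gpos < e:
            return offset + (gpos - s if t.strand == "+" else e - 1 - gpos)
        offset += e - s
    raise ValueError(f"{t.transcript_id}: genomic position {gpos} not exonic")


def project_to_genome(t: TranscriptModel, tx_start: int, tx_end: int) -> tuple:
    """Project a transcript-relative interval to sorted genomic blocks.

    Returns a tuple of 0-based half-open genomic intervals, ascending.
    """
    if not 0 <= tx_start < tx_end <= t.spliced_length:
        raise ValueError("interval outside transcript")
    blocks = []
    offset = 0
    for s, e in t.exons:
        length = e - s
        lo = max(tx_start, offset)
        hi = min(tx_end, offset + length)
        if lo < hi:
            if t.strand == "+":
                blocks.append((s + (lo - offset), s + (hi - offset)))
            else:
                blocks.append((e - (hi - offset), e - (lo - offset)))
        offset += length
    return tuple(sorted(blocks))


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------


def reverse_complement(nt: str) -> str:
    return nt.upper().translate(_COMPLEMENT)[::-1]


def clean_nucleotides(raw: str) -> str:
    """Uppercase and drop every character outside ACGT.

    Published insert sequences are sometimes decorated with typographic
    separators (zero-width spaces, middle dots); those are formatting
    artifacts, not bases.
    """
    return "".join(c for c in raw.upper() if c in "ACGT")


def translate(nt: str, *, to_stop: bool = False) -> str:
    """Standard-genetic-code translation; stops render as ``*``.

    Length must be divisible by 3.  A codon containing an ambiguous base
    (anything outside ACGT) translates to ``X`` with a warning.
    """
    nt = nt.upper()
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    ambiguous = [i for i in range(0, len(nt), 3) if set(nt[i:i + 3]) - set("ACGT")]
    aa = str(Seq(nt).translate())
    if ambiguous:
        warnings.warn(f"{len(ambiguous)} codon(s) with ambiguous bases translated as X")
        aa = "".join(
            "X" if i * 3 in set(ambiguous) else c for i, c in enumerate(aa)
        )
    if to_stop and "*" in aa:
        aa = aa[: aa.index("*")]
    return aa


def find_restriction_sites(nt: str, pattern: str) -> list:
    """All occurrences of ``pattern`` on both strands of ``nt``.

    Returns ``[(strand, offset), ...]`` with offsets 0-based on the forward
    strand (start of the match as read on the forward strand).  Overlapping
    occurrences are reported; a palindromic pattern is reported once per
    strand.
    """
    nt = nt.upper()
    pattern = pattern.upper()
    if not pattern or set(pattern) - set("ACGT"):
        raise ValueError("pattern must be non-empty over ACGT")
    hits = []
    for strand, probe in (("+", pattern), ("-", reverse_complement(pattern))):
        start = nt.find(probe)
        while start != -1:
            hits.append((strand, start))
            start = nt.find(probe, start + 1)
    return sorted(hits, key=lambda h: (h[1], h[0]))


def check_tag_insert(orf_nt: str, insert_nt: str, pattern: str) -> TagCheckReport:
    """Verify an in-frame tag insertion immediately before the stop codon.

    ``orf_nt`` must end in a stop codon and translate without internal
    stops.  The report states whether the insert is in frame (length
    divisible by 3, stop-free translation), the tag peptide, the tagged
    ORF's translation (original peptide + tag), and restriction-site hits
    within the insert.
    """
    orf_nt = clean_nucleotides(orf_nt)
    insert_nt = clean_nucleotides(insert_nt)
    if len(orf_nt) % 3 or orf_nt[-3:] not in STOP_CODONS:
        raise ValueError("ORF must be in frame and end in a stop codon")
    orf_pep = translate(orf_nt[:-3])
    if "*" in orf_pep:
        raise ValueError("ORF translates with an internal stop")
    hits = tuple(find_restriction_sites(insert_nt, pattern)) if insert_nt else ()
    if len(insert_nt) % 3:
        return TagCheckReport(False, "", hits,
                              reason=f"insert length {len(insert_nt)} not divisible by 3")
    tag_pep = translate(insert_nt) if insert_nt else ""
    if "*" in tag_pep:
        return TagCheckReport(False, "", hits, reason="insert contains an internal stop")
    tagged = orf_nt[:-3] + insert_nt + orf_nt[-3:]
    tagged_pep = translate(tagged[:-3])
    return TagCheckReport(True, tag_pep, hits, tagged_peptide=tagged_pep)
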