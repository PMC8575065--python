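"""Deterministic synthetic genomes, annotation and tables with ground truth.

Every downstream module is testable without downloads: this generator
plants multi-exon coding genes with 5'/3'UTRs, ncRNA genes, and ORFs of
every genomic-context category (uORF, dORF, ncRNA, altORF, intergenic,
isoform) at known coordinates, builds two prediction sets whose length
medians are 25 and 45 aa by construction (the small-ORF vs alternative-ORF
regimes), a detectability fixture with a planted zero-unique-peptide
protein, a homology table with planted conserved queries, and per-engine
identification tables with a planted overlap structure.

All randomness flows through one ``numpy.random.Generator`` seeded from a
single integer: identical seed and spec give byte-identical outputs.  A
self-check pass runs at generation time: every planted ORF must be
rediscovered by the ORF scanner and recover its category before fixtures
ship.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import insilico_digest, orf_annotation, orf_discovery
from .database_assembly import AllOrfDatabase, assemble
from .sequence_io import (
    GenomeSequence,
    ProteinEntry,
    TranscriptModel,
    project_to_genome,
    translate,
    tx_to_genome,
    write_annotation,
    write_fasta,
)

__all__ = ["FixtureSpec", "Fixture", "FixtureError", "generate",
           "plant_undetectable_protein", "make_detectability_fixture"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")
_CODONS61 = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)


class FixtureError(RuntimeError):
    """Raised when a spec is infeasible or a planted construction fails."""


@dataclass(frozen=True)
class FixtureSpec:
    """The stated world the generator emulates.

    Defaults mirror the conditions the toolkit targets: prediction-set
    length medians of 25 aa (small-ORF regime) and 45 aa (alternative-ORF
    regime), roughly 30% of prediction sequences shared between the two
    sets (~70% unique to one), a 1-in-5 zero-unique-peptide fraction in
    the detectability fixture, 85 homology queries with 18 planted
    conserved across four model-organism databases, and a two-engine
    identification overlap of 68 common / 87 vs 119 unique.
    """

    seed: int = 1
    n_coding_genes: int = 6
    n_ncrna_genes: int = 3
    planted_orfs: Mapping = field(
        default_factory=lambda: {
            "uORF": 2, "dORF": 1, "ncRNA": 2, "altORF": 2,
            "intergenic": 2, "isoform": 1,
        }
    )
    predA_median: int = 45
    predB_median: int = 25
    prediction_pairs: int = 10
    n_shared_predictions: int = 9
    intergenic_spacing: int = 80
    chrom_len: Optional[int] = None
    n_detectability_predictions: int = 5
    n_undetectable: int = 1
    n_homology_queries: int = 85
    n_conserved: int = 18
    species_dbs: tuple = ("human", "mouse", "fly", "zebrafish")
    id_n_common: int = 68
    id_n_uniqueA: int = 87
    id_n_uniqueB: int = 119
    id_engines: tuple = ("engineA", "engineB")

    def validate(self) -> None:
        counts = dict(self.planted_orfs)
        unknown = set(counts) - set(orf_annotation.CATEGORIES)
        if unknown:
            raise FixtureError(f"unknown planted categories {sorted(unknown)}")
        if any(v < 0 for v in counts.values()):
            raise FixtureError("planted counts must be non-negative")
        if counts.get("ncRNA", 0) and self.n_ncrna_genes < 1:
            raise FixtureError("ncRNA ORFs planted but no ncRNA genes")
        transcript_cats = {"uORF", "dORF", "altORF", "isoform"}
        if any(counts.get(c, 0) for c in transcript_cats) and self.n_coding_genes < 1:
            raise FixtureError("transcript-hosted ORFs planted but no coding genes")
        if self.intergenic_spacing < 50:
            raise FixtureError("intergenic spacing below 50 nt breaks category rules")
        if self.n_undetectable > self.n_detectability_predictions:
            raise FixtureError("more undetectable plants than predictions")
        if self.n_conserved > self.n_homology_queries:
            raise FixtureError("more conserved plants than queries")

    @classmethod
    def from_yaml(cls, path) -> "FixtureSpec":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("planted_orfs",):
            if key in data and data[key] is not None:
                data[key] = dict(data[key])
        for key in ("species_dbs", "id_engines"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class Fixture:
    """Everything generate() produced, in memory, plus ground truth."""

    spec: FixtureSpec
    genome: dict
    transcripts: list          # annotated transcripts (GFF3 content)
    carriers: dict             # orf_id -> unannotated carrier TranscriptModel
    truth_orfs: pd.DataFrame   # orf_id, category, peptide, tx interval, stop key
    projected: list            # ProjectedOrf per truth row, same order
    reference: list            # (accession, peptide) of the reference proteome
    predA: list
    predB: list
    detectability_db: AllOrfDatabase
    undetectable_accessions: list
    homology: pd.DataFrame
    conserved_queries: set
    id_tables: dict            # engine -> DataFrame
    id_truth: dict             # engine -> planted accession set
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# low-level random sequence helpers
# ---------------------------------------------------------------------------


def _dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _codons(rng, n: int) -> str:
    return "".join(_CODONS61[i] for i in rng.integers(0, len(_CODONS61), n))


def _orf_nt(rng, aa_len: int) -> str:
    return "ATG" + _codons(rng, aa_len - 1) + _STOPS[rng.integers(0, 3)]


def _peptide(rng, length: int) -> str:
    return "M" + "".join(AA20[i] for i in rng.integers(0, 20, length - 1))


def _frameshift_region(rng, alt_aa: int, max_attempts: int = 500) -> tuple:
    """A 3n-nt region whose +1 frame holds a clean ORF and whose own frame
    is stop-free.  Returns (region_nt, offset_of_alt_orf_within_region)."""
    for _ in range(max_attempts):
        alt = _orf_nt(rng, alt_aa)
        region = _dna(rng, 1) + alt + _dna(rng, 2)
        if "*" not in translate(region):
            return region, 1
    raise FixtureError("could not construct frame-shifted region")


# ---------------------------------------------------------------------------
# gene cassette construction
# ---------------------------------------------------------------------------


@dataclass
class _Draft:
    """A transcript drafted in spliced coordinates before genome placement."""

    name: str
    strand: str
    spliced: str
    biotype: str
    cds_span: Optional[tuple]
    plants: list               # (category, tx_start, tx_end)
    intron_at: Optional[int] = None   # transcript position of the intron, if any
    intron_len: int = 0


def _draft_coding_gene(rng, name: str, strand: str, plant_cats: list) -> _Draft:
    plants = []
    utr5_len = int(rng.integers(60, 121))
    utr5 = _dna(rng, utr5_len)
    if "uORF" in plant_cats:
        k = int(rng.integers(5, 16))
        orf = _orf_nt(rng, k)
        off = int(rng.integers(0, utr5_len - len(orf) + 1))
        utr5 = utr5[:off] + orf + utr5[off + len(orf):]
        plants.append(("uORF", off, off + len(orf)))

    cds_aa = int(rng.integers(50, 91))
    body_codons = [_codons(rng, 1) for _ in range(cds_aa - 1)]
    alt_info = None
    if "altORF" in plant_cats:
        alt_aa = int(rng.integers(12, 25))
        region, alt_off = _frameshift_region(rng, alt_aa)
        n_region = len(region) // 3
        # leave room for an isoform start upstream of the shifted region
        pre = int(rng.integers(12, cds_aa - 1 - n_region - 3))
        region_codons = [region[i:i + 3] for i in range(0, len(region), 3)]
        body_codons = (
            [_codons(rng, 1) for _ in range(pre)]
            + region_codons
            + [_codons(rng, 1) for _ in range(cds_aa - 1 - pre - n_region)]
        )
        alt_info = (3 + 3 * pre + alt_off, 3 * (alt_aa + 1))
    if "isoform" in plant_cats:
        lo = 8
        hi = len(body_codons) - 8
        if alt_info is not None:
            # keep the internal start clear of the frame-shifted region
            hi = min(hi, (alt_info[0] - 3) // 3 - 1)
        j = int(rng.integers(lo, max(lo + 1, hi)))
        body_codons[j] = "ATG"
    cds_nt = "ATG" + "".join(body_codons) + "TAA"
    assert "*" not in translate(cds_nt[:-3]), "internal stop in drafted CDS"
    cds_start = utr5_len
    cds_end = cds_start + len(cds_nt)
    if alt_info is not None:
        a0, alen = alt_info
        plants.append(("altORF", cds_start + a0, cds_start + a0 + alen))
    if "isoform" in plant_cats:
        iso_start = cds_start + 3 * (1 + j)
        plants.append(("isoform", iso_start, cds_end))

    utr3_len = int(rng.integers(60, 121))
    utr3 = _dna(rng, utr3_len)
    if "dORF" in plant_cats:
        k = int(rng.integers(5, 16))
        orf = _orf_nt(rng, k)
        off = int(rng.integers(0, utr3_len - len(orf) + 1))
        utr3 = utr3[:off] + orf + utr3[off + len(orf):]
        plants.append(("dORF", cds_end + off, cds_end + off + len(orf)))

    spliced = utr5 + cds_nt + utr3
    draft = _Draft(name, strand, spliced, "protein_coding",
                   (cds_start, cds_end), plants)
    # roughly half the coding genes get an intron inside the CDS
    if rng.random() < 0.5:
        draft.intron_at = cds_start + 3 * int(rng.integers(5, 20)) + 1
        draft.intron_len = int(rng.integers(40, 81))
    return draft


def _draft_ncrna_gene(rng, name: str, strand: str, plant: bool) -> _Draft:
    pad1, pad2 = _dna(rng, int(rng.integers(30, 61))), _dna(rng, int(rng.integers(30, 61)))
    plants = []
    if plant:
        k = int(rng.integers(8, 20))
        orf = _orf_nt(rng, k)
        plants.append(("ncRNA", len(pad1), len(pad1) + len(orf)))
        spliced = pad1 + orf + pad2
    else:
        spliced = pad1 + pad2
    return _Draft(name, strand, spliced, "ncRNA", None, plants)


def _place(draft: _Draft, chrom: str, start: int) -> tuple:
    """Lay a draft onto the genome at ``start``; returns (segment, transcript)."""
    from .sequence_io import reverse_complement

    if draft.intron_at is None:
        pieces_tx = [draft.spliced]
    else:
        pieces_tx = [draft.spliced[: draft.intron_at], draft.spliced[draft.intron_at:]]
    intron = _STATIC_INTRON[: draft.intron_len]
    if draft.strand == "+":
        segment = intron.join(pieces_tx) if len(pieces_tx) > 1 else pieces_tx[0]
        exons, pos = [], start
        for i, piece in enumerate(pieces_tx):
            exons.append((pos, pos + len(piece)))
            pos += len(piece) + (draft.intron_len if i == 0 and len(pieces_tx) > 1 else 0)
    else:
        genomic_pieces = [reverse_complement(p) for p in pieces_tx[::-1]]
        segment = intron.join(genomic_pieces) if len(pieces_tx) > 1 else genomic_pieces[0]
        bounds, pos = [], start
        for i, piece in enumerate(genomic_pieces):
            bounds.append((pos, pos + len(piece)))
            pos += len(piece) + (draft.intron_len if i == 0 and len(pieces_tx) > 1 else 0)
        exons = bounds[::-1]  # transcript order: 5'->3' = genomically descending
    t = TranscriptModel(
        transcript_id=draft.name,
        gene_id=draft.name.rsplit(".", 1)[0],
        chrom_id=chrom,
        strand=draft.strand,
        exons=tuple(exons),
        biotype=draft.biotype,
        cds_span=draft.cds_span,
    )
    return segment, t


# introns are non-functional filler; a fixed string keeps placement simple
_STATIC_INTRON = ("GT" + "C" * 96 + "AG") * 2


# ---------------------------------------------------------------------------
# detectability fixture
# ---------------------------------------------------------------------------


def _tryptic_fragment(rng, length: int) -> str:
    """A fragment ending in K with no internal cleavage site and no P start."""
    inner = "".join(
        AA20.replace("K", "").replace("R", "").replace("P", "")[i]
        for i in rng.integers(0, 17, length - 1)
    )
    frag = inner + "K"
    return frag if frag[0] != "P" else "A" + frag[1:]


def plant_undetectable_protein(rng, n_fragments: int = 3, max_attempts: int = 50):
    """Construct (prediction, host) where the prediction has zero unique
    in-window tryptic peptides under the default digest configuration.

    The prediction is a concatenation of K-terminated fragments; the host
    embeds the identical fragment run, so every digestion product of the
    prediction (0 or 1 missed cleavage) also arises from the host.
    Verified by running the digest module; bounded attempts, then error.
    """
    cfg = insilico_digest.DigestConfig()
    for _ in range(max_attempts):
        frags = [_tryptic_fragment(rng, int(rng.integers(8, 13)))
                 for _ in range(n_fragments)]
        pred_pep = "".join(frags)
        tail = "A" + _peptide(rng, 25)[1:]  # host-specific unique material
        host_pep = pred_pep + tail
        db = assemble(predA=[("PLANT", pred_pep)], host=[("CARRIER", host_pep)])
        _, report = insilico_digest.digest_database(db, cfg)
        per = report.per_protein.set_index("accession")["n_unique"]
        if per["PLANT"] == 0:
            return ("PLANT", pred_pep), ("CARRIER", host_pep)
    raise FixtureError("failed to plant an undetectable protein")


def make_detectability_fixture(
    rng,
    n_predictions: int = 5,
    n_undetectable: int = 1,
    max_attempts: int = 50,
) -> tuple:
    """An assembled database whose predA zero-unique fraction is exactly
    ``n_undetectable / n_predictions``.  Returns (db, undetectable_accs)."""
    for _ in range(max_attempts):
        preds, hosts, planted = [], [], []
        for i in range(n_undetectable):
            (p_acc, p_pep), (h_acc, h_pep) = plant_undetectable_protein(rng)
            acc = f"pred_undet_{i}"
            preds.append((acc, p_pep))
            hosts.append((f"host_carrier_{i}", h_pep))
            planted.append(acc)
        for i in range(n_predictions - n_undetectable):
            preds.append((f"pred_det_{i}", _peptide(rng, int(rng.integers(40, 61)))))
        db = assemble(predA=preds, host=hosts)
        _, report = insilico_digest.digest_database(db)
        per = report.per_protein.set_index("accession")["n_unique"]
        ok_detectable = all(
            per[acc] > 0 for acc, _ in preds if acc not in planted
        )
        ok_planted = all(per[acc] == 0 for acc in planted)
        if ok_detectable and ok_planted:
            return db, planted
    raise FixtureError("failed to build detectability fixture")


# ---------------------------------------------------------------------------
# prediction sets with exact planted medians
# ---------------------------------------------------------------------------


def _unique_peptides(rng, lengths, taken: set) -> list:
    out = []
    for L in lengths:
        pep = _peptide(rng, int(L))
        while pep in taken:
            pep = _peptide(rng, int(L))
        taken.add(pep)
        out.append(pep)
    return out


def _prediction_sets(rng, spec: FixtureSpec) -> tuple:
    s, pairs = spec.n_shared_predictions, spec.prediction_pairs
    shared_len = (spec.predA_median + spec.predB_median) // 2
    if not spec.predB_median < shared_len < spec.predA_median:
        raise FixtureError("shared-prediction length must sit between the medians")
    taken: set = set()
    shared = _unique_peptides(rng, [shared_len] * s, taken)

    a_low = [spec.predA_median - int(x) for x in rng.integers(1, 41, pairs)]
    a_high = [spec.predA_median + int(x) for x in rng.integers(1, 41, pairs)]
    a_extra = [int(x) for x in rng.integers(spec.predA_median + 1,
                                            spec.predA_median + 46, s)]
    predA_own = _unique_peptides(rng, [spec.predA_median] + a_low + a_high + a_extra,
                                 taken)

    b_low = [spec.predB_median - int(x) for x in rng.integers(1, 21, pairs)]
    b_high = [spec.predB_median + int(x) for x in rng.integers(1, 21, pairs)]
    b_extra = [int(x) for x in rng.integers(5, spec.predB_median, s)]
    predB_own = _unique_peptides(rng, [spec.predB_median] + b_low + b_high + b_extra,
                                 taken)

    predA = [(f"altp_{i:04d}", pep) for i, pep in enumerate(predA_own + shared)]
    predB = [(f"sorf_{i:04d}", pep) for i, pep in enumerate(predB_own + shared)]
    return predA, predB


# ---------------------------------------------------------------------------
# homology and identification tables
# ---------------------------------------------------------------------------


def _homology_table(rng, spec: FixtureSpec) -> tuple:
    queries = [f"cand_{i:03d}" for i in range(spec.n_homology_queries)]
    conserved = set(
        queries[i] for i in rng.choice(len(queries), spec.n_conserved, replace=False)
    )
    rows = []
    for q in queries:
        if q in conserved:
            n_sp = int(rng.integers(1, len(spec.species_dbs) + 1))
            for sp in rng.choice(spec.species_dbs, n_sp, replace=False):
                best_e = 10.0 ** -int(rng.integers(11, 41))
                rows.append(_hit_row(rng, q, sp, best_e, best=True))
                if rng.random() < 0.5:  # a worse decoy hit for tie-break exercise
                    rows.append(_hit_row(rng, q, sp, best_e * 10, best=False))
        elif rng.random() < 0.5:
            sp = spec.species_dbs[int(rng.integers(0, len(spec.species_dbs)))]
            weak_e = 10.0 ** -int(rng.integers(2, 10))  # above the 1e-10 bar
            rows.append(_hit_row(rng, q, sp, weak_e, best=False))
    table = pd.DataFrame(rows)
    return table, conserved


def _hit_row(rng, q, sp, evalue, best):
    return {
        "query_id": q,
        "subject_id": f"{sp}_{int(rng.integers(0, 99999)):05d}",
        "percent_identity": round(float(rng.uniform(30, 95)), 1),
        "length": int(rng.integers(15, 120)),
        "mismatches": int(rng.integers(0, 30)),
        "gap_opens": int(rng.integers(0, 4)),
        "q_start": 1, "q_end": 20, "s_start": 1, "s_end": 20,
        "evalue": evalue,
        "bitscore": round(float(rng.uniform(40, 200)), 1),
        "species_db": sp,
    }


def _identification_tables(rng, spec: FixtureSpec) -> tuple:
    common = [f"nc_common_{i:03d}" for i in range(spec.id_n_common)]
    uniqueA = [f"nc_onlyA_{i:03d}" for i in range(spec.id_n_uniqueA)]
    uniqueB = [f"nc_onlyB_{i:03d}" for i in range(spec.id_n_uniqueB)]
    engineA, engineB = spec.id_engines
    truth = {engineA: set(common + uniqueA), engineB: set(common + uniqueB)}
    tables = {}
    for engine, accs in ((engineA, common + uniqueA), (engineB, common + uniqueB)):
        rows = [
            {
                "accession": acc,
                "n_unique_peptides": int(rng.integers(1, 11)),
                "condition": "WL",
                "engine": engine,
                "replicate": "r1",
                "is_subgroup": False,
            }
            for acc in accs
        ]
        # filter fodder: contaminants, zero-unique rows, subgroup rows
        rows.append({"accession": "crap|KRT1_HUMAN", "n_unique_peptides": 5,
                     "condition": "WL", "engine": engine, "replicate": "r1",
                     "is_subgroup": False})
        rows.append({"accession": f"nc_zero_{engine}", "n_unique_peptides": 0,
                     "condition": "WL", "engine": engine, "replicate": "r1",
                     "is_subgroup": False})
        rows.append({"accession": f"nc_sub_{engine}", "n_unique_peptides": 3,
                     "condition": "WL", "engine": engine, "replicate": "r1",
                     "is_subgroup": True})
        tables[engine] = pd.DataFrame(rows)
    return tables, truth


# ---------------------------------------------------------------------------
# generation driver
# ---------------------------------------------------------------------------


def generate(spec: FixtureSpec = FixtureSpec(), outdir=None) -> Fixture:
    """Build the full fixture; optionally write it under ``outdir``.

    Raises :class:`FixtureError` before writing any file when the spec is
    infeasible or a self-check fails.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chrom = "chrI"

    # --- draft and place genes ------------------------------------------
    per_gene_plants = [[] for _ in range(spec.n_coding_genes)]
    for cat in ("uORF", "dORF", "altORF", "isoform"):
        for k in range(spec.planted_orfs.get(cat, 0)):
            per_gene_plants[k % spec.n_coding_genes].append(cat)
    for plants in per_gene_plants:
        if plants.count("altORF") > 1 or plants.count("isoform") > 1:
            raise FixtureError(
                "at most one altORF and one isoform per gene; add coding genes"
            )

    drafts = []
    for i, plants in enumerate(per_gene_plants):
        strand = "-" if i % 3 == 2 else "+"
        drafts.append(_draft_coding_gene(rng, f"tx_coding_{i}.1", strand, plants))
    n_nc_plants = spec.planted_orfs.get("ncRNA", 0)
    for i in range(spec.n_ncrna_genes):
        strand = "-" if i % 2 else "+"
        want = sum(1 for k in range(n_nc_plants) if k % spec.n_ncrna_genes == i)
        if want > 1:
            raise FixtureError("at most one ncRNA ORF per ncRNA gene; add genes")
        drafts.append(_draft_ncrna_gene(rng, f"tx_ncrna_{i}.1", strand, want == 1))

    parts, cursor = [], 0
    transcripts, plant_records = [], []
    for draft in drafts:
        spacer = spec.intergenic_spacing + int(rng.integers(0, 40))
        parts.append(_dna(rng, spacer))
        cursor += spacer
        segment, t = _place(draft, chrom, cursor)
        parts.append(segment)
        cursor += len(segment)
        transcripts.append(t)
        for cat, s, e in draft.plants:
            plant_records.append((cat, t, s, e))

    # --- intergenic ORFs -------------------------------------------------
    carriers: dict = {}
    intergenic_records = []
    for k in range(spec.planted_orfs.get("intergenic", 0)):
        spacer = spec.intergenic_spacing + int(rng.integers(0, 40))
        parts.append(_dna(rng, spacer))
        cursor += spacer
        strand = "-" if k % 2 else "+"
        orf = _orf_nt(rng, int(rng.integers(8, 25)))
        pad1, pad2 = _dna(rng, 10), _dna(rng, 10)
        cassette_tx = pad1 + orf + pad2
        if strand == "+":
            segment = cassette_tx
        else:
            from .sequence_io import reverse_complement

            segment = reverse_complement(cassette_tx)
        start = cursor
        parts.append(segment)
        cursor += len(segment)
        carrier = TranscriptModel(
            transcript_id=f"carrier_intergenic_{k}",
            gene_id=f"carrier_intergenic_{k}",
            chrom_id=chrom,
            strand=strand,
            exons=((start, start + len(segment)),),
            biotype="other",
            cds_span=None,
        )
        intergenic_records.append(("intergenic", carrier, len(pad1), len(pad1) + len(orf)))
    parts.append(_dna(rng, spec.intergenic_spacing))
    cursor += spec.intergenic_spacing

    sequence = "".join(parts)
    if spec.chrom_len is not None:
        if len(sequence) > spec.chrom_len:
            raise FixtureError(
                f"planted content needs {len(sequence)} nt but chrom_len is "
                f"{spec.chrom_len}"
            )
        sequence += _dna(rng, spec.chrom_len - len(sequence))
    genome = {chrom: GenomeSequence(chrom, sequence)}

    # --- project truths and self-check -----------------------------------
    truth_rows, projected = [], []
    for cat, t, s, e in plant_records + intergenic_records:
        blocks = project_to_genome(t, s, e)
        stop_key = (t.chrom_id, t.strand, tx_to_genome(t, e - 1))
        orf_id = f"{t.transcript_id}|{cat}|{s}-{e}"
        nt = _spliced_slice(t, genome, s, e)
        projected.append(
            orf_annotation.ProjectedOrf(orf_id, t.chrom_id, t.strand, blocks, stop_key)
        )
        truth_rows.append(
            {
                "orf_id": orf_id, "category": cat,
                "transcript_id": t.transcript_id,
                "tx_start": s, "tx_end": e,
                "stop_chrom": stop_key[0], "stop_strand": stop_key[1],
                "stop_pos": stop_key[2],
                "peptide": translate(nt[:-3]),
            }
        )
        carriers[orf_id] = t
    truth = pd.DataFrame(truth_rows)

    annotated = [t for t in transcripts]  # carriers stay unannotated
    _self_check_orfs(truth, carriers, genome)
    _self_check_categories(truth, projected, annotated)

    # --- proteomes, predictions, tables ----------------------------------
    reference = []
    for t in annotated:
        if t.cds_span is None:
            continue
        cds_nt = _spliced_slice(t, genome, *t.cds_span)
        reference.append((f"ref_{t.transcript_id}", translate(cds_nt[:-3])))
    predA, predB = _prediction_sets(rng, spec)
    det_db, undet = make_detectability_fixture(
        rng, spec.n_detectability_predictions, spec.n_undetectable
    )
    homology, conserved = _homology_table(rng, spec)
    id_tables, id_truth = _identification_tables(rng, spec)

    fx = Fixture(
        spec=spec, genome=genome, transcripts=annotated, carriers=carriers,
        truth_orfs=truth, projected=projected, reference=reference,
        predA=predA, predB=predB, detectability_db=det_db,
        undetectable_accessions=undet, homology=homology,
        conserved_queries=conserved, id_tables=id_tables, id_truth=id_truth,
    )
    if outdir is not None:
        fx.manifest = _write_fixture(fx, Path(outdir))
    return fx


def _spliced_slice(t, genome, s, e) -> str:
    from .sequence_io import spliced_sequence

    return spliced_sequence(t, genome)[s:e]


def _self_check_orfs(truth: pd.DataFrame, carriers: dict, genome) -> None:
    """Every planted ORF must be rediscovered by the scanner (exact
    transcript interval) before fixtures ship."""
    for row in truth.itertuples():
        t = carriers[row.orf_id]
        found = orf_discovery.scan_orfs(t, genome, min_len_aa=2, max_len_aa=None)
        if not any(r.tx_start == row.tx_start and r.tx_end == row.tx_end
                   for r in found):
            raise FixtureError(f"planted ORF {row.orf_id} not rediscovered by scan")


def _self_check_categories(truth, projected, annotation) -> None:
    table, _ = orf_annotation.annotate_set(projected, annotation)
    got = dict(zip(table["orf_id"], table["category"]))
    for row in truth.itertuples():
        if got.get(row.orf_id) != row.category:
            raise FixtureError(
                f"planted {row.orf_id}: expected {row.category}, "
                f"categorized {got.get(row.orf_id)}"
            )


def _write_fixture(fx: Fixture, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _done(name):
        paths[name] = str(outdir / name)

    write_fasta(
        [(cid, "", g.sequence) for cid, g in fx.genome.items()],
        outdir / "genome.fa",
    )
    _done("genome.fa")
    write_annotation(fx.transcripts, outdir / "annotation.gff3")
    _done("annotation.gff3")
    for name, pool, source in (
        ("reference.fa", fx.reference, "reference"),
        ("predA.fa", fx.predA, "predA"),
        ("predB.fa", fx.predB, "predB"),
    ):
        write_fasta(
            [ProteinEntry(acc, pep, frozenset({source})) for acc, pep in pool],
            outdir / name,
        )
        _done(name)
    fx.detectability_db.to_fasta(outdir / "detectability.fa")
    _done("detectability.fa")
    fx.truth_orfs.to_csv(outdir / "truth_orfs.tsv", sep="\t", index=False)
    _done("truth_orfs.tsv")
    fx.homology.to_csv(outdir / "homology.tsv", sep="\t", index=False, header=False)
    _done("homology.tsv")
    pd.DataFrame({"query_id": sorted(fx.conserved_queries)}).to_csv(
        outdir / "truth_conserved.tsv", sep="\t", index=False
    )
    _done("truth_conserved.tsv")
    for engine, table in fx.id_tables.items():
        name = f"ids_{engine}.tsv"
        table.to_csv(outdir / name, sep="\t", index=False)
        _done(name)

    manifest = {
        "seed": fx.spec.seed,
        "files": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in paths.items()
        },
        "n_transcripts": len(fx.transcripts),
        "n_planted_orfs": int(len(fx.truth_orfs)),
        "undetectable_accessions": list(fx.undetectable_accessions),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
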