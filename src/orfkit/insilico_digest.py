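"""In-silico protease digestion and unique-peptide detectability accounting.

Bottom-up proteomics only sees a protein through its digestion products, so
a database entry without a single *unique* in-window peptide is effectively
undetectable however abundant the protein.  This module cleaves every
database entry with trypsin or chymotrypsin, applies the mass and length
windows typical of a tryptic shotgun run (600-4000 Da monoisotopic,
7-30 aa, one missed cleavage by default), pools identical peptide strings
across parents and reports the unique-peptide count per protein together
with the zero-unique fraction per source and length class.

Masses are monoisotopic and unmodified; an optional fixed modification
mass on cysteine (e.g. +57.02146 for carbamidomethylation) can be added
via the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .sequence_io import AA_ALPHABET

__all__ = [
    "DigestConfig",
    "PeptideRecord",
    "DetectabilityReport",
    "cleave",
    "cleavage_sites",
    "monoisotopic_mass",
    "digest_database",
    "RESIDUE_MONOISOTOPIC",
    "WATER_MONOISOTOPIC",
]

#: monoisotopic residue (amino-acid minus water) masses, Da
RESIDUE_MONOISOTOPIC = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}
WATER_MONOISOTOPIC = 18.0105646863

#: cleavage specificity: residues cut after, residues blocking when next
ENZYME_RULES = {
    "trypsin": (frozenset("KR"), frozenset("P")),
    "chymotrypsin": (frozenset("FWYL"), frozenset("P")),
    # stricter chymotrypsin variant, selectable via DigestConfig.enzyme
    "chymotrypsin-fwy": (frozenset("FWY"), frozenset("P")),
}


@dataclass(frozen=True)
class DigestConfig:
    """Digestion parameters; defaults match a standard tryptic evaluation."""

    enzyme: str = "trypsin"
    missed_cleavages: int = 1
    mass_min: float = 600.0
    mass_max: float = 4000.0
    len_min: int = 7
    len_max: int = 30
    il_equivalence: bool = False
    cys_fixed_mod: float = 0.0

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYME_RULES:
            raise ValueError(f"unknown enzyme {self.enzyme!r}")
        if not self.mass_min < self.mass_max:
            raise ValueError("mass_min must be below mass_max")
        if not self.len_min <= self.len_max:
            raise ValueError("len_min must not exceed len_max")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")


@dataclass(frozen=True)
class PeptideRecord:
    peptide: str
    parents: frozenset
    mass: float
    n_missed: int

    @property
    def unique(self) -> bool:
        return len(self.parents) == 1


@dataclass
class DetectabilityReport:
    """Unique-peptide counts per protein plus zero-unique fractions.

    ``per_protein`` has one row per database entry (accession, sources,
    length_class, n_unique, n_peptides); ``by_group`` aggregates the
    zero-unique fraction per source and length class.  An entry with
    multi-source membership contributes to each of its source groups.
    """

    per_protein: pd.DataFrame
    by_group: pd.DataFrame

    @property
    def zero_unique_fraction(self) -> float:
        if len(self.per_protein) == 0:
            return float("nan")
        return float((self.per_protein["n_unique"] == 0).mean())

    def zero_unique_fraction_for(self, source: str) -> float:
        sub = self.per_protein[self.per_protein["sources"].map(lambda s: source in s)]
        if len(sub) == 0:
            return float("nan")
        return float((sub["n_unique"] == 0).mean())


def cleavage_sites(p: str, enzyme: str) -> list:
    """Internal cut positions (between p[i-1] and p[i]) for the enzyme rule."""
    cut_after, block_next = ENZYME_RULES[enzyme]
    return [
        i for i in range(1, len(p))
        if p[i - 1] in cut_after and p[i] not in block_next
    ]


def cleave(p: str, enzyme: str = "trypsin", missed_cleavages: int = 0) -> list:
    """All digestion products with up to ``missed_cleavages`` uncut sites.

    Returns ``[(peptide, n_missed), ...]`` ordered by start position then
    span.  With ``missed_cleavages=0`` the products tile the parent.
    """
    if not p:
        raise ValueError("empty peptide")
    bad = set(p) - AA_ALPHABET
    if bad:
        raise ValueError(f"nonstandard residues {sorted(bad)}")
    bounds = [0] + cleavage_sites(p, enzyme) + [len(p)]
    out = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            out.append((p[bounds[i]:bounds[j]], j - i - 1))
    return out


def monoisotopic_mass(p: str, cys_fixed_mod: float = 0.0) -> float:
    """Sum of residue monoisotopic masses plus one water, Da."""
    if not p:
        raise ValueError("empty peptide has no mass")
    try:
        mass = sum(RESIDUE_MONOISOTOPIC[c] for c in p) + WATER_MONOISOTOPIC
    except KeyError as exc:
        raise ValueError(f"nonstandard residue {exc.args[0]!r} in {p!r}") from exc
    if cys_fixed_mod:
        mass += cys_fixed_mod * p.count("C")
    return mass


def digest_database(db, cfg: DigestConfig = DigestConfig()):
    """Digest every entry, pool identical peptides, count unique peptides.

    Peptides outside the length or mass windows are discarded before
    pooling.  Identical strings (after optional I->L collapsing) from
    different proteins merge into one record with the union of parents;
    uniqueness is evaluated after pooling, so the result is invariant to
    input order.  Returns ``(peptides, report)``.
    """
    pool: dict = {}
    entries = list(db.entries) if hasattr(db, "entries") else list(db)
    for entry in entries:
        for pep, n_missed in cleave(entry.peptide, cfg.enzyme, cfg.missed_cleavages):
            if not cfg.len_min <= len(pep) <= cfg.len_max:
                continue
            mass = monoisotopic_mass(pep, cfg.cys_fixed_mod)
            if not cfg.mass_min <= mass <= cfg.mass_max:
                continue
            key = pep.replace("I", "L") if cfg.il_equivalence else pep
            rec = pool.get(key)
            if rec is None:
                pool[key] = [pep, {entry.accession}, mass, n_missed]
            else:
                rec[1].add(entry.accession)
                rec[3] = min(rec[3], n_missed)
    peptides = [
        PeptideRecord(pep, frozenset(parents), mass, n_missed)
        for pep, parents, mass, n_missed in
        sorted(pool.values(), key=lambda r: r[0])
    ]
    unique_counts: dict = {e.accession: 0 for e in entries}
    pep_counts: dict = {e.accession: 0 for e in entries}
    for rec in peptides:
        for acc in rec.parents:
            pep_counts[acc] += 1
        if rec.unique:
            unique_counts[next(iter(rec.parents))] += 1
    per_protein = pd.DataFrame(
        {
            "accession": [e.accession for e in entries],
            "sources": [e.sources for e in entries],
            "length_class": [e.length_class for e in entries],
            "n_peptides": [pep_counts[e.accession] for e in entries],
            "n_unique": [unique_counts[e.accession] for e in entries],
        }
    )
    rows = []
    for source in sorted({s for e in entries for s in e.sources}):
        for cls in ("small", "large"):
            sub = per_protein[
                per_protein["sources"].map(lambda s: source in s)
                & (per_protein["length_class"] == cls)
            ]
            if len(sub) == 0:
                continue
            rows.append(
                {
                    "source": source,
                    "length_class": cls,
                    "n_proteins": len(sub),
                    "zero_unique_fraction": float((sub["n_unique"] == 0).mean()),
                }
            )
    report = DetectabilityReport(per_protein=per_protein, by_group=pd.DataFrame(rows))
    return peptides, report
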