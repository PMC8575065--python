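"""Merging and comparison of protein-identification tables.

Search engines emit per-condition tables of protein identifications; this
module applies the standard downstream filters (contaminant/host removal,
a minimum unique-peptide count, removal of rows pre-flagged as subgroup /
non-razor proteins), classifies each surviving accession as canonical,
isoform or novel against the assembled database plus the genomic-context
calls, and computes exact set-overlap statistics between conditions or
engines.

FDR is consumed, never computed: input tables are assumed pre-thresholded
by the search engine (e.g. "at least 1 peptide at 1% FDR"); a passthrough
score/FDR column, when present, is retained untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional

import pandas as pd

from .sequence_io import CONTAMINANT_SOURCES

__all__ = ["load_and_filter", "classify_noncanonical", "overlap_summary",
           "OverlapSummary"]

REQUIRED_COLUMNS = ("accession", "n_unique_peptides")

#: novel genomic-context categories (everything non-isoform)
NOVEL_CATEGORIES = frozenset({"uORF", "dORF", "ncRNA", "altORF", "intergenic"})


def _entry_sources(db, accession: str):
    try:
        return db.by_accession(accession).sources
    except KeyError:
        return None


def load_and_filter(
    table: pd.DataFrame,
    db,
    min_unique: int = 1,
    drop_contaminants: bool = True,
    top_group_only: bool = True,
    strict: bool = False,
) -> pd.DataFrame:
    """Apply the standard identification filters to one table.

    Rows are removed when (a) the accession resolves to a contaminant/host
    source (or carries a ``crap|``/``host|`` header prefix) and
    ``drop_contaminants`` is set, (b) ``n_unique_peptides`` is below
    ``min_unique``, or (c) the input ``is_subgroup`` flag is truthy and
    ``top_group_only`` is set — the flag is consumed from the input, not
    recomputed, because protein grouping is the search engine's business.

    Accessions absent from the database are kept with a warning (they may
    be genuinely novel) unless ``strict`` is set.
    """
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    df = table.copy()
    # strip a dialected prefix if the engine reported the full header id
    prefixed = df["accession"].astype(str)
    df["_prefix"] = prefixed.str.extract(r"^(\w+)\|", expand=False)
    df["accession"] = prefixed.str.replace(r"^\w+\|", "", regex=True)

    unknown = []
    contam = []
    for acc, prefix in zip(df["accession"], df["_prefix"]):
        sources = _entry_sources(db, acc) if db is not None else None
        if sources is None:
            if db is not None:
                unknown.append(acc)
            contam.append(prefix in {"crap", "host"})
        else:
            contam.append(bool(sources & CONTAMINANT_SOURCES))
    if unknown:
        msg = f"{len(unknown)} accession(s) not in database, e.g. {unknown[:3]}"
        if strict:
            raise KeyError(msg)
        warnings.warn(msg)
    df["is_contaminant"] = contam
    df = df.drop(columns="_prefix")

    if drop_contaminants:
        df = df[~df["is_contaminant"]]
    df = df[df["n_unique_peptides"] >= min_unique]
    if top_group_only and "is_subgroup" in df.columns:
        df = df[~df["is_subgroup"].astype(bool)]
    return df.reset_index(drop=True)


def classify_noncanonical(
    table: pd.DataFrame,
    db,
    categories: Optional[Mapping] = None,
) -> pd.DataFrame:
    """Add a per-row {canonical, isoform, novel} class column.

    ``canonical``: the accession has reference-source evidence (reference
    membership wins over prediction membership for merged entries).
    Prediction-only accessions split by their genomic-context category:
    ``isoform`` vs ``novel`` (uORF/dORF/ncRNA/altORF/intergenic).  A
    prediction-only accession without a category is classed
    ``novel-uncategorized`` and logged.
    """
    categories = dict(categories or {})
    classes = []
    uncategorized = []
    for acc in table["accession"]:
        sources = _entry_sources(db, acc) if db is not None else None
        if sources is None or "reference" in sources:
            classes.append("canonical" if sources is not None else "novel-uncategorized")
            if sources is None:
                uncategorized.append(acc)
            continue
        if sources & CONTAMINANT_SOURCES and not sources - CONTAMINANT_SOURCES:
            classes.append("contaminant")  # only reachable when filtering kept them
            continue
        cat = categories.get(acc)
        if cat is None:
            classes.append("novel-uncategorized")
            uncategorized.append(acc)
        elif getattr(cat, "category", cat) == "isoform":
            classes.append("isoform")
        else:
            classes.append("novel")
    if uncategorized:
        warnings.warn(
            f"{len(uncategorized)} prediction accession(s) without category, "
            f"e.g. {uncategorized[:3]}"
        )
    out = table.copy()
    out["class"] = classes
    return out


@dataclass
class OverlapSummary:
    """Exact set-overlap statistics over named accession sets.

    ``table`` is long-format with one row per non-empty combination:
    ``kind`` in {set_size, intersection, exclusive}, ``members`` the
    '+'-joined set names, ``n_total`` the count, and ``n_noncanonical``
    the same count restricted to a caller-supplied non-canonical subset.
    """

    sets: dict
    table: pd.DataFrame

    def inclusion_exclusion_holds(self) -> bool:
        """Union size equals the alternating sum of intersection sizes."""
        names = sorted(self.sets)
        union = len(set().union(*(self.sets[n] for n in names)))
        total = 0
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                inter = len(set.intersection(*(set(self.sets[n]) for n in combo)))
                total += (-1) ** (r + 1) * inter
        return union == total


def overlap_summary(
    sets: Mapping,
    noncanonical: Optional[Iterable] = None,
) -> OverlapSummary:
    """Pairwise and higher-order intersections over >=2 accession sets.

    ``sets`` maps a group label (condition, engine, ...) to its accession
    collection.  ``noncanonical`` restricts a parallel count column to the
    non-canonical subset.  Output is suitable for upset/Venn plotting.
    """
    sets = {name: set(members) for name, members in sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least two groups to compare")
    nc = set(noncanonical) if noncanonical is not None else None
    names = sorted(sets)
    rows = []
    for name in names:
        s = sets[name]
        rows.append(_row("set_size", (name,), s, nc))
        exclusive = s - set().union(*(sets[o] for o in names if o != name))
        rows.append(_row("exclusive", (name,), exclusive, nc))
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[n] for n in combo))
            rows.append(_row("intersection", combo, inter, nc))
    return OverlapSummary(sets=sets, table=pd.DataFrame(rows))


def _row(kind, members, accessions, nc):
    return {
        "kind": kind,
        "members": "+".join(members),
        "n_total": len(accessions),
        "n_noncanonical": len(accessions & nc) if nc is not None else pd.NA,
    }
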