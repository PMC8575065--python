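"""Assembly of the final searchable protein database.

The search space for non-canonical discovery is the concatenation of the
reference proteome, two prediction sets, MS contaminants (cRAP-style) and
the host/feeding-organism proteome.  Identical peptide sequences appearing
in several non-contaminant sources are merged into a single entry carrying
multi-source membership — overlap categories such as "reference + predA"
are only meaningful at sequence level.  Contaminant and host entries are
flagged and excluded from all composition statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import chain
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .sequence_io import (
    CONTAMINANT_SOURCES,
    ProteinEntry,
    parse_header,
    read_fasta,
    write_fasta,
)

__all__ = ["AllOrfDatabase", "assemble", "composition_report", "length_summary",
           "entries_from_fasta", "database_from_fasta"]

#: accession priority when merging identical sequences across sources
SOURCE_PRIORITY = ("reference", "predA", "predB", "contaminant", "host")


@dataclass
class AllOrfDatabase:
    """The assembled database: entries plus source manifests."""

    entries: list
    source_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = [e.accession for e in self.entries]
        if len(accs) != len(set(accs)):
            dup = sorted({a for a in accs if accs.count(a) > 1})
            raise ValueError(f"duplicate accessions in database: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.entries)

    def by_accession(self, accession: str) -> ProteinEntry:
        return self._index()[accession]

    def _index(self) -> dict:
        if not hasattr(self, "_acc_index"):
            self._acc_index = {e.accession: e for e in self.entries}
        return self._acc_index

    @property
    def noncontaminant_entries(self) -> list:
        return [e for e in self.entries if not e.is_contaminant]

    def to_fasta(self, path) -> None:
        write_fasta(self.entries, path)

    @property
    def composition(self) -> pd.DataFrame:
        return composition_report(self)

    @property
    def length_stats(self) -> pd.DataFrame:
        return length_summary(self)


def _coerce_entries(items: Iterable, source: str) -> list:
    """Accept ProteinEntry objects or (accession, peptide[, description]) tuples."""
    out = []
    for item in items:
        if isinstance(item, ProteinEntry):
            out.append(
                ProteinEntry(item.accession, item.peptide, frozenset({source}),
                             item.description)
            )
        else:
            acc, pep, *rest = item
            out.append(ProteinEntry(acc, pep, frozenset({source}),
                                    rest[0] if rest else ""))
    accs = [e.accession for e in out]
    if len(accs) != len(set(accs)):
        raise ValueError(f"{source}: input not accession-unique")
    return out


def assemble(
    ref: Iterable = (),
    predA: Iterable = (),
    predB: Iterable = (),
    contaminants: Iterable = (),
    host: Iterable = (),
    merge_duplicates: bool = True,
) -> AllOrfDatabase:
    """Concatenate the five source sets into one database.

    With ``merge_duplicates`` (default), identical peptides across the
    non-contaminant sources collapse into one entry with merged sources;
    the retained accession follows source priority reference > predA >
    predB and the other accessions are recorded in the description.
    ``merge_duplicates=False`` preserves the literal concatenation.
    An accession appearing twice with different sequences is an error.
    """
    pools = {
        "reference": _coerce_entries(ref, "reference"),
        "predA": _coerce_entries(predA, "predA"),
        "predB": _coerce_entries(predB, "predB"),
        "contaminant": _coerce_entries(contaminants, "contaminant"),
        "host": _coerce_entries(host, "host"),
    }
    seen = {}
    for e in chain.from_iterable(pools.values()):
        if e.accession in seen and seen[e.accession] != e.peptide:
            raise ValueError(
                f"accession collision with differing sequences: {e.accession} "
                f"({seen[e.accession][:12]}... vs {e.peptide[:12]}...)"
            )
        seen[e.accession] = e.peptide

    entries: list = []
    if merge_duplicates:
        by_pep: dict = {}
        order = []
        for source in ("reference", "predA", "predB"):
            for e in pools[source]:
                if e.peptide not in by_pep:
                    by_pep[e.peptide] = [e]
                    order.append(e.peptide)
                else:
                    by_pep[e.peptide].append(e)
        for pep in order:
            group = by_pep[pep]
            group.sort(key=lambda e: SOURCE_PRIORITY.index(next(iter(e.sources))))
            primary = group[0]
            sources = frozenset(chain.from_iterable(e.sources for e in group))
            desc = primary.description
            others = [e.accession for e in group[1:]]
            if others:
                also = "also:" + ",".join(others)
                desc = f"{desc} {also}".strip()
            entries.append(ProteinEntry(primary.accession, pep, sources, desc))
    else:
        entries.extend(chain.from_iterable(
            pools[s] for s in ("reference", "predA", "predB")
        ))
    # contaminant/host entries are never merged with the search space proper
    entries.extend(pools["contaminant"])
    entries.extend(pools["host"])
    manifests = {s: [e.accession for e in pool] for s, pool in pools.items() if pool}
    return AllOrfDatabase(entries=entries, source_sets=manifests)


def _combo_label(sources: frozenset) -> str:
    ordered = sorted(sources, key=SOURCE_PRIORITY.index)
    return "+".join(ordered)


def composition_report(db: AllOrfDatabase) -> pd.DataFrame:
    """Per source-combination counts and percentages, plus size marginals.

    Percentages are relative to the non-contaminant total; the small/large
    split is at the 100-aa boundary (small: <=100 aa).  Two marginal rows
    summarize the size classes.
    """
    entries = db.noncontaminant_entries
    total = len(entries)
    rows = []
    combos: dict = {}
    for e in entries:
        combos.setdefault(_combo_label(e.sources), []).append(e)
    for combo in sorted(combos, key=lambda c: (c.count("+"), c)):
        group = combos[combo]
        small = sum(1 for e in group if e.length_class == "small")
        rows.append(
            {
                "group": combo,
                "kind": "source_combination",
                "count": len(group),
                "percent": 100.0 * len(group) / total if total else float("nan"),
                "n_small": small,
                "n_large": len(group) - small,
            }
        )
    for cls in ("small", "large"):
        group = [e for e in entries if e.length_class == cls]
        rows.append(
            {
                "group": f"{cls} (<=100 aa)" if cls == "small" else f"{cls} (>100 aa)",
                "kind": "length_class",
                "count": len(group),
                "percent": 100.0 * len(group) / total if total else float("nan"),
                "n_small": len(group) if cls == "small" else 0,
                "n_large": len(group) if cls == "large" else 0,
            }
        )
    return pd.DataFrame(rows)


def length_summary(db: AllOrfDatabase, sources: Sequence = SOURCE_PRIORITY) -> pd.DataFrame:
    """Median and quartile peptide lengths (aa) per source set.

    An entry with multi-source membership contributes to every one of its
    sources.  Medians use the midpoint convention for even counts
    (numpy's default); quartiles use linear interpolation.
    """
    rows = []
    for source in sources:
        lengths = np.array(
            [len(e.peptide) for e in db.entries if source in e.sources], dtype=float
        )
        if lengths.size == 0:
            rows.append({"source": source, "count": 0, "median": np.nan,
                         "q1": np.nan, "q3": np.nan})
            continue
        rows.append(
            {
                "source": source,
                "count": int(lengths.size),
                "median": float(np.median(lengths)),
                "q1": float(np.percentile(lengths, 25)),
                "q3": float(np.percentile(lengths, 75)),
            }
        )
    return pd.DataFrame(rows)


def entries_from_fasta(path) -> list:
    """Read a dialect-headed FASTA back into ProteinEntry objects."""
    entries = []
    for rid, desc, seq in read_fasta(path):
        sources, accession, clean_desc = parse_header(rid, desc)
        entries.append(ProteinEntry(accession, seq, sources, clean_desc))
    return entries


def database_from_fasta(path) -> AllOrfDatabase:
    """Round-trip loader: reproduces identical composition from to_fasta output."""
    entries = entries_from_fasta(path)
    manifests: dict = {}
    for e in entries:
        for s in e.sources:
            manifests.setdefault(s, []).append(e.accession)
    return AllOrfDatabase(entries=entries, source_sets=manifests)
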