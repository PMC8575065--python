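"""Best-hit filtering of tabular protein-homology search results.

Candidate non-canonical proteins are screened for cross-species
conservation by searching them against per-organism proteome databases.
This module consumes the standard 12-column tabular output (outfmt-6
style); it filters, it does not run the search.  Per (query, species
database) only the best surviving hit is retained: lowest E-value at or
below the threshold (default 1e-10), ties broken by highest percent
identity, then highest bitscore, then lexicographic subject id — a
deterministic replacement for the manual inspection such screens often
rely on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = ["HomologyHit", "BLAST6_COLUMNS", "read_outfmt6", "best_hits",
           "conservation_summary"]

logger = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "evalue", "bitscore",
]

_NUMERIC = ["percent_identity", "evalue", "bitscore"]


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    species_db: str
    percent_identity: float
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError("evalue must be > 0")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity must be in [0, 100]")


def read_outfmt6(path, species_db: Optional[str] = None) -> pd.DataFrame:
    """Read a 12-column tabular homology file.

    Malformed rows (wrong field count or non-numeric identity/E-value/
    bitscore) are skipped with their line numbers logged.  ``species_db``
    labels every row; when absent, a 13th input column is used if present.
    """
    path = Path(path)
    rows, skipped = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                skipped.append(lineno)
                continue
            row = dict(zip(BLAST6_COLUMNS, fields[:12]))
            try:
                for col in _NUMERIC:
                    row[col] = float(row[col])
            except ValueError:
                skipped.append(lineno)
                continue
            row["species_db"] = (
                species_db if species_db is not None
                else (fields[12] if len(fields) > 12 else "default")
            )
            rows.append(row)
    if skipped:
        logger.warning("%s: skipped malformed rows at lines %s", path.name, skipped)
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS + ["species_db"])


def _as_frame(hits: Union[pd.DataFrame, Iterable]) -> pd.DataFrame:
    if isinstance(hits, pd.DataFrame):
        return hits.copy()
    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "species_db": h.species_db,
                "percent_identity": h.percent_identity,
                "evalue": h.evalue,
                "bitscore": h.bitscore,
            }
            for h in hits
        ],
        columns=["query_id", "subject_id", "species_db"] + _NUMERIC,
    )


def best_hits(hits, e_threshold: float = 1e-10) -> pd.DataFrame:
    """One retained hit per (query, species_db) after E-value thresholding.

    Hits with E-value above the threshold are discarded outright; a hit at
    exactly the threshold survives.  The operation is idempotent and
    invariant to input row order.
    """
    df = _as_frame(hits)
    if len(df) == 0:
        return df
    df = df[df["evalue"] <= e_threshold]
    if len(df) == 0:
        return df.reset_index(drop=True)
    df = df.sort_values(
        by=["query_id", "species_db", "evalue", "percent_identity", "bitscore",
            "subject_id"],
        ascending=[True, True, True, False, False, True],
        kind="mergesort",
    )
    return df.groupby(["query_id", "species_db"], as_index=False, sort=True).first()


def conservation_summary(
    best: pd.DataFrame,
    n_species_min: int = 1,
    all_queries: Optional[Iterable] = None,
) -> pd.DataFrame:
    """Per-query species count and conserved flag.

    A query is conserved when retained hits exist in at least
    ``n_species_min`` distinct species databases.  ``all_queries`` lets
    callers include queries with zero surviving hits (count 0, not
    conserved).
    """
    if len(best):
        counts = best.groupby("query_id")["species_db"].nunique()
    else:
        counts = pd.Series(dtype=int, name="species_db")
    extra = set(all_queries) if all_queries is not None else set()
    queries = sorted(set(counts.index) | extra)
    n = [int(counts.get(q, 0)) for q in queries]
    return pd.DataFrame(
        {
            "query_id": queries,
            "n_species": n,
            "conserved": [c >= n_species_min for c in n],
        }
    )
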