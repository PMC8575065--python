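"""Interior-sequence containment filtering of ORF predictions.

A predicted small ORF adds nothing to a search database when it is already
represented inside a known or longer protein.  The rule applied here is
exact ("identical overlap"): a prediction is removed iff its interior
sequence — the peptide with its first and last residue stripped — occurs
verbatim as a substring of any reference protein.  No alignment, no
mismatches, and leucine/isoleucine are deliberately *not* equated: this is
a sequence-level rule, not a mass-spectrometric one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = ["interior_sequence", "ContainmentIndex", "filter_contained"]

TOO_SHORT_REASON = "too short to test"


def interior_sequence(p: str) -> str:
    """Peptide without its first and last residue.

    Raises ``ValueError`` below 3 residues — there is no interior to test.
    """
    if len(p) < 3:
        raise ValueError(f"peptide {p!r} has no interior (length {len(p)} < 3)")
    return p[1:-1]


class ContainmentIndex:
    """Answers "is q a substring of any reference peptide?".

    Backed by one concatenated text with a separator that cannot occur in a
    peptide, so a single scan rejects most queries; the per-reference pass
    then names the first matching accession in input order.
    """

    def __init__(self, references: Sequence):
        self._refs = list(references)
        self._text = "\x00".join(e.peptide for e in self._refs)

    def first_containing(self, query: str):
        """Accession of the first reference containing ``query``, or None."""
        if not query or query not in self._text:
            return None
        for entry in self._refs:
            if query in entry.peptide:
                return entry.accession
        return None

    def __contains__(self, query: str) -> bool:
        return self.first_containing(query) is not None


def filter_contained(predictions: Iterable, references: Sequence):
    """Partition predictions into (kept, removed-with-reason).

    A prediction is removed iff ``interior_sequence(peptide)`` is an exact
    substring of any reference peptide; the removal reason names the first
    matching reference accession.  Predictions shorter than 3 aa cannot be
    tested and are removed with reason ``"too short to test"``.
    """
    refs = list(references)
    if not refs:
        raise ValueError("references must be non-empty")
    index = ContainmentIndex(refs)
    kept, removed = [], []
    for pred in predictions:
        pep = pred.peptide
        if len(pep) < 3:
            removed.append((pred, TOO_SHORT_REASON))
            continue
        acc = index.first_containing(interior_sequence(pep))
        if acc is not None:
            removed.append((pred, f"interior contained in {acc}"))
        else:
            kept.append(pred)
    return kept, removed
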