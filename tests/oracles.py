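"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by a different route than the
implementation: translate-and-scan for ORFs, exhaustive substring
enumeration for cleavage, quadratic substring search for containment.
"""

import re

from orfkit.sequence_io import spliced_sequence, translate

STOPS = {"TAA", "TAG", "TGA"}

ENZYME_RESIDUES = {
    "trypsin": (set("KR"), set("P")),
    "chymotrypsin": (set("FWYL"), set("P")),
}


def oracle_scan(t, genome, starts=("ATG",), min_aa=2, max_aa=None):
    """Translate every frame; regex stop-delimited segments; enumerate starts.

    Returns a set of (frame, tx_start, tx_end, peptide) tuples.
    """
    seq = spliced_sequence(t, genome)
    starts = set(starts)
    found = set()
    for frame in range(3):
        usable = seq[frame: frame + 3 * ((len(seq) - frame) // 3)]
        if not usable:
            continue
        aa = _safe_translate(usable)
        for seg in re.finditer(r"[^*]*\*", aa):
            for j in range(seg.start(), seg.end() - 1):
                codon = usable[3 * j: 3 * j + 3]
                if codon not in starts:
                    continue
                n_aa = (seg.end() - 1) - j
                if n_aa < min_aa or (max_aa is not None and n_aa > max_aa):
                    continue
                nt = usable[3 * j: 3 * seg.end()]
                if "N" in nt:
                    continue
                pep = aa[j: seg.end() - 1]
                if codon != "ATG":
                    pep = "M" + pep[1:]
                found.add((frame, frame + 3 * j, frame + 3 * seg.end(), pep))
    return found


def _safe_translate(nt):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return translate(nt)


def oracle_cleave(p, enzyme, missed_cleavages):
    """Every substring whose ends are cleavage boundaries and whose interior
    holds at most the allowed number of uncut sites."""
    residues, blockers = ENZYME_RESIDUES[enzyme]

    def is_cut(i):
        return 0 < i < len(p) and p[i - 1] in residues and p[i] not in blockers

    bounds = [i for i in range(len(p) + 1) if i in (0, len(p)) or is_cut(i)]
    prods = []
    for a in bounds:
        for b in bounds:
            if b <= a:
                continue
            internal = sum(1 for i in range(a + 1, b) if is_cut(i))
            if internal <= missed_cleavages:
                prods.append((p[a:b], internal))
    return sorted(prods)


def oracle_contained(predictions, references):
    """Quadratic naive check: interior of each prediction vs each reference."""
    removed = set()
    for pred in predictions:
        if len(pred.peptide) < 3:
            removed.add(pred.orf_id if hasattr(pred, "orf_id") else pred.accession)
            continue
        interior = pred.peptide[1:-1]
        for ref in references:
            if interior in ref.peptide:
                removed.add(
                    pred.orf_id if hasattr(pred, "orf_id") else pred.accession
                )
                break
    return removed
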