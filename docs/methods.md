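# Methods

## Scope and model of the problem

`orfkit` implements the computational core of a proteogenomic workflow for
discovering non-canonical translation products (small ORFs, alternative
ORFs, UTR- and ncRNA-encoded proteins) by bottom-up mass spectrometry. The
workflow has five stages, each a module:

1. **ORF discovery** (`orf_discovery`) — enumerate candidate ORFs on
   spliced transcripts;
2. **Redundancy filtering** (`redundancy_filter`) — drop predictions
   already represented inside known proteins;
3. **Database assembly** (`database_assembly`) — concatenate reference,
   prediction, contaminant and host proteomes into one provenance-tracked
   search FASTA;
4. **Detectability evaluation** (`insilico_digest`) — quantify, by
   in-silico digestion, which database entries can ever be confidently
   identified;
5. **Post-identification analysis** (`orf_annotation`,
   `conservation_screen`, `id_merge`) — categorize identified ORFs by
   genomic context, screen them for cross-species conservation, and
   compare identification sets across conditions and search engines.

The search engines themselves, FDR estimation and ribosome-profiling
signal processing are out of scope: identification tables are consumed
pre-thresholded, and ORF discovery is purely sequence-based. A
consequence worth stating: sequence-only scanning predicts a superset of
what translation-initiation-site evidence would support.

## Definitions and rules

**ORF.** A mature-mRNA span from an allowed start codon to the first
in-frame stop codon. Start codons default to ATG; the NTG near-cognate
set is available for pipelines with initiation-site evidence, and
near-cognate starts translate to initiator Met. The small-ORF cap of 100
codons is interpreted as peptide length ≤ 100 aa with the stop codon
excluded from the count; the boundary (100 kept, 101 excluded) is pinned
by tests. Candidates containing N in any codon are excluded
(conservative treatment of assembly gaps). The minimum peptide length
defaults to 2 aa — the shortest peptide with a distinguishable start.

**Stop-site collapsing.** Candidates sharing a stop are collapsed to the
longest. "Stop site" is genomic — `(chrom, strand, coordinate of the last
stop-codon base)` — so the same physical ORF reached through different
transcripts collapses. Ties on length break by 5'-most start, then
lexicographic id, making the result order-independent.

**Interior containment.** A prediction is redundant iff its peptide with
first and last residue stripped occurs verbatim in a reference protein.
This is exact substring containment — no alignment, no mismatches, and
I/L are not equated here (the rule is sequence-level, not
mass-spectrometric). Containment against contaminant databases is off by
default. Backed by a single concatenated-text scan with a sentinel
separator; correctness is checked against a naive quadratic oracle.

**Database merging.** Identical peptide sequences across reference and
prediction sources merge into one entry with multi-source membership,
because overlap categories ("reference + prediction A") are only
meaningful at sequence level. The retained accession follows priority
reference > predA > predB, keeping reference accessions stable for
identification matching; `--keep-duplicates` preserves literal
concatenation. Contaminant/host entries are flagged, never merged with
the search space, and excluded from composition percentages.

**Digestion.** Trypsin cleaves C-terminal to K/R except before P;
chymotrypsin uses the common low-specificity-minus-M rule {F,W,Y,L}
not-before-P, with a stricter {F,W,Y} variant selectable. Defaults: one
missed cleavage, monoisotopic mass 600–4000 Da, length 7–30 aa. Masses
are monoisotopic and unmodified (the evaluation precedes MS-level
modification handling); a fixed Cys modification mass is a config switch.
Whether such mass windows are monoisotopic or average is often left
unstated in practice; monoisotopic is chosen and documented here.
Identical peptide strings are pooled across parents before uniqueness is
evaluated, so results are invariant to protein order. I/L equivalence
for uniqueness is off by default but available, since isobaric I/L are
indistinguishable by MS. No semitryptic forms, no N-terminal Met
clipping.

**Genomic-context categories.** A fixed-priority cascade, least novel
first: isoform (shares the genomic stop site — hence frame — with an
annotated CDS), uORF (entirely within 5'UTR exons), dORF (entirely
within 3'UTR exons), ncRNA (hosted on a non-coding transcript), altORF
(any other exonic overlap with a coding transcript, typically CDS
overlap in a different frame), intergenic (no same-strand exonic
overlap). An ORF straddling a CDS boundary is altORF, not uORF/dORF:
the UTR classes read as containment. Frame comparison is splice-aware,
per genomic base, since transcript-relative frames are meaningless
across isoforms. Antisense-only overlap counts as intergenic — the
category system describes sense-strand context. The small-ORF/altORF
distinction within alternative translation products is not a category:
callers combine `length_class` (≤ 100 aa) with the category instead.

**Best-hit conservation filter.** Per (query, species database), hits
with E-value above 1e-10 are discarded; among survivors the lowest
E-value wins, ties broken by highest percent identity, then bitscore,
then subject id. This deterministic tiebreak replaces the manual
inspection such screens traditionally use. A query is conserved when it
retains hits in at least `n_species_min` databases (default 1).

**Identification merging.** Contaminant/host rows are dropped by source
prefix or database lookup, a minimum unique-peptide count applied
(default 1), and subgroup/non-razor rows honored via an input flag only —
protein grouping is engine-specific and is not re-derived. FDR is
consumed, never computed. Set overlaps are exact and emitted long-format
with set sizes, exclusive counts and all intersection orders;
inclusion–exclusion consistency is asserted in tests.

## Coordinates and formats

Internal coordinates are 0-based half-open everywhere; GFF3-style input
(1-based inclusive) is converted at the I/O boundary only, and re-export
reproduces the original intervals. Exons are stored 5'→3' in transcript
orientation. The annotated CDS span includes its stop codon. FASTA
database headers follow `>{source}|{accession} {description}` with
source ∈ {ref, predA, predB, crap, host}, so contaminant filtering can
key on the prefix; multi-source membership is carried in a
`sources=...` description token. The genetic code is the standard
nuclear table only. Published tag inserts decorated with typographic
characters (zero-width spaces between codons) are cleaned by dropping
every non-ACGT character before use.

## The synthetic fixture generator

`synthetic_fixtures.generate` builds a single-chromosome world whose
defaults are the stated conditions of the workflow it emulates:

- multi-exon coding genes with 5'/3'UTRs (some minus-strand, ~half with
  an intron inside the CDS) and ncRNA genes, separated by ≥ 80 nt so
  category rules never fire across genes (50 nt is the enforced floor);
- planted ORFs of every category at known coordinates, including a
  frame-shifted ORF inside a CDS (built by rejection sampling so both
  frames are stop-free where required) and an in-frame internal-start
  isoform sharing the CDS stop;
- two prediction sets with length medians of exactly 45 aa and 25 aa by
  symmetric construction (odd counts, equal numbers above and below the
  middle element) and ~30% of sequences shared between them;
- a detectability fixture in which 1 of 5 predictions has zero unique
  in-window tryptic peptides, built by embedding the prediction's entire
  fragment run in a host protein and verified by actually running the
  digest module at generation time;
- a homology table with 18 of 85 queries planted conserved (sub-1e-10
  best hits plus decoys), and two identification tables with a planted
  68-common / 87-vs-119-unique engine overlap.

All randomness flows through one seeded `numpy` generator; identical
seed and spec give byte-identical files. Before a fixture ships, a
self-check verifies every planted ORF is rediscovered by `scan_orfs`
(intergenic ORFs via an unannotated carrier transcript spanning their
window, since they sit on no annotated transcript) and recovers its
category.

What the generator does **not** emulate: realistic codon usage and GC
content, sequencing or ribosome-profiling noise, spectra, retention
times, search-engine scoring, or FDR behaviour. A green fixture test
therefore establishes the correctness of the combinatorial and
coordinate logic, not field performance on real data.

## Numerical choices

- Monoisotopic residue masses from the standard 20-residue table; water
  18.0105646863 Da; peptide-mass agreement asserted to 1e-4 Da.
- Median: numpy midpoint convention for even counts; quartiles: linear
  interpolation. Stated in output metadata because conventions differ.
- Composition percentages are over non-contaminant entries and must sum
  to 100 ± 0.1 (floating-point tolerance only).
- E-value threshold comparison is inclusive (`evalue <= threshold`).
- Deterministic tie-breaks everywhere a choice is otherwise arbitrary
  (stop-collapse, best-hit retention, table orderings by id).

## Known limitations

- Sequence-only ORF scanning cannot distinguish translated from merely
  possible ORFs; it is the database-construction superset by design.
- Interval queries use plain per-chromosome scans — adequate for
  fixture- and single-genome-scale annotation, not for whole-mammal
  annotation sets.
- The categorizer assigns one category per ORF; biologically ambiguous
  cases (e.g. an ORF that is a uORF on one isoform and CDS-overlapping
  on another) resolve by the stated priority, with all evidence listed.
- `read_annotation` infers transcripts as "features with direct exon
  children" and takes CDS features as written (stop codon included);
  annotations that exclude the stop from CDS will shift UTR boundaries
  by one codon.
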