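# orfkit

Toolkit for building and evaluating **non-canonical ORF protein search
databases** for bottom-up proteomics.

Genome annotation pipelines historically exclude open reading frames
shorter than 100 codons and enforce one ORF per transcript, so small ORFs
(sORFs), alternative-frame ORFs (altORFs), and ORFs in UTRs or annotated
non-coding RNA escape the reference proteome — and therefore escape
standard mass-spectrometric identification, which can only match spectra
against the database it is given. `orfkit` is for proteogenomics
practitioners who want to close that gap: it constructs an inclusive
"all-ORF" search database from transcript and annotation input, tells you
in advance which entries are even detectable by a tryptic shotgun
experiment, and processes what comes back out of the search engines.

## What it computes

- **ORF discovery** — three-frame enumeration of start→first-stop ORFs on
  spliced transcripts, with the sORF length cap (peptide ≤ 100 aa, stop
  excluded), collapsing of candidates that share a genomic stop site to
  the longest, and sequence-level deduplication.
- **Redundancy filtering** — a prediction is removed iff its *interior*
  sequence (first and last residue stripped) occurs verbatim inside a
  reference protein: exact containment, no alignment.
- **Database assembly** — reference + prediction sets + cRAP-style
  contaminants + host proteome, merged by exact sequence with
  provenance-carrying headers `>{source}|{accession}`, plus composition
  and length statistics per source.
- **In-silico digestion** — trypsin/chymotrypsin with missed cleavages,
  monoisotopic mass window 600–4000 Da and length window 7–30 aa by
  default; identical peptides are pooled across proteins and a peptide is
  *unique* iff it maps to exactly one entry. The per-protein
  unique-peptide count is the detectability currency: an entry with zero
  unique in-window peptides cannot be confidently identified at all.
- **Genomic-context annotation** — each identified ORF gets exactly one
  category by priority: isoform > uORF > dORF > ncRNA > altORF >
  intergenic, with splice-aware frame comparison.
- **Conservation screening** — best-hit filtering of 12-column tabular
  homology results: E ≤ 1e-10, then lowest E-value per (query, species
  database), ties by identity, bitscore, subject id.
- **Identification merging** — contaminant/min-unique/subgroup filters,
  canonical/isoform/novel classification, and exact set-overlap tables
  across conditions or search engines.
- **Synthetic fixtures** — a deterministic generator that plants all of
  the above with known ground truth (see `docs/methods.md`).

## Worked example

Verify an in-frame 11-residue tag insertion (the HiBit-style knock-in
check: the tag's nucleotide sequence carries a restriction site, so
successful enzymatic digestion of a PCR product reads out successful
integration):

```
$ printf ">orf toy\nATGGCCAAGTAA\n" > orf.fa
$ orfkit tag-check --orf orf.fa \
    --insert "gtg agc ggc tgg cgc ctg ttt aaa aaa att agc" --site CCGCTC
in_frame: True
tag_peptide: VSGWRLFKKIS (11 aa)
restriction_hits: [('-', 2)]
```

The 33-nt insert is in frame (length divisible by 3, no internal stop),
translates to the 11-aa tag peptide, and contains exactly one occurrence
of the CCGCTC recognition pattern — on the reverse strand, starting at
forward-strand offset 2.

A full pipeline run on a generated fixture:

```
$ orfkit simulate --seed 1 --out fx/
$ orfkit scan --genome fx/genome.fa --gff fx/annotation.gff3 \
    --out-fasta sorfs.fa --out-table sorfs.tsv
28 ORFs retained
$ orfkit annotate --orfs sorfs.tsv --genome fx/genome.fa \
    --gff fx/annotation.gff3 --out calls.tsv
$ orfkit conserve --hits fx/homology.tsv --summary-out conserved.tsv
18 conserved queries
```

Other subcommands: `filter` (interior containment), `assemble`, `digest`,
`merge-ids`. Every subcommand is a thin wrapper over the library modules
in `src/orfkit/`.

## Acceptance script

`scripts/acceptance.py` re-runs the entire pipeline from scratch on a
seeded synthetic fixture — generation, ORF scan, containment filtering,
database assembly, digestion with detectability accounting, category
annotation, conservation screening and identification overlap — printing
a one-screen summary and writing its JSON result to `--out`:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
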