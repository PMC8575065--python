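import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import single_exon_tx
from orfkit.sequence_io import (
    FastaParseError,
    GenomeSequence,
    ProteinEntry,
    check_tag_insert,
    clean_nucleotides,
    find_restriction_sites,
    format_header,
    parse_header,
    project_to_genome,
    read_annotation,
    read_fasta,
    reverse_complement,
    spliced_sequence,
    translate,
    tx_to_genome,
    write_annotation,
    write_fasta,
)

HIBIT_NT = "gtgagcggctggcgcctgtttaaaaaaattagc"


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n")
        assert read_fasta(p) == [("a", "", "ACGT")]

    def test_duplicate_ids_returned_and_warned(self, tmp_path):
        p = tmp_path / "d.fa"
        p.write_text(">x one\nAAA\n>x two\nCCC\n")
        with pytest.warns(UserWarning, match="duplicate"):
            recs = read_fasta(p)
        assert [r[0] for r in recs] == ["x", "x"]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fa"
        p.write_text("")
        assert read_fasta(p) == []

    def test_sequence_before_header_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n>a\nACGT\n")
        with pytest.raises(FastaParseError, match="bad.fa:1"):
            read_fasta(p)

    def test_round_trip_identity(self, tmp_path):
        records = [("a", "first", "ACGT" * 40), ("b", "", "GGGG")]
        p = tmp_path / "rt.fa"
        write_fasta(records, p)
        back = read_fasta(p)
        assert [(r[0], r[2]) for r in back] == [(r[0], r[2]) for r in records]

    def test_header_dialect_round_trip(self):
        e = ProteinEntry("P1", "MAAAK", frozenset({"reference", "predA"}), "demo")
        header = format_header(e)
        rid, desc = header.split(" ", 1)
        sources, acc, _ = parse_header(rid, desc)
        assert acc == "P1"
        assert sources == {"reference", "predA"}


class TestTranslate:
    def test_hibit_insert_is_eleven_residues(self):
        pep = translate(clean_nucleotides(HIBIT_NT))
        assert len(pep) == 11
        assert pep == "VSGWRLFKKIS"

    @pytest.mark.parametrize("nt,aa", [("ATG", "M"), ("TAA", "*"), ("ATGGCC", "MA")])
    def test_simple_codons(self, nt, aa):
        assert translate(nt) == aa

    def test_partial_codon_is_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            translate("ATGA")

    def test_ambiguous_codon_is_x_with_warning(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            assert translate("ATGANA") == "MX"

    @given(st.text(alphabet="ACGT", min_size=3, max_size=60).map(
        lambda s: s[: 3 * (len(s) // 3)]))
    @settings(max_examples=50, derandomize=True)
    def test_double_revcomp_identity(self, nt):
        if not nt:
            return
        assert reverse_complement(reverse_complement(nt)) == nt
        assert translate(reverse_complement(reverse_complement(nt))) == translate(nt)


class TestSplicing:
    def test_plus_single_exon(self):
        t, genome = single_exon_tx("ATGTAA")
        assert spliced_sequence(t, genome) == "ATGTAA"

    def test_minus_single_exon_is_revcomp(self):
        t, genome = single_exon_tx("ATGTAA", strand="-")
        assert spliced_sequence(t, genome) == "TTACAT"

    def test_two_exon_manual_splice(self):
        from orfkit.sequence_io import TranscriptModel

        genome = {"c": GenomeSequence("c", "ATGCCCTAA")}
        t = TranscriptModel("t", "g", "c", "+", ((0, 3), (6, 9)))
        assert spliced_sequence(t, genome) == "ATGTAA"

    def test_minus_two_exon_manual_splice(self):
        # genome: exon2(rc)="TTA" at [0,3), intron, exon1(rc)="CAT" at [6,9)
        from orfkit.sequence_io import TranscriptModel

        genome = {"c": GenomeSequence("c", "TTAGGGCAT")}
        t = TranscriptModel("t", "g", "c", "-", ((6, 9), (0, 3)))
        assert spliced_sequence(t, genome) == "ATGTAA"

    def test_spliced_length_equals_exon_sum(self, bundle):
        for t in bundle.transcripts:
            assert len(spliced_sequence(t, bundle.genome)) == sum(
                e - s for s, e in t.exons
            )

    def test_coordinate_maps_are_inverse(self, bundle):
        from orfkit.sequence_io import genome_to_tx

        t = bundle.transcripts[0]
        for pos in (0, 1, t.spliced_length // 2, t.spliced_length - 1):
            assert genome_to_tx(t, tx_to_genome(t, pos)) == pos


class TestAnnotationIO:
    GFF = "\n".join(
        [
            "##gff-version 3",
            "chr1\tsrc\ttranscript\t11\t40\t.\t+\t.\tID=tx1;biotype=protein_coding",
            "chr1\tsrc\texon\t11\t40\t.\t+\t.\tParent=tx1",
            "chr1\tsrc\tCDS\t14\t37\t.\t+\t0\tParent=tx1",
            "chr1\tsrc\ttranscript\t51\t80\t.\t+\t.\tID=tx2",
            "chr1\tsrc\texon\t51\t80\t.\t+\t.\tParent=tx2",
        ]
    ) + "\n"

    def test_one_based_to_half_open(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(self.GFF)
        txs = {t.transcript_id: t for t in read_annotation(p)}
        assert txs["tx1"].exons == ((10, 40),)
        assert txs["tx1"].cds_span == (3, 27)

    def test_no_cds_defaults_to_ncrna(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(self.GFF)
        txs = {t.transcript_id: t for t in read_annotation(p)}
        assert txs["tx2"].biotype == "ncRNA"
        assert txs["tx2"].cds_span is None

    def test_cds_not_multiple_of_three_dropped_with_warning(self, tmp_path):
        gff = self.GFF.replace("\t14\t37\t", "\t14\t36\t")
        p = tmp_path / "b.gff3"
        p.write_text(gff)
        with pytest.warns(UserWarning, match="divisible by 3"):
            txs = {t.transcript_id: t for t in read_annotation(p)}
        assert txs["tx1"].cds_span is None

    def test_exon_outside_chromosome_is_error(self, tmp_path):
        p = tmp_path / "c.gff3"
        p.write_text(self.GFF)
        tiny = {"chr1": GenomeSequence("chr1", "ACGT")}
        with pytest.raises(ValueError, match="bounds"):
            read_annotation(p, tiny)

    def test_round_trip_preserves_coordinates(self, bundle, tmp_path):
        out = tmp_path / "rt.gff3"
        write_annotation(bundle.transcripts, out)
        back = {t.transcript_id: t for t in read_annotation(out, bundle.genome)}
        for t in bundle.transcripts:
            assert back[t.transcript_id].exons == t.exons
            assert back[t.transcript_id].cds_span == t.cds_span
            assert back[t.transcript_id].strand == t.strand


class TestRestrictionAndTag:
    def test_hibit_insert_has_single_site_both_strands(self):
        hits = find_restriction_sites(clean_nucleotides(HIBIT_NT), "CCGCTC")
        assert len(hits) == 1
        assert hits[0][0] == "-"

    def test_pattern_matches_itself_forward(self):
        assert find_restriction_sites("CCGCTC", "CCGCTC") == [("+", 0)]

    def test_no_hits(self):
        assert find_restriction_sites("AAAA", "CCGCTC") == []

    def test_tag_insert_adds_eleven_residues(self):
        # 84-codon toy ORF, tag placed immediately before the stop codon
        orf = "ATG" + "GCC" * 83 + "TAA"
        report = check_tag_insert(orf, HIBIT_NT, "CCGCTC")
        assert report.insert_is_inframe
        assert report.tag_length == 11
        assert len(report.tagged_peptide) == 84 + 11
        assert report.tagged_peptide.endswith(report.tag_peptide)

    def test_insert_with_internal_stop_rejected(self):
        report = check_tag_insert("ATGTAA", "TAA", "CCGCTC")
        assert not report.insert_is_inframe
        assert "stop" in report.reason

    def test_insert_not_multiple_of_three_rejected(self):
        report = check_tag_insert("ATGTAA", "A" * 32, "CCGCTC")
        assert not report.insert_is_inframe
        assert "divisible" in report.reason
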