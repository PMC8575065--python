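import numpy as np
import pytest

from orfkit.database_assembly import (
    assemble,
    composition_report,
    database_from_fasta,
    length_summary,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def peptide(rng, n):
    return "M" + "".join(AA[i] for i in rng.integers(0, 20, n - 1))


class TestAssemble:
    def test_identical_sequence_merges_sources(self):
        db = assemble(ref=[("P1", "MAAAK")], predA=[("A1", "MAAAK")])
        assert len(db) == 1
        (e,) = db.entries
        assert e.sources == {"reference", "predA"}
        assert e.accession == "P1"  # reference accession wins
        assert "A1" in e.description

    def test_disjoint_inputs_concatenate(self):
        db = assemble(
            ref=[("r1", "MAK"), ("r2", "MCK"), ("r3", "MDK")],
            predA=[("a1", "MEK"), ("a2", "MFK")],
            predB=[("b1", "MGK")],
        )
        assert len(db) == 6

    def test_accession_collision_different_sequence_is_error(self):
        with pytest.raises(ValueError, match="collision"):
            assemble(ref=[("X", "MAK")], predA=[("X", "MCK")])

    def test_keep_duplicates_preserves_concatenation(self):
        db = assemble(ref=[("P1", "MAAAK")], predA=[("A1", "MAAAK")],
                      merge_duplicates=False)
        assert len(db) == 2

    def test_contaminants_flagged_not_merged(self):
        db = assemble(ref=[("P1", "MAAAK")], contaminants=[("C1", "MAAAK")])
        assert len(db) == 2
        assert db.by_accession("C1").is_contaminant

    def test_entry_count_is_distinct_sequences_plus_contaminants(self, rng):
        peps = [peptide(rng, 20) for _ in range(30)]
        ref = [(f"r{i}", p) for i, p in enumerate(peps[:15])]
        predA = [(f"a{i}", p) for i, p in enumerate(peps[5:25])]
        crap = [(f"c{i}", peptide(rng, 25)) for i in range(3)]
        db = assemble(ref=ref, predA=predA, contaminants=crap)
        distinct = len({p for _, p in ref} | {p for _, p in predA})
        assert len(db) == distinct + len(crap)


class TestComposition:
    def test_single_entry_is_hundred_percent(self):
        db = assemble(ref=[("P1", "MAAAK")])
        table = composition_report(db)
        row = table[table["group"] == "reference"].iloc[0]
        assert row["count"] == 1 and row["percent"] == 100.0

    def test_percentages_sum_to_hundred(self, rng):
        db = assemble(
            ref=[(f"r{i}", peptide(rng, 30)) for i in range(10)],
            predA=[(f"a{i}", peptide(rng, 120)) for i in range(7)],
            predB=[(f"b{i}", peptide(rng, 15)) for i in range(3)],
        )
        table = composition_report(db)
        combos = table[table["kind"] == "source_combination"]
        assert abs(combos["percent"].sum() - 100.0) < 0.1

    def test_contaminants_do_not_change_percentages(self, rng):
        ref = [(f"r{i}", peptide(rng, 30)) for i in range(8)]
        predA = [(f"a{i}", peptide(rng, 40)) for i in range(4)]
        base = composition_report(assemble(ref=ref, predA=predA))
        spiked = composition_report(
            assemble(ref=ref, predA=predA,
                     contaminants=[("c1", peptide(rng, 50))],
                     host=[("h1", peptide(rng, 60))])
        )
        assert base["percent"].tolist() == spiked["percent"].tolist()

    def test_small_large_split_at_100aa(self, rng):
        db = assemble(ref=[("s", peptide(rng, 100)), ("l", peptide(rng, 101))])
        table = composition_report(db).set_index("group")
        assert table.loc["small (<=100 aa)", "count"] == 1
        assert table.loc["large (>100 aa)", "count"] == 1

    def test_fasta_round_trip_reproduces_composition(self, rng, tmp_path):
        db = assemble(
            ref=[("r1", "MAAAK"), ("r2", peptide(rng, 44))],
            predA=[("a1", "MAAAK"), ("a2", peptide(rng, 23))],
            contaminants=[("c1", peptide(rng, 99))],
        )
        path = tmp_path / "db.fa"
        db.to_fasta(path)
        back = database_from_fasta(path)
        a = composition_report(db).to_dict("records")
        b = composition_report(back).to_dict("records")
        assert a == b


class TestLengthSummary:
    def test_odd_count_median(self):
        db = assemble(ref=[("a", "M" * 10), ("b", "M" * 20), ("c", "M" * 30)])
        row = length_summary(db).set_index("source").loc["reference"]
        assert row["median"] == 20

    def test_even_count_midpoint_convention(self):
        db = assemble(ref=[("a", "M" * 10), ("b", "M" * 20)])
        row = length_summary(db).set_index("source").loc["reference"]
        assert row["median"] == 15

    def test_empty_source_reported_without_median(self):
        db = assemble(ref=[("a", "MAK")])
        row = length_summary(db).set_index("source").loc["predA"]
        assert row["count"] == 0 and np.isnan(row["median"])

    def test_planted_medians_recovered(self, bundle):
        db = assemble(ref=bundle.reference, predA=bundle.predA, predB=bundle.predB)
        table = length_summary(db).set_index("source")
        assert table.loc["predA", "median"] == bundle.spec.predA_median
        assert table.loc["predB", "median"] == bundle.spec.predB_median
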