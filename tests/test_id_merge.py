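import numpy as np
import pandas as pd
import pytest

from orfkit.database_assembly import assemble
from orfkit.id_merge import classify_noncanonical, load_and_filter, overlap_summary
from orfkit.orf_annotation import CategoryCall


@pytest.fixture
def toy_db():
    return assemble(
        ref=[("REF1", "MAAAK"), ("BOTH1", "MCCCK")],
        predA=[("A1", "MDDDK"), ("AB1", "MCCCK"), ("A2", "MEEEK")],
        host=[("ECOLI1", "MFFFK")],
        contaminants=[("KRT1", "MGGGK")],
    )


def id_table(rows):
    return pd.DataFrame(
        rows, columns=["accession", "n_unique_peptides", "engine", "is_subgroup"]
    )


class TestLoadAndFilter:
    def test_counted_removals(self, toy_db):
        # 10 rows: 1 zero-unique, 1 contaminant, 1 subgroup fail -> 7 kept
        rows = [[f"A{i % 2 + 1}", i + 1, "e1", False] for i in range(7)]
        rows += [["REF1", 0, "e1", False], ["KRT1", 5, "e1", False],
                 ["A1", 3, "e1", True]]
        out = load_and_filter(id_table(rows), toy_db)
        assert len(out) == 7

    def test_zero_unique_removed(self, toy_db):
        out = load_and_filter(id_table([["REF1", 0, "e1", False]]), toy_db)
        assert len(out) == 0

    def test_host_and_contaminant_sources_removed(self, toy_db):
        out = load_and_filter(
            id_table([["ECOLI1", 4, "e1", False], ["KRT1", 4, "e1", False],
                      ["REF1", 4, "e1", False]]),
            toy_db,
        )
        assert out["accession"].tolist() == ["REF1"]

    def test_prefixed_accessions_resolve(self, toy_db):
        out = load_and_filter(
            id_table([["crap|UNSEEN", 4, "e1", False], ["ref|REF1", 4, "e1", False]]),
            toy_db,
        )
        assert out["accession"].tolist() == ["REF1"]

    def test_unknown_accession_warns_or_raises(self, toy_db):
        table = id_table([["NOVEL9", 2, "e1", False]])
        with pytest.warns(UserWarning, match="not in database"):
            out = load_and_filter(table, toy_db)
        assert len(out) == 1
        with pytest.raises(KeyError):
            load_and_filter(table, toy_db, strict=True)

    def test_filters_commute(self, toy_db):
        rows = [["REF1", 0, "e1", False], ["KRT1", 3, "e1", False],
                ["A1", 2, "e1", False], ["ECOLI1", 0, "e1", False]]
        t = id_table(rows)
        a = load_and_filter(t, toy_db, min_unique=1, drop_contaminants=True)
        b = load_and_filter(
            load_and_filter(t, toy_db, min_unique=1, drop_contaminants=False),
            toy_db, min_unique=0, drop_contaminants=True,
        )
        assert a["accession"].tolist() == b["accession"].tolist()


class TestClassify:
    def test_reference_only_is_canonical(self, toy_db):
        out = classify_noncanonical(id_table([["REF1", 2, "e1", False]]), toy_db)
        assert out["class"].tolist() == ["canonical"]

    def test_merged_reference_evidence_wins(self, toy_db):
        out = classify_noncanonical(id_table([["BOTH1", 2, "e1", False]]), toy_db)
        assert out["class"].tolist() == ["canonical"]

    def test_prediction_with_novel_category(self, toy_db):
        cats = {"A1": CategoryCall("A1", "uORF", ("tx1",))}
        out = classify_noncanonical(id_table([["A1", 2, "e1", False]]), toy_db, cats)
        assert out["class"].tolist() == ["novel"]

    def test_prediction_with_isoform_category(self, toy_db):
        cats = {"A1": CategoryCall("A1", "isoform", ("tx1",), "same")}
        out = classify_noncanonical(id_table([["A1", 2, "e1", False]]), toy_db, cats)
        assert out["class"].tolist() == ["isoform"]

    def test_missing_category_logged(self, toy_db):
        with pytest.warns(UserWarning, match="without category"):
            out = classify_noncanonical(id_table([["A2", 2, "e1", False]]), toy_db)
        assert out["class"].tolist() == ["novel-uncategorized"]

    def test_partition_of_rows(self, toy_db):
        cats = {"A1": CategoryCall("A1", "ncRNA", ("nc1",))}
        table = id_table([["REF1", 2, "e", False], ["BOTH1", 1, "e", False],
                          ["A1", 1, "e", False]])
        out = classify_noncanonical(table, toy_db, cats)
        assert out["class"].isin({"canonical", "isoform", "novel"}).all()


class TestOverlap:
    def test_pairwise_example(self):
        summ = overlap_summary({"x": {"a", "b", "c"}, "y": {"b", "c", "d"}})
        t = summ.table.set_index(["kind", "members"])
        assert t.loc[("intersection", "x+y"), "n_total"] == 2
        assert t.loc[("exclusive", "x"), "n_total"] == 1
        assert t.loc[("exclusive", "y"), "n_total"] == 1

    def test_identical_sets_all_in_triple_intersection(self):
        s = {"a", "b", "c"}
        summ = overlap_summary({"x": s, "y": s, "z": s})
        t = summ.table.set_index(["kind", "members"])
        assert t.loc[("intersection", "x+y+z"), "n_total"] == 3
        assert (t.loc["exclusive"]["n_total"] == 0).all()

    def test_noncanonical_restriction(self):
        summ = overlap_summary({"x": {"a", "b"}, "y": {"b", "c"}},
                               noncanonical={"b"})
        t = summ.table.set_index(["kind", "members"])
        assert t.loc[("intersection", "x+y"), "n_noncanonical"] == 1
        assert t.loc[("set_size", "x"), "n_noncanonical"] == 1

    def test_single_group_is_error(self):
        with pytest.raises(ValueError):
            overlap_summary({"x": {"a"}})

    def test_inclusion_exclusion_on_random_families(self, rng):
        universe = [f"p{i}" for i in range(200)]
        for _ in range(10):
            k = int(rng.integers(2, 5))
            sets = {
                f"g{j}": {universe[i] for i in
                          rng.choice(200, rng.integers(10, 100), replace=False)}
                for j in range(k)
            }
            assert overlap_summary(sets).inclusion_exclusion_holds()

    def test_planted_engine_overlap_recovered(self, bundle):
        engines = list(bundle.id_truth)
        sets = {}
        for engine, table in bundle.id_tables.items():
            filtered = load_and_filter(table, db=None)
            sets[engine] = set(filtered["accession"])
        assert sets == bundle.id_truth
        summ = overlap_summary(sets)
        t = summ.table.set_index(["kind", "members"])
        both = "+".join(sorted(engines))
        assert t.loc[("intersection", both), "n_total"] == bundle.spec.id_n_common
        a, b = sorted(engines)
        assert t.loc[("exclusive", a), "n_total"] == bundle.spec.id_n_uniqueA
        assert t.loc[("exclusive", b), "n_total"] == bundle.spec.id_n_uniqueB
        assert summ.inclusion_exclusion_holds()
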