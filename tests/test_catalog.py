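"""Catalog assembly, age assignment, cross-validation, paralog collapse."""

import pandas as pd
import pytest

from sfpage.catalog import (
    UNASSIGNED,
    Catalog,
    GeneRecord,
    assemble_catalog,
    assign_ages,
    collapse_paralogs,
    cross_validate_ages,
    read_gene_table,
    write_gene_table,
)


class TestReadGeneTable:
    def test_reads_unique_rows(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tsymbol\ng1\ts1\ng2\ts2\ng3\ts3\n")
        df = read_gene_table(p)
        assert len(df) == 3
        assert list(df["gene_id"]) == ["g1", "g2", "g3"]

    def test_duplicate_id_strict_errors_naming_the_id(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\ng1\ng2\ng1\n")
        with pytest.raises(ValueError, match="g1"):
            read_gene_table(p)
        assert len(read_gene_table(p, on_duplicate="first")) == 2

    def test_missing_id_column_and_empty_file_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("name\ng1\n")
        with pytest.raises(ValueError, match="gene_id"):
            read_gene_table(p)
        p.write_text("gene_id\n")
        with pytest.raises(ValueError, match="no data"):
            read_gene_table(p)

    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)], "age_class": list("ABCDE") * 2}
        )
        p = tmp_path / "rt.tsv"
        write_gene_table(df, p)
        back = read_gene_table(p)
        pd.testing.assert_frame_equal(df, back)

    def test_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("# provenance comment\ngene_id\ng1\n")
        assert len(read_gene_table(p)) == 1


class TestAssembleCatalog:
    def test_union_and_intersection(self):
        c = assemble_catalog({"g1", "g2"}, {"g2", "g3"})
        assert len(c) == 3
        assert c.conservative_ids == {"g2"}
        assert c.get("g1").in_list_a and not c.get("g1").in_list_b
        assert c.get("g2").in_list_a and c.get("g2").in_list_b

    def test_identical_lists_collapse(self):
        c = assemble_catalog({"g1", "g2"}, {"g1", "g2"})
        assert c.ids == c.conservative_ids == {"g1", "g2"}

    def test_symmetric_up_to_flag_labels(self):
        c1 = assemble_catalog({"g1", "g2"}, {"g2", "g3"})
        c2 = assemble_catalog({"g2", "g3"}, {"g1", "g2"})
        assert c1.ids == c2.ids
        assert c1.conservative_ids == c2.conservative_ids
        for g in c1.ids:
            assert c1.get(g).in_list_a == c2.get(g).in_list_b

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            assemble_catalog(set(), {"g1"})

    def test_paper_like_counts_recovered(self, paper_bundle, aged_catalog):
        # generator plants |union|=357, |intersection|=228, equal unique shares
        assert len(aged_catalog) == 357
        assert len(aged_catalog.conservative_ids) == 228
        cat = paper_bundle["catalog"]
        only_a = len(set(cat.list_a) - set(cat.list_b))
        only_b = len(set(cat.list_b) - set(cat.list_a))
        assert abs(only_a - only_b) <= 1
        assert only_a + only_b + 228 == 357

    def test_duplicate_ids_rejected_by_catalog(self):
        rec = GeneRecord("g1", in_list_a=True)
        with pytest.raises(ValueError, match="duplicate"):
            Catalog((rec, rec))


class TestAssignAges:
    def test_full_mapping_leaves_nothing_unassigned(self):
        c = assemble_catalog({"g1", "g2", "g3"}, {"g3", "g4", "g5"})
        c = assign_ages(c, {f"g{i}": "A" for i in range(1, 6)})
        assert not c.unassigned_ids

    def test_exception_gene_stays_unassigned_without_warning(self, caplog):
        c = assemble_catalog({"g1", "g2"}, {"g2", "g3", "g4", "g5"})
        ages = {g: "B" for g in ["g1", "g2", "g3", "g4"]}
        with caplog.at_level("WARNING"):
            c = assign_ages(c, ages, exceptions={"g5"})
        assert c.unassigned_ids == {"g5"}
        assert not caplog.records

    def test_missing_gene_warns_but_is_not_fatal(self, caplog):
        c = assemble_catalog({"g1"}, {"g2"})
        with caplog.at_level("WARNING"):
            c = assign_ages(c, {"g1": "A"})
        assert c.unassigned_ids == {"g2"}
        assert any("missing" in r.message for r in caplog.records)

    def test_unknown_class_rejected(self):
        c = assemble_catalog({"g1"}, {"g1"})
        with pytest.raises(ValueError, match="unknown classes"):
            assign_ages(c, {"g1": "Z"})

    def test_planted_class_counts_recovered(self, paper_bundle, aged_catalog):
        truth = paper_bundle["catalog"].truth["class_counts"]
        assert aged_catalog.class_counts() == truth


class TestCrossValidateAges:
    @staticmethod
    def _catalog(classes):
        recs = tuple(
            GeneRecord(f"g{i}", in_list_a=True, age_class=c) for i, c in enumerate(classes)
        )
        return Catalog(recs)

    def test_planted_discrepancy_rate(self, paper_bundle, aged_catalog):
        rep = cross_validate_ages(aged_catalog, paper_bundle["catalog"].ortholog_ids)
        assert rep.n_checked == 178
        assert rep.n_discrepant == 5
        assert round(rep.rate_percent, 2) == 2.81

    def test_all_old_classes_give_zero_rate(self):
        c = self._catalog("AAAB")
        rep = cross_validate_ages(c, c.ids)
        assert rep.n_discrepant == 0 and rep.rate_percent == 0.0

    def test_young_classes_counted_as_discrepant(self):
        c = self._catalog("AADE")
        rep = cross_validate_ages(c, c.ids)
        assert rep.n_checked == 4
        assert set(rep.discrepant_ids) == {"g2", "g3"}

    def test_invariant_under_input_order(self, paper_bundle, aged_catalog):
        ids = paper_bundle["catalog"].ortholog_ids
        r1 = cross_validate_ages(aged_catalog, ids)
        r2 = cross_validate_ages(aged_catalog, list(reversed(ids)))
        assert r1.rate_percent == r2.rate_percent

    def test_non_members_skipped_and_empty_overlap_errors(self):
        c = self._catalog("AA")
        rep = cross_validate_ages(c, ["g0", "not_in_catalog"])
        assert rep.n_checked == 1 and rep.skipped_ids == ("not_in_catalog",)
        with pytest.raises(ValueError):
            cross_validate_ages(c, ["absent"])


class TestCollapseParalogs:
    def test_pair_collapses_to_one_representative(self):
        c = Catalog(
            (
                GeneRecord("g1", in_list_a=True, age_class="E"),
                GeneRecord("g2", in_list_a=True, age_class="E"),
            )
        )
        out = collapse_paralogs(c, {"g1": "p1", "g2": "p1"})
        assert len(out) == 1 and out.records[0].age_class == "E"
        assert out.records[0].gene_id == "g1"  # lexicographic tie-break

    def test_no_groups_is_identity(self, aged_catalog):
        out = collapse_paralogs(aged_catalog, {})
        assert out.records == aged_catalog.records

    def test_conflicting_ages_keep_oldest(self, caplog):
        c = Catalog(
            (
                GeneRecord("g1", in_list_a=True, age_class="E"),
                GeneRecord("g2", in_list_a=True, age_class="B"),
            )
        )
        with caplog.at_level("WARNING"):
            out = collapse_paralogs(c, {"g1": "p", "g2": "p"})
        assert out.records[0].age_class == "B"
        assert any("conflicting" in r.message for r in caplog.records)

    def test_group_arithmetic_and_idempotence(self, aged_catalog):
        ids = sorted(aged_catalog.ids)[:30]
        groups = {g: f"p{i // 3}" for i, g in enumerate(ids)}  # 10 groups of 3
        out = collapse_paralogs(aged_catalog, groups)
        assert len(out) == len(aged_catalog) - 20
        again = collapse_paralogs(out, groups)
        assert again.records == out.records

    def test_representative_prefers_completeness(self):
        c = Catalog(
            (
                GeneRecord("g1", in_list_a=True),
                GeneRecord("g2", in_list_a=True, symbol="sym", age_class="A"),
            )
        )
        out = collapse_paralogs(c, {"g1": "p", "g2": "p"})
        assert out.records[0].gene_id == "g2"
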