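"""Exposure-catalog ingestion, keyword mapping and presence-matrix filtering."""

import numpy as np
import pandas as pd
import pytest

from coexmix.catalog import (
    ListPresenceRecord,
    build_presence_matrix,
    filter_min_categories,
    load_keyword_map,
    load_list_presence,
    map_keywords,
    normalize_chemical_id,
    read_presence_matrix,
    write_presence_matrix,
)


class TestNormalizeChemicalId:
    @pytest.mark.parametrize(
        "raw,expected",
        [(" 103-41-3 ", "103-41-3"), ("dtxsid50 20023", "DTXSID5020023"), ("94-26-8", "94-26-8")],
    )
    def test_normalizes(self, raw, expected):
        assert normalize_chemical_id(raw) == expected

    def test_idempotent(self):
        raw = "  DtxSiD 123 "
        once = normalize_chemical_id(raw)
        assert normalize_chemical_id(once) == once


class TestLoadListPresence:
    def test_duplicates_preserved(self, tmp_path):
        p = tmp_path / "lp.csv"
        p.write_text(
            "chemical_id,preferred_name,keyword\n"
            "A,ChemA,pesticides\nA,ChemA,pesticides\nB,ChemB,shampoo\n"
        )
        recs = load_list_presence(p)
        assert len(recs) == 3  # duplicates pass through untouched

    def test_blank_keyword_rejected_with_warning(self, tmp_path, caplog):
        p = tmp_path / "lp.csv"
        p.write_text("chemical_id,preferred_name,keyword\nA,ChemA,pesticides\nB,ChemB,\n")
        with caplog.at_level("WARNING"):
            recs = load_list_presence(p)
        assert len(recs) == 1
        assert "1 row(s)" in caplog.text

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        chems = [f"CHEM{i:02d}" for i in range(10)]
        kws = ["pesticides", "shampoo", "paint", "flooring"]
        original = [
            ListPresenceRecord(c, f"Chemical {c}", k)
            for c in chems
            for k in kws
            if rng.random() < 0.6
        ]
        p = tmp_path / "lp.csv"
        pd.DataFrame(original, columns=["chemical_id", "preferred_name", "keyword"]).to_csv(
            p, index=False
        )
        assert load_list_presence(p) == original

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_list_presence(tmp_path / "nope.csv")

    def test_missing_column(self, tmp_path):
        p = tmp_path / "lp.csv"
        p.write_text("chemical_id,name\nA,ChemA\n")
        with pytest.raises(KeyError, match="keyword"):
            load_list_presence(p)

    def test_empty_table(self, tmp_path):
        p = tmp_path / "lp.csv"
        p.write_text("chemical_id,preferred_name,keyword\n")
        with pytest.raises(ValueError, match="no data rows"):
            load_list_presence(p)


class TestMapKeywords:
    MAPPING = {
        "laundry detergent": "household care and cleaning products",
        "shampoo": "personal care",
    }

    def test_simple_mapping(self):
        recs = [
            ListPresenceRecord("A", "A", "laundry detergent"),
            ListPresenceRecord("B", "B", "shampoo"),
        ]
        pairs = map_keywords(recs, self.MAPPING)
        assert pairs == [
            ("A", "household care and cleaning products"),
            ("B", "personal care"),
        ]

    def test_same_category_collapses(self):
        mapping = {"kw1": "personal care", "kw2": "personal care"}
        recs = [ListPresenceRecord("A", "A", "kw1"), ListPresenceRecord("A", "A", "kw2")]
        assert map_keywords(recs, mapping) == [("A", "personal care")]

    def test_case_insensitive(self):
        recs = [ListPresenceRecord("A", "A", " Shampoo ")]
        assert map_keywords(recs, self.MAPPING) == [("A", "personal care")]

    def test_unmapped_policies(self, caplog):
        recs = [ListPresenceRecord("A", "A", "mystery keyword")]
        with caplog.at_level("WARNING"):
            assert map_keywords(recs, self.MAPPING) == []
        assert "mystery keyword" in caplog.text
        with pytest.raises(KeyError):
            map_keywords(recs, self.MAPPING, unmapped_policy="error")

    def test_many_to_one_bounds_category_count(self):
        # 117 keywords funneled through a 117 -> 30 map never exceed 30 categories
        mapping = {f"kw{i}": f"cat{i % 30}" for i in range(117)}
        recs = [ListPresenceRecord(f"C{i % 7}", "x", f"kw{i}") for i in range(117)]
        pairs = map_keywords(recs, mapping)
        assert len({cat for _, cat in pairs}) <= 30


class TestBuildPresenceMatrix:
    def test_small_example(self):
        m = build_presence_matrix([("A", "x"), ("A", "y"), ("B", "x")])
        assert m.values.tolist() == [[1, 1], [1, 0]]
        assert list(m.index) == ["A", "B"] and list(m.columns) == ["x", "y"]

    def test_order_and_duplication_invariance(self):
        pairs = [("A", "x"), ("B", "x"), ("A", "y")]
        m1 = build_presence_matrix(pairs)
        m2 = build_presence_matrix(pairs[::-1] + pairs)
        pd.testing.assert_frame_equal(m1, m2)

    def test_empty_pairs(self):
        with pytest.raises(ValueError):
            build_presence_matrix([])

    def test_tsv_round_trip(self, tmp_path):
        m = build_presence_matrix([("A", "x"), ("A", "y"), ("B", "y")])
        write_presence_matrix(m, tmp_path / "m.tsv", {"note": "test"})
        back = read_presence_matrix(tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(m.astype("int8"), back)


class TestFilterMinCategories:
    def test_row_sum_threshold(self):
        m = pd.DataFrame(
            [[1, 0, 0], [1, 1, 0], [1, 1, 1]], index=["a", "b", "c"], columns=["x", "y", "z"]
        )
        res = filter_min_categories(m, 2)
        assert list(res.matrix.index) == ["b", "c"]
        assert res.removed_chemicals == [("a", 1)]

    def test_min_count_one_is_identity(self):
        m = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"], columns=["x", "y"])
        res = filter_min_categories(m, 1)
        pd.testing.assert_frame_equal(res.matrix, m)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(50, 10)),
            index=[f"c{i:02d}" for i in range(50)],
            columns=[f"s{j}" for j in range(10)],
        )
        expected_rows = {i for i in m.index if m.loc[i].sum() >= 2}
        res = filter_min_categories(m, 2)
        assert set(res.matrix.index) == expected_rows

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(30, 6)),
            index=[f"c{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(6)],
        )
        once = filter_min_categories(m, 2).matrix
        twice = filter_min_categories(once, 2).matrix
        pd.testing.assert_frame_equal(once, twice)

    def test_all_zero_column_dropped(self):
        m = pd.DataFrame(
            [[1, 1, 0], [1, 1, 0]], index=["a", "b"], columns=["x", "y", "z"]
        )
        res = filter_min_categories(m, 2)
        assert res.dropped_categories == ["z"]
        assert list(res.matrix.columns) == ["x", "y"]

    def test_no_rows_left_errors(self):
        m = pd.DataFrame([[1, 0]], index=["a"], columns=["x", "y"])
        with pytest.raises(ValueError, match="nothing to analyze"):
            filter_min_categories(m, 2)


def test_keyword_map_loader(tmp_path):
    p = tmp_path / "map.csv"
    p.write_text("keyword,exposure_source_category\nShampoo,personal care\nsoap,personal care\n")
    mapping = load_keyword_map(p)
    assert mapping == {"shampoo": "personal care", "soap": "personal care"}
    bad = tmp_path / "bad.csv"
    bad.write_text("keyword,exposure_source_category\nkw,cat1\nkw,cat2\n")
    with pytest.raises(ValueError, match="multiple categories"):
        load_keyword_map(bad)
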