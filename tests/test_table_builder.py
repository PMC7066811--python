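"""Merging, quantile binning, de-identification and deterministic output."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import pytest

from spatiopit.table_builder import (
    BinSpec,
    DeidPolicy,
    IntegrityError,
    PolicyGapError,
    SchemaError,
    apply_binning,
    bin_quantiles,
    deidentify,
    merge_sources,
    write_feature_table,
)


def _clinical(pids=("p1", "p2", "p3")):
    return pd.DataFrame(
        {
            "patient_id": list(pids),
            "year": 2010,
            "visits": range(len(pids)),
        }
    )


class TestMergeSources:
    def test_all_sources_present(self):
        exp = pd.DataFrame(
            {"patient_id": ["p1", "p2", "p3"], "year": 2010, "pm25": [7.0, 8.0, 9.0]}
        )
        acs = pd.DataFrame({"patient_id": ["p1", "p2", "p3"], "ur": "urban"})
        out = merge_sources(_clinical(), exposures=exp, acs=acs)
        assert len(out) == 3
        assert out["pm25"].notna().all()
        assert out["ur"].notna().all()

    def test_patient_missing_from_source_keeps_row(self):
        acs = pd.DataFrame({"patient_id": ["p1"], "ur": ["rural"]})
        out = merge_sources(_clinical(), acs=acs)
        assert len(out) == 3
        assert out.set_index("patient_id")["ur"].isna().sum() == 2

    def test_duplicate_keys_name_the_source(self):
        bad = pd.DataFrame({"patient_id": ["p1", "p1"], "pm25": [1.0, 2.0], "year": 2010})
        with pytest.raises(IntegrityError, match="exposures"):
            merge_sources(_clinical(), exposures=bad)

    def test_matches_dictionary_merge_oracle(self):
        rng = np.random.default_rng(41)
        pids = [f"p{i:03d}" for i in range(100)]
        clinical = _clinical(pids)
        road = pd.DataFrame(
            {
                "patient_id": rng.permutation(pids)[:80],
                "dist": rng.uniform(0, 500, 80),
            }
        )
        out = merge_sources(clinical, roads=road).set_index("patient_id")
        oracle = dict(zip(road["patient_id"], road["dist"]))
        for pid in pids:
            want = oracle.get(pid)
            got = out.loc[pid, "dist"]
            assert (pd.isna(got) and want is None) or got == pytest.approx(want)


class TestBinQuantiles:
    def test_four_values_two_even_bins(self):
        labels, edges = bin_quantiles([1, 2, 3, 4], n_bins=2)
        assert labels.value_counts().tolist() == [2, 2]
        assert len(edges) == 3

    def test_edges_match_empirical_quantile_oracle(self):
        rng = np.random.default_rng(43)
        values = rng.uniform(0, 100, size=1000)
        labels, edges = bin_quantiles(values, n_bins=5)
        counts = labels.value_counts()
        assert len(counts) == 5
        assert all(abs(c - 200) <= 1 for c in counts)
        oracle = np.quantile(values, [0.2, 0.4, 0.6, 0.8], method="linear")
        assert edges[1:-1] == pytest.approx(list(oracle))
        assert edges[-1] == pytest.approx(values.max())

    def test_labels_are_right_closed_ranges(self):
        labels, _ = bin_quantiles([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], n_bins=2)
        assert all(re.fullmatch(r"\(.+, .+\]", s) for s in labels)

    def test_constant_vector_collapses_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="spatiopit"):
            labels, edges = bin_quantiles([5.0] * 20, n_bins=5)
        assert labels.nunique() == 1
        assert "collapsing" in caplog.text

    def test_all_missing_is_noop_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="spatiopit"):
            labels, edges = bin_quantiles([np.nan, np.nan], n_bins=2)
        assert edges == []
        assert labels.isna().all()

    def test_binning_preserves_totals(self):
        rng = np.random.default_rng(47)
        values = np.where(rng.random(300) < 0.1, np.nan, rng.normal(10, 3, 300))
        labels, _ = bin_quantiles(values, n_bins=4)
        assert labels.value_counts().sum() == np.count_nonzero(~np.isnan(values))

    def test_minimum_included_in_first_bin(self):
        labels, _ = bin_quantiles([1.0, 2.0, 3.0, 4.0], n_bins=2)
        assert labels.notna().all()


class TestDeidentify:
    def _row(self):
        return pd.DataFrame(
            {
                "patient_id": ["p1"],
                "lat": [35.0],
                "lon": [-79.0],
                "birth_date": ["1950-06-01"],
                "year": [2010],
                "age_in_years": [60],
                "pm25_bin": ["(7.0, 9.0]"],
            }
        )

    POLICY = DeidPolicy(
        identifier_columns=("patient_id",),
        geocode_columns=("lat", "lon"),
        date_columns=("birth_date",),
        age_column="age_in_years",
    )

    def test_identifiers_and_geocodes_removed_year_kept(self):
        out = deidentify(self._row(), self.POLICY)
        assert set(out.columns).isdisjoint({"patient_id", "lat", "lon"})
        assert out.loc[0, "year"] == 2010
        assert out.loc[0, "birth_date"] == "1950"

    def test_age_over_89_recoded_to_top_bin(self):
        df = self._row()
        df["age_in_years"] = 92
        out = deidentify(df, self.POLICY)
        assert out.loc[0, "age_in_years"] == "90+"

    def test_age_89_not_recoded(self):
        df = self._row()
        df["age_in_years"] = 89
        assert deidentify(df, self.POLICY).loc[0, "age_in_years"] == "89"

    def test_idempotent(self):
        once = deidentify(self._row(), self.POLICY)
        twice = deidentify(once, self.POLICY)
        pd.testing.assert_frame_equal(once, twice)

    def test_policy_gap_detected_by_deny_patterns(self):
        df = self._row().rename(columns={"lat": "home_latitude"})
        with pytest.raises(PolicyGapError, match="home_latitude"):
            deidentify(df, self.POLICY)

    def test_keep_list_defines_output_schema(self):
        policy = DeidPolicy(
            identifier_columns=("patient_id",),
            geocode_columns=("lat", "lon"),
            date_columns=("birth_date",),
            keep=("year", "pm25_bin"),
        )
        out = deidentify(self._row(), policy)
        assert list(out.columns) == ["year", "pm25_bin"]


class TestWriteFeatureTable:
    def test_zero_rows_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_feature_table(pd.DataFrame(columns=["a", "b"]), str(path))
        assert path.read_text() == "a,b\n"

    def test_round_trip_identity(self, tmp_path):
        df = pd.DataFrame({"x": [1, 2], "y": ["u", "v"]})
        path = tmp_path / "t.csv"
        write_feature_table(df, str(path))
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(
            back.sort_values(["x"]).reset_index(drop=True), df
        )

    def test_same_input_byte_identical(self, tmp_path):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x": rng.integers(0, 5, 50), "y": rng.random(50)})
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_feature_table(df, str(p1))
        write_feature_table(df.sample(frac=1, random_state=0), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_heterogeneous_schemas_rejected(self, tmp_path):
        rows = [{"a": 1}, {"b": 2}]
        with pytest.raises(SchemaError):
            write_feature_table(rows, str(tmp_path / "x.csv"))

    def test_missing_encoded_as_empty_field(self, tmp_path):
        df = pd.DataFrame({"a": [1.0, np.nan], "b": ["x", "y"]})
        path = tmp_path / "m.csv"
        write_feature_table(df, str(path))
        assert ",y" in path.read_text().replace("\r\n", "\n")


def test_apply_binning_manifest_records_edges():
    df = pd.DataFrame({"v": np.arange(100, dtype=float)})
    binned, manifest = apply_binning(df, [BinSpec("v", n_bins=4)])
    assert manifest["v"]["method"] == "quantile"
    assert len(manifest["v"]["edges"]) == 5
    assert binned["v"].nunique() == 4


def test_bin_spec_validation():
    with pytest.raises(ValueError):
        BinSpec("v", n_bins=1)
    with pytest.raises(ValueError):
        BinSpec("v", method="fixed_edges", edges=[3.0, 1.0])
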