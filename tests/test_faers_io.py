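"""FAERS dialect parsing, partial dates, and quarterly loading."""

from __future__ import annotations

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faersignal.dates import (INVALID, MISSING, PartialDate,
                              parse_partial_date, parse_partial_date_status)
from faersignal.faers_io import (FaersFormatError, load_quarters,
                                 parse_delimited_table, quarter_file_name,
                                 write_delimited_table)


class TestParseDelimitedTable:
    def test_maps_fields_by_header(self):
        rows = parse_delimited_table(
            io.StringIO("primaryid$caseid$fda_dt$sex\n1001$111$20230401$F\n"),
            "DEMO")
        assert len(rows) == 1
        assert rows[0].payload == {"primaryid": "1001", "caseid": "111",
                                   "fda_dt": "20230401", "sex": "F"}
        assert rows[0].primaryid == "1001"

    def test_header_only_gives_empty_list(self):
        assert parse_delimited_table(io.StringIO("primaryid$caseid\n"),
                                     "REAC") == []

    def test_wrong_field_count_strict_names_line(self):
        text = "primaryid$caseid$fda_dt$sex\n1$2$3\n"
        with pytest.raises(FaersFormatError, match="line 2"):
            parse_delimited_table(io.StringIO(text), "DEMO", strict=True)

    def test_wrong_field_count_lenient_skips(self):
        text = "primaryid$caseid$fda_dt$sex\n1$2$3\n9$8$7$M\n"
        rows = parse_delimited_table(io.StringIO(text), "DEMO", strict=False)
        assert [r.primaryid for r in rows] == ["9"]

    def test_missing_primaryid_header_is_format_error(self):
        with pytest.raises(FaersFormatError, match="DRUG"):
            parse_delimited_table(io.StringIO("caseid$drugname\n1$X\n"), "DRUG")

    def test_empty_values_preserved_not_null_coerced(self):
        rows = parse_delimited_table(
            io.StringIO("primaryid$caseid$sex\n1$$\n"), "DEMO")
        assert rows[0].payload["caseid"] == ""
        assert rows[0].payload["sex"] == ""

    @given(st.lists(
        st.lists(st.text(alphabet=st.characters(
            blacklist_characters="$\n\r", min_codepoint=32, max_codepoint=126),
            max_size=8).map(str.strip), min_size=3, max_size=3),
        max_size=20))
    @settings(derandomize=True, deadline=None, max_examples=50)
    def test_write_parse_round_trip(self, table):
        """Writing rows back to '$' text and re-parsing is the identity."""
        header = ("PRIMARYID", "CASEID", "VAL")
        text = "$".join(header) + "\n" + "".join(
            "$".join(row) + "\n" for row in table)
        rows = parse_delimited_table(io.StringIO(text), "DEMO")
        out = io.StringIO()
        write_delimited_table(rows, out, header=header)
        rows2 = parse_delimited_table(io.StringIO(out.getvalue()), "DEMO")
        assert [r.payload for r in rows] == [r.payload for r in rows2]


class TestPartialDate:
    @pytest.mark.parametrize("raw, expected, status", [
        ("20220322", PartialDate(2022, 3, 22), "day"),
        ("202203", PartialDate(2022, 3), "month"),
        ("2022", PartialDate(2022), "year"),
        ("", None, MISSING),
        ("   ", None, MISSING),
        ("20221332", None, INVALID),      # month 13
        ("20220230", None, INVALID),      # Feb 30
        ("20220100", None, INVALID),      # day 00
        ("2022032", None, INVALID),       # 7 digits
        ("abcd1234", None, INVALID),
        ("18990101", None, INVALID),      # implausible year
    ])
    def test_parse_taxonomy(self, raw, expected, status):
        date, got_status = parse_partial_date_status(raw)
        assert date == expected
        assert got_status == status
        assert parse_partial_date(raw) == expected

    @given(st.text(max_size=12))
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_parser_is_total(self, raw):
        """Arbitrary strings never raise; status is always classified."""
        date, status = parse_partial_date_status(raw)
        assert status in ("day", "month", "year", MISSING, INVALID)
        assert (date is None) == (status in (MISSING, INVALID))

    @pytest.mark.parametrize("raw", ["20220322", "202203", "2022"])
    def test_string_round_trip(self, raw):
        assert parse_partial_date(raw).to_string() == raw

    def test_day_requires_month(self):
        with pytest.raises(ValueError):
            PartialDate(2022, None, 5)


class TestLoadQuarters:
    def test_bundles_chronological_and_counts_match_manifest(
            self, small_quarters, small_synth_dir):
        _, manifest = small_synth_dir
        labels = [b.quarter_label for b in small_quarters]
        assert labels == sorted(labels)
        total_demo = sum(b.row_counts["DEMO"] for b in small_quarters)
        assert total_demo == manifest["n_demo_rows"]

    def test_missing_mandatory_table_names_quarter(self, tmp_path):
        (tmp_path / "DEMO22Q1.txt").write_text("primaryid$caseid\n1$1\n")
        (tmp_path / "DRUG22Q1.txt").write_text("primaryid$drugname\n1$X\n")
        with pytest.raises(FileNotFoundError, match="2022Q1.*REAC"):
            load_quarters(tmp_path, ["2022Q1"])

    def test_file_names_resolve_case_insensitively(self, tmp_path):
        (tmp_path / "demo22q1.txt").write_text("primaryid$caseid\n1$1\n")
        (tmp_path / "Drug22Q1.TXT").write_text("primaryid$drugname\n1$X\n")
        (tmp_path / "REAC22Q1.txt").write_text("primaryid$pt\n1$HEADACHE\n")
        bundles = load_quarters(tmp_path, ["2022Q1"])
        assert bundles[0].row_counts == {"DEMO": 1, "DRUG": 1, "REAC": 1}

    def test_orphan_child_rows_recorded_not_dropped(self, tmp_path):
        (tmp_path / "DEMO22Q1.txt").write_text("primaryid$caseid\n1$1\n")
        (tmp_path / "DRUG22Q1.txt").write_text("primaryid$drugname\n99$X\n")
        (tmp_path / "REAC22Q1.txt").write_text("primaryid$pt\n1$HEADACHE\n")
        [bundle] = load_quarters(tmp_path, ["2022Q1"])
        assert bundle.orphans == {"DRUG": ["99"]}
        assert bundle.row_counts["DRUG"] == 1  # kept

    def test_quarter_file_name(self):
        assert quarter_file_name("DEMO", "2024Q1") == "DEMO24Q1.txt"
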