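"""Deduplication, drug matching, cohort construction, descriptives."""

from __future__ import annotations

import pytest

from faersignal.cohort import (build_cohort, characteristics_table,
                               deduplicate, match_target, normalize_drug_name,
                               round_half_up)
from faersignal.faers_io import QuarterBundle, RawRow


def demo_row(primaryid: str, caseid: str, fda_dt: str, **extra) -> RawRow:
    payload = {"primaryid": primaryid, "caseid": caseid, "fda_dt": fda_dt}
    payload.update(extra)
    return RawRow(table="DEMO", payload=payload)


class TestDeduplicate:
    def test_most_recent_fda_dt_survives(self):
        rows = [demo_row("1110", "111", "20230101"),
                demo_row("1111", "111", "20230401")]
        assert deduplicate(rows) == {"111": "1111"}

    def test_fda_dt_tie_breaks_to_larger_primaryid(self):
        rows = [demo_row("2221", "222", "20230301"),
                demo_row("2220", "222", "20230301")]
        assert deduplicate(rows) == {"222": "2221"}

    def test_single_version_is_identity(self):
        assert deduplicate([demo_row("5", "9", "20220101")]) == {"9": "5"}

    def test_unparseable_fda_dt_loses_to_valid(self):
        rows = [demo_row("9999", "333", "garbage"),
                demo_row("3330", "333", "20220101")]
        assert deduplicate(rows) == {"333": "3330"}

    def test_missing_caseid_forms_singleton(self):
        rows = [demo_row("7", "", "20220101"), demo_row("8", "", "20220101")]
        assert sorted(deduplicate(rows).values()) == ["7", "8"]

    def test_idempotent_on_surviving_rows(self, small_quarters):
        demo = [r for q in small_quarters for r in q.rows_by_table["DEMO"]]
        once = deduplicate(demo)
        survivors = {r.primaryid: r for r in demo}
        again = deduplicate(survivors[pid] for pid in once.values())
        assert set(again.values()) == set(once.values())

    def test_recovers_true_case_count_with_duplicate_injection(
            self, small_quarters, small_synth_dir):
        """10% duplicate versions: dedup gets back exactly the true cases."""
        _, manifest = small_synth_dir
        demo = [r for q in small_quarters for r in q.rows_by_table["DEMO"]]
        assert len(demo) > manifest["n_cases"]  # duplicates were injected
        assert len(deduplicate(demo)) == manifest["n_cases"]


class TestDrugMatching:
    @pytest.mark.parametrize("raw, expected", [
        ("Vyvgart Hytrulo", "VYVGART HYTRULO"),
        ("  efgartigimod ", "EFGARTIGIMOD"),
        ("EFGARTIGIMOD   ALFA-FCAB", "EFGARTIGIMOD ALFA-FCAB"),
    ])
    def test_normalize(self, raw, expected):
        assert normalize_drug_name(raw) == expected

    DICT = {"EFGARTIGIMOD", "VYVGART", "VYVGART HYTRULO"}

    @pytest.mark.parametrize("name, expected", [
        ("VYVGART", True),
        ("VYVANSE", False),                 # prefix must end at a word boundary
        ("EFGARTIGIMOD ALFA-FCAB", True),   # whole-word prefix
        ("VYVGART HYTRULO 1000MG", True),
        ("XVYVGART", False),
    ])
    def test_prefix_matching(self, name, expected):
        assert match_target(name, self.DICT) is expected

    def test_exact_mode_rejects_suffixed_names(self):
        assert not match_target("EFGARTIGIMOD ALFA-FCAB", self.DICT,
                                mode="exact")
        assert match_target("VYVGART", self.DICT, mode="exact")


def _mini_quarter(drug_specs):
    """One-quarter bundle: one report per (primaryid, [(name, role)])."""
    bundle = QuarterBundle(quarter_label="2022Q1")
    demo, drug, reac = [], [], []
    for pid, drugs in drug_specs:
        demo.append(demo_row(pid, f"c{pid}", "20220301", sex="F"))
        for seq, (name, role) in enumerate(drugs, 1):
            drug.append(RawRow("DRUG", {"primaryid": pid, "drug_seq": str(seq),
                                        "role_cod": role, "drugname": name}))
        reac.append(RawRow("REAC", {"primaryid": pid, "pt": "HEADACHE"}))
    bundle.rows_by_table = {"DEMO": demo, "DRUG": drug, "REAC": reac}
    return bundle


class TestBuildCohort:
    DICT = {"EFGARTIGIMOD", "VYVGART", "VYVGART HYTRULO"}

    def test_primary_suspect_rule(self):
        bundle = _mini_quarter([
            ("1", [("VYVGART", "PS")]),                      # target
            ("2", [("VYVGART", "C")]),                       # background: role C
            ("3", [("VYVGART", "PS"), ("PREDNISONE", "SS")]),  # target: >=1 PS
            ("4", [("ASPIRIN", "PS")]),                      # background
        ])
        dedup = deduplicate(bundle.rows_by_table["DEMO"])
        cohort = build_cohort([bundle], dedup, self.DICT)
        assert {r.primaryid for r in cohort.target_reports} == {"1", "3"}
        assert {r.primaryid for r in cohort.background_reports} == {"2", "4"}

    def test_empty_dictionary_is_error(self):
        bundle = _mini_quarter([("1", [("VYVGART", "PS")])])
        with pytest.raises(ValueError, match="dictionary"):
            build_cohort([bundle], {"c1": "1"}, set())

    def test_partition_covers_all_cases(self, small_cohort, small_synth_dir):
        _, manifest = small_synth_dir
        assert small_cohort.n_reports == manifest["n_cases"]

    def test_target_count_and_pairs_match_generator_truth(
            self, small_cohort, small_synth_dir):
        _, manifest = small_synth_dir
        assert len(small_cohort.target_reports) == manifest["n_target_cases"]
        assert small_cohort.n_target_pairs == manifest["n_target_pairs"]
        assert small_cohort.n_background_pairs == manifest["n_background_pairs"]

    def test_events_are_sets_per_report(self, small_cohort):
        for report in small_cohort.target_reports:
            assert report.events
            assert len(report.events) == len({e for e in report.events})


class TestCharacteristics:
    def test_single_valued_fields_sum_to_100(self, small_cohort):
        df = characteristics_table(small_cohort)
        for characteristic in ("sex", "age_band", "reporter", "receipt_year"):
            total = df[df.characteristic == characteristic]["percent"].sum()
            assert total == pytest.approx(100.0, abs=0.05)

    def test_counts_equal_planted_draws(self, small_cohort):
        df = characteristics_table(small_cohort)
        sex = df[df.characteristic == "sex"].set_index("subgroup")["n"]
        truth = {"F": 0, "M": 0, "unknown": 0}
        for r in small_cohort.target_reports:
            truth[r.sex] += 1
        assert dict(sex) == truth

    def test_rounding_is_half_up_two_decimals(self):
        assert round_half_up(100 * 402 / 3040) == 13.22
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(2.675, 2) == 2.68
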