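"""Disproportionality estimators, thresholds, SOC aggregation and the
reconstruction oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from faersignal.cohort import Cohort, ReportRecord
from faersignal.disprop import (ContingencyTable, ReconstructionError,
                                aggregate_by_soc, apply_blocklist,
                                build_tables, call_signal,
                                compute_signal_stats, ebgm_stats, ic_stats,
                                prr_stats, reconstruct_table, ror_stats)

tables_strategy = st.builds(
    ContingencyTable,
    pt=st.just("PT"),
    a=st.integers(1, 500).map(float),
    b=st.integers(1, 5000).map(float),
    c=st.integers(1, 5000).map(float),
    d=st.integers(1, 500_000).map(float),
)


def _report(pid: str, events: set) -> ReportRecord:
    return ReportRecord(primaryid=pid, caseid=pid, fda_dt=None, event_dt=None,
                        event_dt_status="missing", sex="unknown",
                        age_years=None, reporter="other_unknown",
                        country="unknown", receipt_year_quarter="2022Q1",
                        events=events)


class TestEstimators:
    T = ContingencyTable("X", 10, 90, 100, 9900)

    def test_ror_point_and_ci(self):
        ror, lo, hi = ror_stats(self.T)
        assert ror == pytest.approx(11.0)
        assert lo == pytest.approx(5.5595, abs=1e-3)
        assert hi == pytest.approx(21.7645, abs=1e-3)

    def test_prr_and_chi2(self):
        prr, chi2 = prr_stats(self.T)
        assert prr == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.4472, abs=1e-3)

    def test_ic_and_ic025(self):
        ic, ic025 = ic_stats(self.T)
        assert ic == pytest.approx(3.1988, abs=1e-3)
        assert ic025 == pytest.approx(2.1942, abs=1e-3)

    def test_ebgm_and_ebgm05(self):
        ebgm, ebgm05 = ebgm_stats(self.T)
        assert ebgm == pytest.approx(9.1818, abs=1e-3)
        assert ebgm05 == pytest.approx(4.6409, abs=1e-3)

    def test_balanced_table_is_null(self):
        """Independence: every estimator at its null value."""
        t = ContingencyTable("X", 5, 45, 50, 450)
        assert ror_stats(t)[0] == pytest.approx(1.0)
        prr, chi2 = prr_stats(t)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert ic_stats(t)[0] == pytest.approx(0.0, abs=1e-12)
        assert ebgm_stats(t)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("cells", [(0, 9, 5, 100), (3, 0, 5, 100),
                                       (3, 9, 0, 100), (3, 9, 5, 0)])
    def test_zero_cells_give_null_not_haldane(self, cells):
        t = ContingencyTable("X", *cells)
        assert ror_stats(t) is None
        stats = compute_signal_stats(t)
        assert stats.null_reason is not None
        assert not stats.is_signal

    def test_haldane_flag_restores_estimates_on_zero_cells(self):
        t = ContingencyTable("X", 0, 9, 5, 100)
        stats = compute_signal_stats(t, haldane=True)
        assert stats.ror is not None

    @given(tables_strategy)
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_ic_is_log2_ebgm(self, t):
        """IC and EBGM are the same ratio on different scales — exactly."""
        ic, _ = ic_stats(t)
        ebgm, _ = ebgm_stats(t)
        assert ic == pytest.approx(math.log2(ebgm), abs=1e-12)

    @given(tables_strategy)
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_chi2_equals_expected_count_pearson(self, t):
        """Closed-form chi2 equals the textbook O/E Pearson statistic."""
        _, chi2 = prr_stats(t)
        obs = np.array([[t.a, t.b], [t.c, t.d]])
        ref = chi2_contingency(obs, correction=False).statistic
        assert chi2 == pytest.approx(ref, rel=1e-10)

    @given(tables_strategy)
    @settings(derandomize=True, deadline=None, max_examples=100)
    def test_ci_brackets_point_estimates(self, t):
        ror, lo, hi = ror_stats(t)
        assert lo <= ror <= hi
        ebgm, ebgm05 = ebgm_stats(t)
        assert ebgm05 <= ebgm

    def test_monotone_in_a_with_other_cells_fixed(self):
        previous = None
        for a in range(1, 30):
            t = ContingencyTable("X", a, 500, 300, 50_000)
            point = (ror_stats(t)[0], prr_stats(t)[0], ic_stats(t)[0],
                     ebgm_stats(t)[0])
            if previous is not None:
                assert all(x > y for x, y in zip(point, previous))
            previous = point


class TestBuildTables:
    def test_counting_unit_is_report_pt_pair(self):
        cohort = Cohort(
            target_reports=[_report("1", {"HEADACHE", "NAUSEA"}),
                            _report("2", {"HEADACHE"})],
            background_reports=[_report("3", {"HEADACHE", "RASH"})],
            drug_dictionary={"X"})
        tables = {t.pt: t for t in build_tables(cohort)}
        assert set(tables) == {"HEADACHE", "NAUSEA"}  # no table for RASH-only
        assert tables["HEADACHE"].a == 2
        assert tables["NAUSEA"].a == 1
        assert all(t.a + t.b == 3 for t in tables.values())  # target pairs
        assert all(t.c + t.d == 2 for t in tables.values())

    def test_empty_target_cohort_is_error(self):
        cohort = Cohort([], [_report("3", {"X"})], {"D"})
        with pytest.raises(ValueError):
            build_tables(cohort)

    def test_planted_counts_recovered(self, big_cohort):
        cohort, manifest = big_cohort
        tables = {t.pt: t for t in build_tables(cohort)}
        t = tables["NEPHROLITHIASIS"]
        assert t.a == manifest["target_pt.NEPHROLITHIASIS"]
        assert t.c == manifest["background_pt.NEPHROLITHIASIS"]


class TestSignalCall:
    BASE = dict(ror_ci_low=1.2, a=5, prr=2.5, chi2=10.0, ic025=0.3,
                ebgm05=2.1)

    def _stats(self, ror_ci_low, a, prr, chi2, ic025, ebgm05):
        s = compute_signal_stats(ContingencyTable("X", 10, 90, 100, 9900))
        s.a = a
        s.ror_ci95 = (ror_ci_low, ror_ci_low * 4)
        s.prr, s.chi2, s.ic025, s.ebgm05 = prr, chi2, ic025, ebgm05
        return s

    @pytest.mark.parametrize("override, expected", [
        ({}, True),
        ({"a": 2}, False),            # N >= 3 boundary (fails at 2)
        ({"a": 3}, True),             # inclusive
        ({"ebgm05": 2.0}, False),     # strict >
        ({"ebgm05": 2.0001}, True),
        ({"prr": 2.0}, True),         # inclusive >=
        ({"prr": 1.999}, False),
        ({"chi2": 4.0}, True),        # inclusive >=
        ({"chi2": 3.999}, False),
        ({"ic025": 0.0}, False),      # strict >
        ({"ror_ci_low": 1.0}, False),  # strict >
        ({"ror_ci_low": 1.0001}, True),
    ])
    def test_threshold_truth_table(self, override, expected):
        kwargs = dict(self.BASE, **override)
        assert call_signal(self._stats(**kwargs)) is expected

    def test_joint_rule_requires_all_four(self):
        """Exhaustively: the joint call is the AND of the four flags."""
        passing = self.BASE
        failing = dict(ror_ci_low=0.9, a=2, prr=1.0, chi2=1.0, ic025=-0.5,
                       ebgm05=1.0)
        keys = list(passing)
        for mask in range(2 ** len(keys)):
            kwargs = {k: (passing[k] if mask & (1 << i) else failing[k])
                      for i, k in enumerate(keys)}
            s = self._stats(**kwargs)
            got = call_signal(s)
            assert got == all(s.criteria_flags.values())
            if got:
                assert mask == 2 ** len(keys) - 1


class TestBlocklistAndSoc:
    def _signals(self):
        return [compute_signal_stats(ContingencyTable(pt, 10, 90, 100, 9900))
                for pt in ("MYASTHENIA GRAVIS", "NEPHROLITHIASIS")]

    def test_blocklist_flags_without_deleting(self):
        out = apply_blocklist(self._signals(), {"MYASTHENIA GRAVIS"})
        assert len(out) == 2
        flagged = {s.pt: s.excluded_reason for s in out}
        assert flagged["MYASTHENIA GRAVIS"] == "blocklist"
        assert flagged["NEPHROLITHIASIS"] is None

    def test_empty_blocklist_is_identity(self):
        out = apply_blocklist(self._signals(), set())
        assert all(s.excluded_reason is None for s in out)

    def test_absent_blocklist_pt_is_noop(self):
        out = apply_blocklist(self._signals(), {"NOT A PT"})
        assert all(s.excluded_reason is None for s in out)

    def test_soc_pair_counts_are_additive(self):
        signals = [compute_signal_stats(ContingencyTable("A", 3, 97, 50, 9850)),
                   compute_signal_stats(ContingencyTable("B", 2, 98, 50, 9850)),
                   compute_signal_stats(ContingencyTable("C", 5, 95, 50, 9850))]
        df = aggregate_by_soc(signals, {"A": "SOC1", "B": "SOC1"})
        by_soc = df.set_index("soc")
        assert by_soc.loc["SOC1", "pair_count"] == 5
        assert by_soc.loc["UNMAPPED", "pair_count"] == 5
        assert df["percent"].sum() == pytest.approx(100.0, abs=0.05)


class TestReconstruction:
    def test_round_trip_recovers_cells(self):
        t = ContingencyTable("X", 58, 4000, 9000, 3_000_000)
        ror, _, _ = ror_stats(t)
        prr, chi2 = prr_stats(t)
        rt = reconstruct_table(t.a, ror, prr, chi2)
        assert rt.b == pytest.approx(t.b, rel=1e-3)
        assert rt.c == pytest.approx(t.c, rel=1e-3)
        assert rt.d == pytest.approx(t.d, rel=1e-3)

    def test_impossible_row_reports_nonconvergence(self):
        # any positive table with ROR > 1 has ROR > PRR, so a row claiming
        # PRR above ROR admits no completion
        with pytest.raises(ReconstructionError):
            reconstruct_table(58, 4.0, 7.99, 353.46)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            reconstruct_table(0, 2.0, 2.0, 10.0)
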