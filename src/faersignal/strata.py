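"""Subgroup (sex-stratified) and sensitivity (monotherapy) analyses.

Both re-run the disproportionality pipeline on a restricted dataset.

For sex subgroups the default background scope is *within the stratum*:
female-only target counts are compared against female-only background
counts, so the stratified estimate does not conflate drug effects with
sex-specific reporting patterns. Comparing against the full mixed-sex
background is supported via ``background_scope="full_database"``.

The sensitivity analysis keeps only target reports in which every DRUG
row matches the target dictionary — i.e. no concomitant, interacting,
secondary-suspect or other primary-suspect medication is listed — and
re-scores. Any report listing a second non-target PS drug is dropped a
fortiori: it involves another suspect medication. The background is left
unchanged.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import pandas as pd

from .cohort import Cohort, ReportRecord, round_half_up
from .disprop import SignalStats, build_tables, score_tables

__all__ = [
    "StratumSpec",
    "apply_stratum",
    "subgroup_analysis",
    "sensitivity_exclude_concomitant",
    "subgroup_table",
]

log = logging.getLogger(__name__)

_OPS: dict[str, Callable] = {
    "eq": operator.eq, "ne": operator.ne, "lt": operator.lt,
    "le": operator.le, "gt": operator.gt, "ge": operator.ge,
    "in": lambda value, options: value in options,
}

_FIELDS = {"primaryid", "caseid", "sex", "age_years", "reporter", "country",
           "receipt_year_quarter"}


@dataclass
class StratumSpec:
    """A declarative report filter: all (field, op, value) clauses must hold."""

    name: str
    clauses: List[Tuple[str, str, object]] = field(default_factory=list)
    background_scope: str = "within_stratum"  # or "full_database"

    def __post_init__(self) -> None:
        for fieldname, op, _ in self.clauses:
            if fieldname not in _FIELDS:
                raise ValueError(f"unknown ReportRecord field: {fieldname}")
            if op not in _OPS:
                raise ValueError(f"unknown operator: {op}")

    def matches(self, report: ReportRecord) -> bool:
        return all(_OPS[op](getattr(report, fieldname), value)
                   for fieldname, op, value in self.clauses)


def apply_stratum(cohort: Cohort, spec: StratumSpec) -> Cohort:
    """Restrict a cohort to one stratum (background per the spec's scope)."""
    target = [r for r in cohort.target_reports if spec.matches(r)]
    if spec.background_scope == "within_stratum":
        background = [r for r in cohort.background_reports if spec.matches(r)]
    else:
        background = list(cohort.background_reports)
    return Cohort(target_reports=target, background_reports=background,
                  drug_dictionary=cohort.drug_dictionary,
                  counting_unit=cohort.counting_unit)


def subgroup_analysis(cohort: Cohort, sex: str,
                      pt_to_soc: Optional[dict] = None,
                      background_scope: str = "within_stratum",
                      ) -> List[SignalStats]:
    """Re-run signal detection within one sex stratum (F or M)."""
    if sex not in ("F", "M"):
        raise ValueError("sex stratum must be 'F' or 'M'")
    spec = StratumSpec(name=f"sex_{sex}", clauses=[("sex", "eq", sex)],
                       background_scope=background_scope)
    sub = apply_stratum(cohort, spec)
    if not sub.target_reports:
        log.warning("sex=%s stratum has no target reports", sex)
        return []
    return score_tables(build_tables(sub), pt_to_soc=pt_to_soc)


def sensitivity_exclude_concomitant(cohort: Cohort) -> Cohort:
    """Monotherapy sensitivity cohort: drop any target report listing a
    medication other than the target drug (any role). Background unchanged."""
    kept = [r for r in cohort.target_reports
            if all(d.is_target for d in r.drugs)]
    log.info("sensitivity: %d of %d target reports are target-monotherapy",
             len(kept), len(cohort.target_reports))
    return Cohort(target_reports=kept,
                  background_reports=list(cohort.background_reports),
                  drug_dictionary=cohort.drug_dictionary,
                  counting_unit=cohort.counting_unit)


def subgroup_table(male: Sequence[SignalStats], female: Sequence[SignalStats],
                   min_a: int = 3) -> pd.DataFrame:
    """Side-by-side male/female ROR table; cells with a < min_a suppressed ('-')."""
    def fmt(s: Optional[SignalStats]) -> Tuple[object, str]:
        if s is None or s.a < min_a or s.ror is None:
            return "-", "-"
        lo, hi = s.ror_ci95
        return s.a, (f"{round_half_up(s.ror):.2f} "
                     f"({round_half_up(lo):.2f}-{round_half_up(hi):.2f})")

    m = {s.pt: s for s in male}
    f = {s.pt: s for s in female}
    rows = []
    for pt in sorted(set(m) | set(f)):
        s = m.get(pt) or f.get(pt)
        n_m, ror_m = fmt(m.get(pt))
        n_f, ror_f = fmt(f.get(pt))
        rows.append((s.soc or "", pt, n_m, ror_m, n_f, ror_f))
    return pd.DataFrame(rows, columns=["soc", "pt", "n_male", "ror_male_ci",
                                       "n_female", "ror_female_ci"])
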