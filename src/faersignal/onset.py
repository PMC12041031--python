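"""Time-to-onset of adverse events and serious-outcome proportions.

Time to onset is the calendar-day interval from START_DT (initiation of
therapy with the target drug, taken from the earliest full-precision
THER start date among target-drug rows) to EVENT_DT (occurrence of the
adverse event). Spontaneous-report dates are frequently absent, partial
(year or year-month only) or wrong, so each report carries an explicit
inclusion status instead of silently vanishing: ``missing_date``,
``partial_date``, ``invalid_date`` or ``event_before_start`` (a reporting
error — the event cannot precede the therapy it is attributed to).
Same-day onset (0 days) is valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import Cohort, ReportRecord, round_half_up
from .dates import INVALID, MISSING, PartialDate

__all__ = [
    "OnsetRecord",
    "OnsetSummary",
    "ONSET_BINS",
    "compute_onset",
    "summarize_onset",
    "outcome_proportions",
]

log = logging.getLogger(__name__)

# (label, low, high) in days, inclusive bounds; None = unbounded.
ONSET_BINS: Tuple[Tuple[str, int, Optional[int]], ...] = (
    ("0-30", 0, 30),
    ("31-90", 31, 90),
    ("91-180", 91, 180),
    ("181-365", 181, 365),
    (">365", 366, None),
)


@dataclass
class OnsetRecord:
    """One target report's validated time-to-onset."""

    primaryid: str
    start_dt: Optional[PartialDate]
    event_dt: Optional[PartialDate]
    days: Optional[int]
    included: bool
    exclusion_reason: Optional[str] = None


@dataclass
class OnsetSummary:
    n_included: int
    median_days: Optional[float]
    iqr: Optional[Tuple[float, float]]
    bins: List[Tuple[str, int, float]]  # (label, count, percent)


def _target_start(report: ReportRecord) -> Tuple[Optional[PartialDate], str]:
    """Earliest full-precision therapy start among target-drug rows.

    If no target row has a day-precision start, the best available status
    is reported for the exclusion taxonomy (partial beats invalid beats
    missing, mirroring the order exclusions are applied in).
    """
    full = [d.therapy_start for d in report.drugs
            if d.is_target and d.therapy_start is not None
            and d.therapy_start.precision == "day"]
    if full:
        return min(full, key=PartialDate.sort_key), "day"
    statuses = {d.therapy_start_status for d in report.drugs if d.is_target}
    partial = [d.therapy_start for d in report.drugs
               if d.is_target and d.therapy_start is not None]
    if partial:
        return min(partial, key=PartialDate.sort_key), "partial"
    if INVALID in statuses:
        return None, INVALID
    return None, MISSING


def compute_onset(report: ReportRecord) -> OnsetRecord:
    """Classify one target report's onset interval.

    Exclusion taxonomy, applied in order: missing_date (either date
    absent), partial_date (either date coarser than day), invalid_date
    (either date calendar-invalid), event_before_start. Exhaustive and
    mutually exclusive; what remains is included with
    days = EVENT_DT - START_DT on the proleptic Gregorian calendar.
    """
    start, start_status = _target_start(report)
    event, event_status = report.event_dt, report.event_dt_status

    def rec(reason: Optional[str], days: Optional[int] = None) -> OnsetRecord:
        return OnsetRecord(primaryid=report.primaryid, start_dt=start,
                           event_dt=event, days=days,
                           included=reason is None, exclusion_reason=reason)

    if event_status == MISSING or start_status == MISSING:
        return rec("missing_date")
    if (event is not None and event.precision != "day") or start_status == "partial":
        return rec("partial_date")
    if event_status == INVALID or start_status == INVALID:
        return rec("invalid_date")
    days = (event.to_date() - start.to_date()).days
    if days < 0:
        return rec("event_before_start")
    return rec(None, days)


def summarize_onset(records: Sequence[OnsetRecord]) -> OnsetSummary:
    """Median, IQR (linear-interpolation quartiles) and fixed onset bins."""
    days = np.array([r.days for r in records if r.included], dtype=float)
    if days.size == 0:
        log.warning("no included onset records; empty summary")
        return OnsetSummary(0, None, None,
                            [(label, 0, 0.0) for label, _, _ in ONSET_BINS])
    q1, med, q3 = np.percentile(days, [25, 50, 75])  # type-7 interpolation
    bins = []
    for label, lo, hi in ONSET_BINS:
        mask = days >= lo if hi is None else (days >= lo) & (days <= hi)
        n = int(mask.sum())
        bins.append((label, n, round_half_up(100.0 * n / days.size)))
    return OnsetSummary(n_included=int(days.size), median_days=float(med),
                        iqr=(float(q1), float(q3)), bins=bins)


def onset_audit_frame(records: Sequence[OnsetRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.primaryid, r.days if r.days is not None else "",
          r.included, r.exclusion_reason or "") for r in records],
        columns=["primaryid", "days", "included", "exclusion_reason"])


def outcome_proportions(cohort: Cohort) -> pd.DataFrame:
    """Serious-outcome counts over the target cohort.

    Each outcome code counts the reports carrying it, divided by the
    total number of target reports; a report with k codes appears in k
    rows, so percentages may sum past 100.
    """
    total = len(cohort.target_reports)
    counts: Dict[str, int] = {}
    for r in cohort.target_reports:
        for code in r.outcomes:
            counts[code] = counts.get(code, 0) + 1
    rows = [(code, n, round_half_up(100.0 * n / total) if total else 0.0)
            for code, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["outcome", "n", "percent"])
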