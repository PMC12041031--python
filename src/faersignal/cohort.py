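"""Case deduplication, target-drug cohort construction and descriptives.

A FAERS *case* (CASEID) accumulates versions (PRIMARYID) across quarters
as follow-up information arrives. Per the FDA's recommended cleaning
rule, one version survives per case: the one with the most recent FDA_DT,
ties broken by the numerically larger PRIMARYID. Rows whose FDA_DT does
not parse lose to any row with a valid one.

The analysis cohort is then split on the drug of interest: a report
belongs to the *target* cohort iff at least one of its DRUG rows has role
PS (primary suspect) and a name matching the drug dictionary; everything
else is *background*. The counting unit downstream is the
(deduplicated report, distinct PT) pair — each preferred term counts at
most once per report, which is the only unit under which a cohort can
have both a report total and a larger adverse-event total.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .dates import MISSING, PartialDate, parse_partial_date, parse_partial_date_status
from .faers_io import QuarterBundle, RawRow

__all__ = [
    "DrugEntry",
    "ReportRecord",
    "Cohort",
    "deduplicate",
    "normalize_drug_name",
    "match_target",
    "load_drug_dictionary",
    "build_cohort",
    "characteristics_table",
    "round_half_up",
]

log = logging.getLogger(__name__)

AGE_BANDS = ("<18", "18-44", "45-64", ">=65", "unknown")

# FAERS OCC_COD / OCP_COD -> the five reporter rows of the descriptive table.
_REPORTER_MAP = {
    "CN": "consumer",
    "MD": "physician",
    "PH": "pharmacist",
    "HP": "health_professional",
}

# FAERS AGE_COD -> factor converting to years.
_AGE_FACTORS = {"DEC": 10.0, "YR": 1.0, "MON": 1 / 12, "WK": 1 / 52, "DY": 1 / 365.25}
_AGE_MAX = 120.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding (the rounding convention of the output tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DrugEntry:
    """One DRUG row of a report, with its linked therapy start date."""

    name: str  # normalized
    role: str  # PS | SS | C | I
    therapy_start: Optional[PartialDate] = None
    therapy_start_status: str = MISSING
    is_target: bool = False


@dataclass
class ReportRecord:
    """One deduplicated FAERS case, joined across the six tables."""

    primaryid: str
    caseid: str
    fda_dt: Optional[PartialDate]
    event_dt: Optional[PartialDate]
    event_dt_status: str
    sex: str  # F | M | unknown
    age_years: Optional[float]
    reporter: str
    country: str
    receipt_year_quarter: str
    drugs: List[DrugEntry] = field(default_factory=list)
    events: Set[str] = field(default_factory=set)
    outcomes: Set[str] = field(default_factory=set)
    indications: List[str] = field(default_factory=list)

    @property
    def is_target(self) -> bool:
        return any(d.role == "PS" and d.is_target for d in self.drugs)


@dataclass
class Cohort:
    """Deduplicated reports partitioned into target and background."""

    target_reports: List[ReportRecord]
    background_reports: List[ReportRecord]
    drug_dictionary: Set[str]
    counting_unit: str = "report_pt_pair"

    @property
    def n_reports(self) -> int:
        return len(self.target_reports) + len(self.background_reports)

    @property
    def n_target_pairs(self) -> int:
        return sum(len(r.events) for r in self.target_reports)

    @property
    def n_background_pairs(self) -> int:
        return sum(len(r.events) for r in self.background_reports)


# ---------------------------------------------------------------------------
# Deduplication


def _dedup_sort_key(row: RawRow) -> Tuple[int, Tuple[int, int, int], int]:
    date, status = parse_partial_date_status(row.payload.get("fda_dt", ""))
    valid = 0 if date is None else 1
    datekey = date.sort_key() if date is not None else (0, 0, 0)
    try:
        pid = int(row.primaryid)
    except ValueError:
        pid = -1
    return (valid, datekey, pid)


def deduplicate(demo_rows: Iterable[RawRow]) -> Dict[str, str]:
    """FDA case deduplication: caseid -> surviving primaryid.

    Survivor has the maximal FDA_DT; FDA_DT ties (and mutually unparseable
    FDA_DTs) break to the numerically larger PRIMARYID. A row with a
    missing CASEID forms its own singleton case keyed by its primaryid.
    """
    by_case: Dict[str, List[RawRow]] = defaultdict(list)
    n_missing_caseid = 0
    for row in demo_rows:
        case = row.caseid
        if not case:
            case = f"__nocase_{row.primaryid}"
            n_missing_caseid += 1
        by_case[case].append(row)
    if n_missing_caseid:
        log.warning("%d DEMO rows without CASEID treated as singleton cases",
                    n_missing_caseid)
    return {case: max(rows, key=_dedup_sort_key).primaryid
            for case, rows in by_case.items()}


# ---------------------------------------------------------------------------
# Drug-name handling


def normalize_drug_name(raw: str) -> str:
    """Upper-case and collapse internal whitespace; no stemming or token drops."""
    return " ".join(raw.upper().split())


def load_drug_dictionary(path: str | Path) -> Set[str]:
    """Read a drug dictionary: one name per line, '#' comments."""
    names: Set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.add(normalize_drug_name(line))
    return names


def match_target(normalized_name: str, dictionary: Iterable[str],
                 mode: str = "prefix") -> bool:
    """True iff a dictionary entry matches the (normalized) drug name.

    ``prefix`` mode (default): the entry's tokens must be a whole-word
    prefix of the name's tokens, so dictionary entry EFGARTIGIMOD matches
    "EFGARTIGIMOD ALFA-FCAB" but VYVGART does not match "VYVANSE".
    ``exact`` mode: string equality only.
    """
    name_tokens = normalized_name.split()
    for entry in dictionary:
        if entry == normalized_name:
            return True
        if mode == "prefix":
            etoks = entry.split()
            if len(etoks) <= len(name_tokens) and name_tokens[: len(etoks)] == etoks:
                return True
    return False


# ---------------------------------------------------------------------------
# Field harmonisation helpers


def _harmonize_sex(raw: str) -> str:
    s = raw.strip().upper()
    return s if s in ("F", "M") else "unknown"


def _harmonize_age(age_raw: str, age_cod_raw: str) -> Optional[float]:
    s = age_raw.strip()
    if not s:
        return None
    try:
        value = float(s)
    except ValueError:
        return None
    factor = _AGE_FACTORS.get(age_cod_raw.strip().upper() or "YR")
    if factor is None:
        return None
    years = value * factor
    if not (0.0 <= years <= _AGE_MAX):
        return None
    return years


def _harmonize_reporter(raw: str) -> str:
    return _REPORTER_MAP.get(raw.strip().upper(), "other_unknown")


def age_band(age_years: Optional[float]) -> str:
    if age_years is None:
        return "unknown"
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-44"
    if age_years < 65:
        return "45-64"
    return ">=65"


# ---------------------------------------------------------------------------
# Cohort construction


def build_cohort(
    quarters: Sequence[QuarterBundle],
    dedup_map: Dict[str, str],
    dictionary: Set[str],
    match_mode: str = "prefix",
) -> Cohort:
    """Join the six tables into ReportRecords and split target/background.

    ``dedup_map`` is the output of :func:`deduplicate` over all quarters'
    DEMO rows; only surviving primaryids are materialised. Target reports
    are those with >=1 PS-role drug whose normalized name matches the
    dictionary; every other deduplicated report is background.
    """
    if not dictionary:
        raise ValueError("drug dictionary is empty")
    survivors = set(dedup_map.values())

    demo: Dict[str, Tuple[RawRow, str]] = {}
    drug_rows: Dict[str, List[RawRow]] = defaultdict(list)
    reac_rows: Dict[str, List[RawRow]] = defaultdict(list)
    outc_rows: Dict[str, List[RawRow]] = defaultdict(list)
    ther_rows: Dict[str, List[RawRow]] = defaultdict(list)
    indi_rows: Dict[str, List[RawRow]] = defaultdict(list)
    sinks = {"DRUG": drug_rows, "REAC": reac_rows, "OUTC": outc_rows,
             "THER": ther_rows, "INDI": indi_rows}

    for bundle in quarters:
        for row in bundle.rows_by_table.get("DEMO", []):
            if row.primaryid in survivors:
                demo[row.primaryid] = (row, bundle.quarter_label)
        for table, sink in sinks.items():
            for row in bundle.rows_by_table.get(table, []):
                if row.primaryid in survivors:
                    sink[row.primaryid].append(row)

    target: List[ReportRecord] = []
    background: List[ReportRecord] = []
    for pid, (drow, quarter_label) in demo.items():
        p = drow.payload
        event_dt, event_status = parse_partial_date_status(p.get("event_dt", ""))

        # THER links to DRUG via dsg_drug_seq == drug_seq.
        starts: Dict[str, List[Tuple[Optional[PartialDate], str]]] = defaultdict(list)
        for trow in ther_rows.get(pid, []):
            seq = trow.payload.get("dsg_drug_seq", "")
            starts[seq].append(parse_partial_date_status(trow.payload.get("start_dt", "")))

        drugs: List[DrugEntry] = []
        for drug_row in drug_rows.get(pid, []):
            name = normalize_drug_name(drug_row.payload.get("drugname", ""))
            role = drug_row.payload.get("role_cod", "").strip().upper()
            seq = drug_row.payload.get("drug_seq", "")
            linked = starts.get(seq, [])
            start, status = (linked[0] if linked else (None, MISSING))
            # prefer a full-precision start if several THER rows exist
            for cand, cand_status in linked[1:]:
                better = (cand is not None and cand.precision == "day"
                          and (start is None or start.precision != "day"
                               or cand.sort_key() < start.sort_key()))
                if better:
                    start, status = cand, cand_status
            drugs.append(DrugEntry(
                name=name, role=role, therapy_start=start,
                therapy_start_status=status,
                is_target=match_target(name, dictionary, mode=match_mode),
            ))

        record = ReportRecord(
            primaryid=pid,
            caseid=drow.caseid or pid,
            fda_dt=parse_partial_date(p.get("fda_dt", "")),
            event_dt=event_dt,
            event_dt_status=event_status,
            sex=_harmonize_sex(p.get("sex", "")),
            age_years=_harmonize_age(p.get("age", ""), p.get("age_cod", "")),
            reporter=_harmonize_reporter(p.get("occp_cod", p.get("occ_cod", ""))),
            country=(p.get("reporter_country", "").strip().upper() or "unknown"),
            receipt_year_quarter=quarter_label,
            drugs=drugs,
            events={e.strip().upper() for r in reac_rows.get(pid, [])
                    if (e := r.payload.get("pt", ""))},
            outcomes={c.strip().upper() for r in outc_rows.get(pid, [])
                      if (c := r.payload.get("outc_cod", "").strip())},
            indications=[s.strip().upper() for r in indi_rows.get(pid, [])
                         if (s := r.payload.get("indi_pt", "")).strip()],
        )
        (target if record.is_target else background).append(record)

    target.sort(key=lambda r: r.primaryid)
    background.sort(key=lambda r: r.primaryid)
    cohort = Cohort(target_reports=target, background_reports=background,
                    drug_dictionary=set(dictionary))
    log.info("cohort: %d target reports (%d report-PT pairs), %d background "
             "reports (%d pairs)", len(target), cohort.n_target_pairs,
             len(background), cohort.n_background_pairs)
    return cohort


# ---------------------------------------------------------------------------
# Descriptive characteristics


def _count_block(rows: List[Tuple[str, str, int]], characteristic: str,
                 counts: Dict[str, int],
                 order: Sequence[str] | None = None) -> None:
    keys = list(order) if order is not None else sorted(
        counts, key=lambda k: (-counts[k], k))
    for key in keys:
        n = counts.get(key, 0)
        rows.append((characteristic, key, n))


def characteristics_table(cohort: Cohort, top_n: int = 5) -> pd.DataFrame:
    """Descriptive table of the target cohort (count and % of reports).

    Covers sex, age band, reporter occupation, reporting country, receipt
    year, indication and serious-outcome codes. Country and indication
    keep the ``top_n`` most frequent levels, folding the rest into
    ``OTHER_OR_UNKNOWN``. Serious-outcome percentages may sum past 100
    because one report can carry several outcome codes.
    """
    reports = cohort.target_reports
    total = len(reports)
    if total == 0:
        raise ValueError("empty target cohort")

    rows: List[Tuple[str, str, int]] = []

    sex_counts: Dict[str, int] = defaultdict(int)
    age_counts: Dict[str, int] = defaultdict(int)
    rep_counts: Dict[str, int] = defaultdict(int)
    ctry_counts: Dict[str, int] = defaultdict(int)
    year_counts: Dict[str, int] = defaultdict(int)
    indi_counts: Dict[str, int] = defaultdict(int)
    outc_counts: Dict[str, int] = defaultdict(int)
    for r in reports:
        sex_counts[r.sex] += 1
        age_counts[age_band(r.age_years)] += 1
        rep_counts[r.reporter] += 1
        ctry_counts[r.country] += 1
        year_counts[r.receipt_year_quarter[:4]] += 1
        primary_indi = r.indications[0] if r.indications else "UNKNOWN"
        indi_counts[primary_indi] += 1
        for code in r.outcomes:
            outc_counts[code] += 1

    def fold_top(counts: Dict[str, int]) -> Dict[str, int]:
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        kept = dict(ranked[:top_n])
        rest = sum(n for _, n in ranked[top_n:])
        if rest or "OTHER_OR_UNKNOWN" in kept:
            kept["OTHER_OR_UNKNOWN"] = kept.get("OTHER_OR_UNKNOWN", 0) + rest
        return kept

    _count_block(rows, "sex", sex_counts, order=("F", "M", "unknown"))
    _count_block(rows, "age_band", age_counts, order=AGE_BANDS)
    _count_block(rows, "reporter", rep_counts,
                 order=("consumer", "health_professional", "physician",
                        "pharmacist", "other_unknown"))
    _count_block(rows, "country", fold_top(ctry_counts))
    _count_block(rows, "receipt_year", year_counts,
                 order=sorted(year_counts))
    _count_block(rows, "indication", fold_top(indi_counts))
    _count_block(rows, "serious_outcome", outc_counts,
                 order=sorted(outc_counts, key=lambda k: (-outc_counts[k], k)))

    df = pd.DataFrame(rows, columns=["characteristic", "subgroup", "n"])
    df["percent"] = [round_half_up(100.0 * n / total) for n in df["n"]]
    return df
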