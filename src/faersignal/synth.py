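"""Synthetic FAERS quarterly files with known ground truth.

The generator emulates the statistical structure of spontaneous-report
data for a recently launched speciality biologic: a small fraction of
cases name the target drug as primary suspect; each report carries one
or more MedDRA preferred terms drawn from a vocabulary of background
reporting rates; planted drug-event associations multiply a PT's rate by
a known rate ratio rho within target reports; case versions (duplicate
CASEIDs with later FDA_DT and larger PRIMARYID) are injected at a
configurable rate; demographics carry the heavy missingness typical of
consumer-submitted reports (~75% sex, ~92% age unknown); and onset times
follow a log-normal with a median of 81 days. Everything the pipeline
should recover is recorded in a ground-truth manifest.

Defaults are the study conditions: 10 quarters (2022Q1-2024Q2), one PT
planted at rho = 5 with ~0.2% of the background PT mass, serious-outcome
rates matching the observed report mix, ~4.1 events per report.

All randomness flows from ``numpy.random.default_rng((seed, quarter))``
— one independent stream per quarter — so identical (config, seed) pairs
produce byte-identical output directories.
"""

from __future__ import annotations

import datetime as _dt
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .cohort import Cohort, DrugEntry, ReportRecord, match_target, normalize_drug_name
from .dates import MISSING, PartialDate, parse_partial_date_status

__all__ = [
    "SynthConfig",
    "DEFAULT_VOCABULARY",
    "TARGET_SPELLINGS",
    "generate",
    "generate_cases",
    "cases_to_reports",
    "write_manifest",
    "read_manifest",
    "make_validation_fixture",
]

# (PT, SOC, background rate weight). Weights are relative; the planted PT
# NEPHROLITHIASIS holds ~0.2% of the total mass so that a planted rate
# ratio distorts the draw normalisation by well under 1%.
DEFAULT_VOCABULARY: Tuple[Tuple[str, str, float], ...] = (
    ("HEADACHE", "NERVOUS SYSTEM DISORDERS", 0.090),
    ("DIZZINESS", "NERVOUS SYSTEM DISORDERS", 0.050),
    ("PARAESTHESIA", "NERVOUS SYSTEM DISORDERS", 0.020),
    ("SPEECH DISORDER", "NERVOUS SYSTEM DISORDERS", 0.008),
    ("BALANCE DISORDER", "NERVOUS SYSTEM DISORDERS", 0.010),
    ("FATIGUE", "GENERAL DISORDERS", 0.080),
    ("ASTHENIA", "GENERAL DISORDERS", 0.040),
    ("PYREXIA", "GENERAL DISORDERS", 0.035),
    ("CHEST PAIN", "GENERAL DISORDERS", 0.020),
    ("DRUG INEFFECTIVE", "GENERAL DISORDERS", 0.070),
    ("CONDITION AGGRAVATED", "GENERAL DISORDERS", 0.030),
    ("NAUSEA", "GASTROINTESTINAL DISORDERS", 0.060),
    ("DIARRHOEA", "GASTROINTESTINAL DISORDERS", 0.045),
    ("VOMITING", "GASTROINTESTINAL DISORDERS", 0.030),
    ("DYSPHAGIA", "GASTROINTESTINAL DISORDERS", 0.008),
    ("ABDOMINAL PAIN", "GASTROINTESTINAL DISORDERS", 0.025),
    ("URINARY TRACT INFECTION", "INFECTIONS AND INFESTATIONS", 0.020),
    ("PNEUMONIA", "INFECTIONS AND INFESTATIONS", 0.018),
    ("NASOPHARYNGITIS", "INFECTIONS AND INFESTATIONS", 0.015),
    ("HERPES ZOSTER", "INFECTIONS AND INFESTATIONS", 0.007),
    ("SEPSIS", "INFECTIONS AND INFESTATIONS", 0.006),
    ("BRONCHITIS", "INFECTIONS AND INFESTATIONS", 0.008),
    ("RASH", "SKIN AND SUBCUTANEOUS TISSUE DISORDERS", 0.040),
    ("PRURITUS", "SKIN AND SUBCUTANEOUS TISSUE DISORDERS", 0.025),
    ("URTICARIA", "SKIN AND SUBCUTANEOUS TISSUE DISORDERS", 0.012),
    ("ALOPECIA", "SKIN AND SUBCUTANEOUS TISSUE DISORDERS", 0.010),
    ("ARTHRALGIA", "MUSCULOSKELETAL DISORDERS", 0.035),
    ("MYALGIA", "MUSCULOSKELETAL DISORDERS", 0.020),
    ("BACK PAIN", "MUSCULOSKELETAL DISORDERS", 0.018),
    ("MUSCULAR WEAKNESS", "MUSCULOSKELETAL DISORDERS", 0.009),
    ("DYSPNOEA", "RESPIRATORY DISORDERS", 0.030),
    ("COUGH", "RESPIRATORY DISORDERS", 0.020),
    ("NEPHROLITHIASIS", "RENAL AND URINARY DISORDERS", 0.002),
    ("MICTURITION URGENCY", "RENAL AND URINARY DISORDERS", 0.003),
    ("RENAL IMPAIRMENT", "RENAL AND URINARY DISORDERS", 0.008),
    ("INAPPROPRIATE SCHEDULE OF PRODUCT ADMINISTRATION",
     "INJURY AND PROCEDURAL COMPLICATIONS", 0.015),
    ("INFUSION RELATED REACTION", "INJURY AND PROCEDURAL COMPLICATIONS", 0.010),
    ("FALL", "INJURY AND PROCEDURAL COMPLICATIONS", 0.020),
    ("INSOMNIA", "PSYCHIATRIC DISORDERS", 0.020),
    ("ANXIETY", "PSYCHIATRIC DISORDERS", 0.015),
)

TARGET_SPELLINGS = ("EFGARTIGIMOD", "Vyvgart", "VYVGART HYTRULO",
                    "EFGARTIGIMOD ALFA-FCAB", "vyvgart")

_OTHER_DRUGS = ("PREDNISONE", "ADALIMUMAB", "METFORMIN", "LISINOPRIL",
                "ATORVASTATIN", "RITUXIMAB", "IBUPROFEN", "OMEPRAZOLE",
                "MYCOPHENOLATE MOFETIL", "AZATHIOPRINE", "GABAPENTIN",
                "LEVOTHYROXINE", "AMLODIPINE", "PYRIDOSTIGMINE",
                "DUPILUMAB", "SEMAGLUTIDE", "APIXABAN", "SERTRALINE")

_TARGET_INDICATIONS = (("MYASTHENIA GRAVIS", 0.6852),
                       ("IMMUNE THROMBOCYTOPENIA", 0.0040),
                       ("PEMPHIGUS", 0.0020),
                       ("PRODUCT USED FOR UNKNOWN INDICATION", 0.3088))

_COUNTRIES = (("US", 0.8599), ("JP", 0.0559), ("DE", 0.0171),
              ("GB", 0.0105), ("CA", 0.0046), ("", 0.0520))

_REPORTERS = (("CN", 0.7954), ("HP", 0.0865), ("MD", 0.0865),
              ("PH", 0.0204), ("", 0.0112))

HEADERS: Dict[str, Tuple[str, ...]] = {
    "DEMO": ("primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
             "sex", "occp_cod", "reporter_country"),
    "DRUG": ("primaryid", "caseid", "drug_seq", "role_cod", "drugname"),
    "REAC": ("primaryid", "caseid", "pt"),
    "OUTC": ("primaryid", "caseid", "outc_cod"),
    "THER": ("primaryid", "caseid", "dsg_drug_seq", "start_dt"),
    "INDI": ("primaryid", "caseid", "indi_drug_seq", "indi_pt"),
}


@dataclass
class SynthConfig:
    """Full parameterisation of the synthetic FAERS generator."""

    seed: int = 7
    n_cases: int = 20_000
    n_quarters: int = 10  # 2022Q1 .. 2024Q2
    first_year: int = 2022
    duplicate_version_rate: float = 0.10
    target_share: float = 0.05
    pt_vocabulary: Tuple[Tuple[str, str, float], ...] = DEFAULT_VOCABULARY
    planted_signals: Tuple[Tuple[str, float], ...] = (("NEPHROLITHIASIS", 5.0),)
    events_per_report: Tuple[float, float] = (4.1, 3.0)  # (mean, NB size r)
    sex_missingness: float = 0.7554
    female_share_of_known: float = 402 / (402 + 372)
    age_missingness: float = 0.9155
    onset_distribution: Tuple[str, float, float] = ("lognormal", 81.0, 2.0)
    outcome_rates: Tuple[Tuple[str, float], ...] = (
        ("HO", 0.5322), ("OT", 0.4763), ("DE", 0.0888),
        ("LT", 0.0572), ("RI", 0.0026), ("DS", 0.0023))
    concomitant_rate: float = 0.30
    event_date_full_rate: float = 0.40
    event_date_partial_rate: float = 0.10
    ther_date_full_rate: float = 0.85
    inverted_date_rate: float = 0.02

    def __post_init__(self) -> None:
        probs = [self.duplicate_version_rate, self.target_share,
                 self.sex_missingness, self.age_missingness,
                 self.concomitant_rate]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(rho < 1.0 for _, rho in self.planted_signals):
            raise ValueError("planted rate ratios must be >= 1")
        if not self.pt_vocabulary:
            raise ValueError("PT vocabulary is empty")
        if sum(r for _, _, r in self.pt_vocabulary) <= 0:
            raise ValueError("background rates sum to zero")

    @property
    def quarter_labels(self) -> List[str]:
        labels = []
        year, q = self.first_year, 1
        for _ in range(self.n_quarters):
            labels.append(f"{year}Q{q}")
            q += 1
            if q == 5:
                year, q = year + 1, 1
        return labels

    @property
    def pt_to_soc(self) -> Dict[str, str]:
        return {pt: soc for pt, soc, _ in self.pt_vocabulary}


def _quarter_bounds(label: str) -> Tuple[_dt.date, _dt.date]:
    year, q = int(label[:4]), int(label.split("Q")[1])
    start = _dt.date(year, 3 * (q - 1) + 1, 1)
    end = (_dt.date(year + 1, 1, 1) if q == 4
           else _dt.date(year, 3 * q + 1, 1)) - _dt.timedelta(days=1)
    return start, end


def _categorical(rng: np.random.Generator, n: int,
                 table: Sequence[Tuple[str, float]]) -> np.ndarray:
    labels = [t[0] for t in table]
    p = np.array([t[1] for t in table], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(labels, dtype=object), size=n, p=p)


@dataclass
class SynthCase:
    """Internal per-case record; mirrors one joined FAERS case."""

    caseid: str
    primaryids: List[str]          # version ids, ascending
    fda_dts: List[str]             # aligned with primaryids
    is_target: bool
    pts: Tuple[str, ...]
    sex: str
    age: str
    age_cod: str
    occp_cod: str
    country: str
    indication: str
    outcomes: Tuple[str, ...]
    drugs: List[Tuple[str, str]]   # (drugname, role)
    event_dt: str
    start_dt: str
    onset_days_true: Optional[int]
    quarter_index: int


def generate_cases(config: SynthConfig) -> Tuple[List[SynthCase], Dict]:
    """Draw all cases in memory and return them with the truth manifest."""
    pts = np.array([v[0] for v in config.pt_vocabulary], dtype=object)
    rates = np.array([v[2] for v in config.pt_vocabulary], dtype=float)
    rho = np.ones_like(rates)
    planted = dict(config.planted_signals)
    for i, pt in enumerate(pts):
        if pt in planted:
            rho[i] = planted[pt]
    logw_bg = np.log(rates)
    logw_t = np.log(rates * rho)
    n_pts = len(pts)
    mean_k, size_r = config.events_per_report
    p_nb = size_r / (size_r + mean_k)
    med, sigma = config.onset_distribution[1], config.onset_distribution[2]

    base = config.n_cases // config.n_quarters
    extra = config.n_cases % config.n_quarters
    cases: List[SynthCase] = []
    case_counter = 0
    for qi, label in enumerate(config.quarter_labels):
        n_q = base + (1 if qi < extra else 0)
        if n_q == 0:
            continue
        rng = np.random.default_rng((config.seed, qi))
        qstart, qend = _quarter_bounds(label)
        span = (qend - qstart).days + 1

        is_target = rng.random(n_q) < config.target_share
        ks = np.clip(rng.negative_binomial(size_r, p_nb, size=n_q), 1, n_pts)
        gumbel = rng.gumbel(size=(n_q, n_pts))
        scores = gumbel + np.where(is_target[:, None], logw_t[None, :],
                                   logw_bg[None, :])
        order = np.argsort(-scores, axis=1)

        sex_u = rng.random(n_q)
        sex_f = rng.random(n_q) < config.female_share_of_known
        age_missing = rng.random(n_q) < config.age_missingness
        ages = np.clip(rng.normal(60, 15, size=n_q), 18, 90).astype(int)
        occp = _categorical(rng, n_q, _REPORTERS)
        country = _categorical(rng, n_q, _COUNTRIES)
        indi_t = _categorical(rng, n_q, _TARGET_INDICATIONS)
        indi_b = rng.choice(np.array(
            ["HYPERTENSION", "RHEUMATOID ARTHRITIS", "DIABETES MELLITUS",
             "PRODUCT USED FOR UNKNOWN INDICATION"], dtype=object), size=n_q)
        outc_u = rng.random((n_q, len(config.outcome_rates)))
        fda_offsets = rng.integers(0, span, size=n_q)
        report_lag = rng.integers(0, 61, size=n_q)
        # heavy right tail clipped at ~14 years so therapy starts stay on-calendar
        onset = np.minimum(
            np.floor(rng.lognormal(math.log(med), sigma, size=n_q)), 5000
        ).astype(int)
        ev_quality = rng.random(n_q)
        ther_full = rng.random(n_q) < config.ther_date_full_rate
        inverted = rng.random(n_q) < config.inverted_date_rate
        inv_delta = rng.integers(1, 31, size=n_q)
        has_concom = rng.random(n_q) < config.concomitant_rate
        n_concom = rng.integers(1, 3, size=n_q)
        concom_pick = rng.integers(0, len(_OTHER_DRUGS), size=(n_q, 2))
        spelling_pick = rng.integers(0, len(TARGET_SPELLINGS), size=n_q)
        bg_drug_pick = rng.integers(0, len(_OTHER_DRUGS), size=n_q)
        dup = rng.random(n_q) < config.duplicate_version_rate
        dup_lag = rng.integers(20, 121, size=n_q)

        for i in range(n_q):
            caseid = str(100_000_000 + case_counter)
            pid0 = caseid + "1"
            fda0 = qstart + _dt.timedelta(days=int(fda_offsets[i]))
            fda_dts = [fda0.strftime("%Y%m%d")]
            primaryids = [pid0]
            if dup[i]:
                fda1 = fda0 + _dt.timedelta(days=int(dup_lag[i]))
                fda_dts.append(fda1.strftime("%Y%m%d"))
                primaryids.append(caseid + "2")

            event_date = fda0 - _dt.timedelta(days=int(report_lag[i]))
            start_date = event_date - _dt.timedelta(days=int(onset[i]))
            onset_true: Optional[int] = int(onset[i])
            if inverted[i]:
                event_date = start_date - _dt.timedelta(days=int(inv_delta[i]))
                onset_true = None
            if ev_quality[i] < config.event_date_full_rate:
                event_str = event_date.strftime("%Y%m%d")
            elif ev_quality[i] < (config.event_date_full_rate
                                  + config.event_date_partial_rate):
                event_str = event_date.strftime("%Y%m")
                onset_true = None
            else:
                event_str = ""
                onset_true = None
            if ther_full[i]:
                start_str = start_date.strftime("%Y%m%d")
            else:
                start_str = ""
                onset_true = None

            if is_target[i]:
                drugs = [(TARGET_SPELLINGS[spelling_pick[i]], "PS")]
                if has_concom[i]:
                    for j in range(int(n_concom[i])):
                        drugs.append((_OTHER_DRUGS[concom_pick[i, j]],
                                      "C" if j == 0 else "SS"))
                indication = str(indi_t[i])
            else:
                drugs = [(_OTHER_DRUGS[bg_drug_pick[i]], "PS")]
                if has_concom[i]:
                    drugs.append((_OTHER_DRUGS[concom_pick[i, 0]], "C"))
                indication = str(indi_b[i])

            outcomes = tuple(code for j, (code, rate)
                             in enumerate(config.outcome_rates)
                             if outc_u[i, j] < rate)
            cases.append(SynthCase(
                caseid=caseid, primaryids=primaryids, fda_dts=fda_dts,
                is_target=bool(is_target[i]),
                pts=tuple(str(p) for p in pts[order[i, :ks[i]]]),
                sex=("" if sex_u[i] < config.sex_missingness
                     else ("F" if sex_f[i] else "M")),
                age=("" if age_missing[i] else str(int(ages[i]))),
                age_cod=("" if age_missing[i] else "YR"),
                occp_cod=str(occp[i]), country=str(country[i]),
                indication=indication, outcomes=outcomes, drugs=drugs,
                event_dt=event_str, start_dt=start_str,
                onset_days_true=onset_true, quarter_index=qi,
            ))
            case_counter += 1

    manifest = _build_manifest(config, cases)
    return cases, manifest


def _build_manifest(config: SynthConfig, cases: List[SynthCase]) -> Dict:
    target_pt = Counter()
    background_pt = Counter()
    target_pairs = background_pairs = 0
    n_target = n_versions = 0
    for case in cases:
        n_versions += len(case.primaryids)
        counter = target_pt if case.is_target else background_pt
        if case.is_target:
            n_target += 1
            target_pairs += len(case.pts)
        else:
            background_pairs += len(case.pts)
        for pt in case.pts:
            counter[pt] += 1
    manifest: Dict[str, object] = {
        "seed": config.seed,
        "n_cases": len(cases),
        "n_target_cases": n_target,
        "n_demo_rows": n_versions,
        "n_target_pairs": target_pairs,
        "n_background_pairs": background_pairs,
        "quarters": ",".join(config.quarter_labels),
    }
    for pt, rho in config.planted_signals:
        manifest[f"planted_rho.{pt}"] = rho
    for pt, n in sorted(target_pt.items()):
        manifest[f"target_pt.{pt}"] = n
    for pt, n in sorted(background_pt.items()):
        manifest[f"background_pt.{pt}"] = n
    return manifest


# ---------------------------------------------------------------------------
# File output


def _case_rows(case: SynthCase) -> Dict[str, List[List[str]]]:
    """Rows for every (table, version) of one case, keyed by table."""
    rows: Dict[str, List[List[str]]] = {t: [] for t in HEADERS}
    for pid, fda in zip(case.primaryids, case.fda_dts):
        rows["DEMO"].append([pid, case.caseid, fda, case.event_dt, case.age,
                             case.age_cod, case.sex, case.occp_cod,
                             case.country])
        for seq, (name, role) in enumerate(case.drugs, start=1):
            rows["DRUG"].append([pid, case.caseid, str(seq), role, name])
            if role == "PS":
                rows["THER"].append([pid, case.caseid, str(seq), case.start_dt])
        for pt in case.pts:
            rows["REAC"].append([pid, case.caseid, pt])
        for code in case.outcomes:
            rows["OUTC"].append([pid, case.caseid, code])
        rows["INDI"].append([pid, case.caseid, "1", case.indication])
    return rows


def _version_quarter(fda_str: str, labels: Sequence[str]) -> int:
    date = _dt.date(int(fda_str[:4]), int(fda_str[4:6]), int(fda_str[6:8]))
    for qi, label in enumerate(labels):
        start, end = _quarter_bounds(label)
        if start <= date <= end:
            return qi
    return len(labels) - 1  # late follow-up clamps to the final quarter


def write_quarter_files(cases: Sequence[SynthCase], config: SynthConfig,
                        out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = config.quarter_labels
    per_quarter: Dict[int, Dict[str, List[List[str]]]] = {
        qi: {t: [] for t in HEADERS} for qi in range(len(labels))}
    for case in cases:
        rows = _case_rows(case)
        for version_idx, (pid, fda) in enumerate(zip(case.primaryids,
                                                     case.fda_dts)):
            qi = _version_quarter(fda, labels)
            for table, table_rows in rows.items():
                for row in table_rows:
                    if row[0] == pid:
                        per_quarter[qi][table].append(row)
    for qi, label in enumerate(labels):
        yy, q = int(label[:4]) % 100, label.split("Q")[1]
        for table, header in HEADERS.items():
            path = out_dir / f"{table}{yy:02d}Q{q}.txt"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("$".join(header) + "\n")
                for row in per_quarter[qi][table]:
                    fh.write("$".join(row) + "\n")


def write_manifest(manifest: Dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(manifest):
            fh.write(f"{key}={manifest[key]}\n")


def read_manifest(path: str | Path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if "=" in line:
            key, _, value = line.partition("=")
            out[key] = value
    return out


def generate(config: SynthConfig, out_dir: str | Path) -> Dict:
    """Write a full synthetic quarterly-file set plus manifest.txt."""
    cases, manifest = generate_cases(config)
    out_dir = Path(out_dir)
    write_quarter_files(cases, config, out_dir)
    write_manifest(manifest, out_dir / "manifest.txt")
    (out_dir / "target_drugs.txt").write_text(
        "# synthetic target-drug dictionary\n"
        "EFGARTIGIMOD\nVYVGART\nVYVGART HYTRULO\n", encoding="utf-8")
    return manifest


# ---------------------------------------------------------------------------
# Fast in-memory path (no files, no dedup) for simulation studies


def cases_to_reports(cases: Sequence[SynthCase],
                     dictionary: Optional[Set[str]] = None) -> Cohort:
    """Materialise ReportRecords directly, bypassing file IO and dedup.

    Equivalent to generate -> load_quarters -> deduplicate -> build_cohort
    when duplicate versions carry identical content (they do); used for
    replicated simulation studies where file round-trips would dominate.
    """
    dictionary = dictionary or {"EFGARTIGIMOD", "VYVGART", "VYVGART HYTRULO"}
    target: List[ReportRecord] = []
    background: List[ReportRecord] = []
    for case in cases:
        event_dt, event_status = parse_partial_date_status(case.event_dt)
        start_dt, start_status = parse_partial_date_status(case.start_dt)
        drugs = []
        for name, role in case.drugs:
            norm = normalize_drug_name(name)
            is_t = match_target(norm, dictionary)
            drugs.append(DrugEntry(
                name=norm, role=role,
                therapy_start=start_dt if role == "PS" else None,
                therapy_start_status=start_status if role == "PS" else MISSING,
                is_target=is_t))
        record = ReportRecord(
            primaryid=case.primaryids[-1], caseid=case.caseid,
            fda_dt=parse_partial_date_status(case.fda_dts[-1])[0],
            event_dt=event_dt, event_dt_status=event_status,
            sex=case.sex if case.sex in ("F", "M") else "unknown",
            age_years=float(case.age) if case.age else None,
            reporter={"CN": "consumer", "MD": "physician", "PH": "pharmacist",
                      "HP": "health_professional"}.get(case.occp_cod,
                                                       "other_unknown"),
            country=case.country or "unknown",
            receipt_year_quarter="",
            drugs=drugs, events=set(case.pts), outcomes=set(case.outcomes),
            indications=[case.indication],
        )
        (target if record.is_target else background).append(record)
    return Cohort(target_reports=target, background_reports=background,
                  drug_dictionary=set(dictionary))


# ---------------------------------------------------------------------------
# Deterministic validation fixture


def make_validation_fixture(out_dir: str | Path) -> Dict:
    """Write a deterministic dataset planting the study's count ratios.

    3,040 target reports carry exactly 402 F / 372 M sex codes, 1,618
    hospitalisation and 270 death outcome codes (with the other serious
    outcomes at their observed counts), and exactly 992 reports have
    fully datable onsets binned 342 / 250 / 150 / 113 / 137 across
    0-30 / 31-90 / 91-180 / 181-365 / >365 days. A small synthetic
    background (1,000 reports) completes the database. Golden-file tests
    check that the pipeline reproduces the planted percentages.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_target, n_background = 3040, 1000
    config = SynthConfig(n_cases=n_target + n_background, n_quarters=2)

    outcome_slices = {  # planted counts; overlapping index windows
        "HO": range(0, 1618), "OT": range(800, 2248), "DE": range(100, 370),
        "LT": range(2000, 2174), "RI": range(50, 58), "DS": range(10, 17)}
    onset_plan: List[int] = (
        [1 + i % 30 for i in range(342)]
        + [31 + i % 60 for i in range(250)]
        + [91 + i % 90 for i in range(150)]
        + [181 + i % 185 for i in range(113)]
        + [366 + i % 300 for i in range(137)])
    fixture_pts = ("HEADACHE", "URINARY TRACT INFECTION", "NEPHROLITHIASIS",
                   "FATIGUE", "NAUSEA")

    cases: List[SynthCase] = []
    for i in range(n_target + n_background):
        is_target = i < n_target
        caseid = str(500_000_000 + i)
        fda = _dt.date(2022, 1, 3) + _dt.timedelta(days=(i * 7) % 180)
        qi = 0 if fda < _dt.date(2022, 4, 1) else 1
        if is_target:
            sex = "F" if i < 402 else ("M" if i < 402 + 372 else "")
            outcomes = tuple(code for code, idx in outcome_slices.items()
                             if i in idx)
            if i < len(onset_plan):
                start = _dt.date(2022, 1, 1) + _dt.timedelta(days=i % 5)
                event = start + _dt.timedelta(days=onset_plan[i])
                start_str, event_str = (start.strftime("%Y%m%d"),
                                        event.strftime("%Y%m%d"))
            else:
                start_str, event_str = "", ""
            drugs = [("VYVGART", "PS")]
            pts = (fixture_pts[i % len(fixture_pts)],)
            indication = "MYASTHENIA GRAVIS"
        else:
            sex, outcomes = "", ("HO",) if i % 2 else ()
            start_str, event_str = "", ""
            drugs = [(_OTHER_DRUGS[i % len(_OTHER_DRUGS)], "PS")]
            pts = (fixture_pts[i % len(fixture_pts)],
                   fixture_pts[(i + 1) % len(fixture_pts)])
            indication = "HYPERTENSION"
        cases.append(SynthCase(
            caseid=caseid, primaryids=[caseid + "1"],
            fda_dts=[fda.strftime("%Y%m%d")], is_target=is_target, pts=pts,
            sex=sex, age="", age_cod="", occp_cod="CN", country="US",
            indication=indication, outcomes=outcomes, drugs=drugs,
            event_dt=event_str, start_dt=start_str,
            onset_days_true=None, quarter_index=qi))

    write_quarter_files(cases, config, out_dir)
    manifest = _build_manifest(config, cases)
    manifest["fixture"] = "validation"
    write_manifest(manifest, out_dir / "manifest.txt")
    (out_dir / "target_drugs.txt").write_text(
        "EFGARTIGIMOD\nVYVGART\nVYVGART HYTRULO\n", encoding="utf-8")
    return manifest
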