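"""Disproportionality estimators, joint signal calling, and the
contingency-table reconstruction oracle.

For each preferred term (PT) a 2x2 table is formed over (report, PT)
pairs:

    a  target drug  & target PT          b  target drug  & other PTs
    c  other drugs  & target PT          d  other drugs  & other PTs

Four estimators are computed in their simplified (non-shrunk) forms:

    ROR  = ad/(bc),             95% CI = exp(ln ROR +/- 1.96*sqrt(S))
    PRR  = [a/(a+b)]/[c/(c+d)], with Pearson chi2 (no continuity corr.)
    IC   = log2[ a*N / ((a+c)(a+b)) ]
    EBGM = a*N / ((a+c)(a+b)),  EBGM05 = exp(ln EBGM - 1.96*sqrt(S))

with S = 1/a + 1/b + 1/c + 1/d. Note that in these simplified forms
IC == log2(EBGM) identically: both are the relative reporting ratio, once
on the log2 scale and once on the natural scale. No empirical-Bayes or
BCPNN posterior shrinkage is applied. IC025 uses the delta-method
variance V(IC) = S/(ln 2)^2, i.e. IC025 = IC - 2*sqrt(V); interval
conventions for IC differ across the literature, so IC025 is reported but
deliberately not treated as a cross-implementation invariant.

A PT is a *signal* only when all four criteria hold simultaneously:
ROR CI low > 1 with a >= 3; PRR >= 2 with chi2 >= 4 and a >= 3;
IC025 > 0; EBGM05 > 2. The joint rule is conservative by construction.

Zero cells yield null statistics rather than Haldane-corrected ones by
default: a zero-a PT can never meet the a >= 3 criterion anyway, and
uncorrected estimates are what the threshold set was defined for. Pass
``haldane=True`` to add 0.5 to every cell for exploration.

The reconstruction oracle inverts the estimators: given a published row
(a, ROR, PRR, chi2) it numerically solves for the unpublished cells
(b, c, d), allowing published EBGM/IC/CI values to be checked without the
source database.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import Cohort, round_half_up

__all__ = [
    "ContingencyTable",
    "SignalStats",
    "ReconstructionError",
    "build_tables",
    "ror_stats",
    "prr_stats",
    "ic_stats",
    "ebgm_stats",
    "compute_signal_stats",
    "score_tables",
    "call_signal",
    "apply_blocklist",
    "aggregate_by_soc",
    "load_pt_soc_map",
    "load_blocklist",
    "reconstruct_table",
    "signals_to_frame",
]

log = logging.getLogger(__name__)

Z95 = 1.96
LN2 = math.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 (report, PT)-pair counts for one drug-PT combination."""

    pt: str
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.N <= 0:
            raise ValueError("empty table")

    @property
    def N(self) -> float:
        return self.a + self.b + self.c + self.d

    def with_haldane(self) -> "ContingencyTable":
        """Haldane-Anscombe 0.5 continuity correction on every cell."""
        return ContingencyTable(self.pt, self.a + 0.5, self.b + 0.5,
                                self.c + 0.5, self.d + 0.5)


@dataclass
class SignalStats:
    """All four estimators plus the joint signal call for one PT."""

    pt: str
    a: int
    soc: Optional[str] = None
    ror: Optional[float] = None
    ror_ci95: Optional[Tuple[float, float]] = None
    prr: Optional[float] = None
    chi2: Optional[float] = None
    ic: Optional[float] = None
    ic025: Optional[float] = None
    ebgm: Optional[float] = None
    ebgm05: Optional[float] = None
    is_signal: bool = False
    criteria_flags: Dict[str, bool] = field(default_factory=dict)
    excluded_reason: Optional[str] = None
    null_reason: Optional[str] = None


class ReconstructionError(RuntimeError):
    """The published statistics admit no positive 2x2 completion."""


# ---------------------------------------------------------------------------
# Table construction


def build_tables(cohort: Cohort) -> List[ContingencyTable]:
    """One 2x2 table per PT occurring at least once in the target cohort.

    a+b equals the target cohort's total (report, PT) pair count for every
    table; c+d the background's — each PT counts at most once per report.
    """
    if not cohort.target_reports:
        raise ValueError("empty target cohort: no tables to build")
    target_pairs = cohort.n_target_pairs
    background_pairs = cohort.n_background_pairs

    a_counts: Dict[str, int] = {}
    for r in cohort.target_reports:
        for pt in r.events:
            a_counts[pt] = a_counts.get(pt, 0) + 1
    c_counts: Dict[str, int] = {}
    for r in cohort.background_reports:
        for pt in r.events:
            c_counts[pt] = c_counts.get(pt, 0) + 1

    log.info("margins: target pairs=%d, background pairs=%d, PTs=%d",
             target_pairs, background_pairs, len(a_counts))
    tables = []
    for pt in sorted(a_counts):
        a = a_counts[pt]
        c = c_counts.get(pt, 0)
        tables.append(ContingencyTable(pt=pt, a=a, b=target_pairs - a,
                                       c=c, d=background_pairs - c))
    return tables


# ---------------------------------------------------------------------------
# Estimators


def _S(t: ContingencyTable) -> float:
    return 1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d


def ror_stats(t: ContingencyTable) -> Optional[Tuple[float, float, float]]:
    """(ROR, CI low, CI high); None when any cell is zero."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return None
    ror = (t.a * t.d) / (t.b * t.c)
    half = Z95 * math.sqrt(_S(t))
    return ror, ror * math.exp(-half), ror * math.exp(half)


def prr_stats(t: ContingencyTable) -> Optional[Tuple[float, float]]:
    """(PRR, Pearson chi2 without continuity correction); None on a zero margin."""
    if t.c == 0 or t.a + t.b == 0 or t.c + t.d == 0:
        return None
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    denom = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    if denom == 0:
        return None
    chi2 = (t.a * t.d - t.b * t.c) ** 2 * t.N / denom
    return prr, chi2


def ic_stats(t: ContingencyTable) -> Optional[Tuple[float, float]]:
    """(IC, IC025) with the delta-method variance; None when a cell is zero."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return None
    ic = math.log2(t.a * t.N / ((t.a + t.c) * (t.a + t.b)))
    v = _S(t) / LN2 ** 2
    return ic, ic - 2.0 * math.sqrt(v)


def ebgm_stats(t: ContingencyTable) -> Optional[Tuple[float, float]]:
    """(EBGM, EBGM05) in the simplified relative-reporting-ratio form."""
    if min(t.a, t.b, t.c, t.d) == 0:
        return None
    ebgm = t.a * t.N / ((t.a + t.c) * (t.a + t.b))
    ebgm05 = math.exp(math.log(ebgm) - Z95 * math.sqrt(_S(t)))
    return ebgm, ebgm05


def compute_signal_stats(t: ContingencyTable, soc: Optional[str] = None,
                         haldane: bool = False) -> SignalStats:
    """Evaluate all four estimators on one table and apply the joint rule."""
    tt = t.with_haldane() if haldane else t
    stats = SignalStats(pt=t.pt, a=int(t.a), soc=soc)
    if min(tt.a, tt.b, tt.c, tt.d) == 0:
        zero = [n for n, v in zip("abcd", (tt.a, tt.b, tt.c, tt.d)) if v == 0]
        stats.null_reason = f"zero cell(s): {','.join(zero)}"
    else:
        ror = ror_stats(tt)
        stats.ror, lo, hi = ror
        stats.ror_ci95 = (lo, hi)
        stats.prr, stats.chi2 = prr_stats(tt)
        stats.ic, stats.ic025 = ic_stats(tt)
        stats.ebgm, stats.ebgm05 = ebgm_stats(tt)
    stats.is_signal = call_signal(stats)
    return stats


def call_signal(stats: SignalStats) -> bool:
    """The joint four-criterion rule; also fills ``criteria_flags``.

    A null estimator (zero cell) fails its own criterion. Boundary
    conventions: a >= 3 and PRR >= 2 and chi2 >= 4 are inclusive;
    IC025 > 0 and EBGM05 > 2 and ROR CI low > 1 are strict.
    """
    a_ok = stats.a >= 3
    flags = {
        "ror": stats.ror_ci95 is not None and stats.ror_ci95[0] > 1.0 and a_ok,
        "prr": (stats.prr is not None and stats.chi2 is not None
                and stats.prr >= 2.0 and stats.chi2 >= 4.0 and a_ok),
        "ic": stats.ic025 is not None and stats.ic025 > 0.0,
        "ebgm": stats.ebgm05 is not None and stats.ebgm05 > 2.0,
    }
    stats.criteria_flags = flags
    return all(flags.values())


def score_tables(tables: Sequence[ContingencyTable],
                 pt_to_soc: Optional[Dict[str, str]] = None,
                 haldane: bool = False) -> List[SignalStats]:
    pt_to_soc = pt_to_soc or {}
    return [compute_signal_stats(t, soc=pt_to_soc.get(t.pt), haldane=haldane)
            for t in tables]


# ---------------------------------------------------------------------------
# Blocklist and SOC aggregation


def load_blocklist(path: str | Path) -> Set[str]:
    """One PT per line, '#' comments, case-insensitive."""
    pts: Set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            pts.add(line.upper())
    return pts


def load_pt_soc_map(path: str | Path) -> Dict[str, str]:
    """Two-column TSV (pt, soc); pt matched case-insensitively."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    return {str(pt).strip().upper(): str(soc).strip()
            for pt, soc in zip(df["pt"], df["soc"])}


def apply_blocklist(signals: Sequence[SignalStats],
                    blocklist: Set[str]) -> List[SignalStats]:
    """Flag blocklisted PTs as excluded; nothing is deleted.

    Mechanical support for the study-design step of removing signals that
    reflect the treated disease itself (e.g. MYASTHENIA GRAVIS under a
    myasthenia drug) rather than the drug. Excluded rows stay in the full
    output and are only omitted from headline tables.
    """
    blocklist = {pt.upper() for pt in blocklist}
    present = {s.pt for s in signals}
    for pt in sorted(blocklist - present):
        log.warning("blocklist PT not among scored PTs: %s", pt)
    out = []
    for s in signals:
        if s.pt in blocklist:
            s.excluded_reason = "blocklist"
        out.append(s)
    return out


def aggregate_by_soc(signals: Sequence[SignalStats],
                     pt_to_soc: Dict[str, str]) -> pd.DataFrame:
    """Per-SOC totals: (report, PT) pair count, share of all pairs, signal count."""
    pt_to_soc = {k.upper(): v for k, v in pt_to_soc.items()}
    rows: Dict[str, Dict[str, float]] = {}
    total_pairs = sum(s.a for s in signals)
    for s in signals:
        soc = pt_to_soc.get(s.pt)
        if soc is None:
            soc = "UNMAPPED"
            log.warning("PT without SOC mapping: %s", s.pt)
        agg = rows.setdefault(soc, {"pair_count": 0, "signal_count": 0})
        agg["pair_count"] += s.a
        agg["signal_count"] += int(s.is_signal and s.excluded_reason is None)
    df = pd.DataFrame(
        [(soc, int(v["pair_count"]),
          round_half_up(100.0 * v["pair_count"] / total_pairs) if total_pairs else 0.0,
          int(v["signal_count"]))
         for soc, v in sorted(rows.items(), key=lambda kv: -kv[1]["pair_count"])],
        columns=["soc", "pair_count", "percent", "signal_count"],
    )
    return df


# ---------------------------------------------------------------------------
# Reconstruction oracle


def _log_residuals(x: np.ndarray, a: float, ror: float, prr: float,
                   chi2: float) -> np.ndarray:
    # far-field starts can overflow; treat any non-finite point as terrible
    with np.errstate(over="ignore", invalid="ignore"):
        b, c, d = np.exp(np.clip(x, -500, 500))
        n = a + b + c + d
        r_hat = (a * d) / (b * c)
        p_hat = (a / (a + b)) / (c / (c + d))
        num = (a * d - b * c) ** 2 * n
        den = (a + b) * (c + d) * (a + c) * (b + d)
        x2_hat = num / den
    if not (np.isfinite(r_hat) and np.isfinite(p_hat)
            and np.isfinite(x2_hat)) or min(r_hat, p_hat, x2_hat) <= 0:
        return np.array([1e3, 1e3, 1e3])
    return np.array([math.log(r_hat / ror), math.log(p_hat / prr),
                     math.log(x2_hat / chi2)])


def reconstruct_table(a: float, ror: float, prr: float, chi2: float,
                      pt: str = "", rel_tol: float = 0.005,
                      seed: int = 0) -> ContingencyTable:
    """Complete the 2x2 table from a published (a, ROR, PRR, chi2) row.

    Solves the three estimator equations for positive (b, c, d) by
    damped least squares on the log scale, from a deterministic ladder of
    starting points spanning plausible database scales, then a seeded
    random multi-start as a fallback. A solution must reproduce all three
    inputs within ``rel_tol`` relative error; otherwise
    :class:`ReconstructionError` is raised — a table that does not
    reproduce the inputs is worse than no table.
    """
    if min(a, ror, prr, chi2) <= 0:
        raise ValueError("all reconstruction inputs must be positive")
    target = (ror, prr, chi2)

    def solve_from(x0: np.ndarray) -> Optional[ContingencyTable]:
        sol = optimize.least_squares(
            _log_residuals, x0, args=(a, ror, prr, chi2),
            method="lm", xtol=1e-14, ftol=1e-14, max_nfev=4000)
        b, c, d = np.exp(sol.x)
        try:
            t = ContingencyTable(pt=pt, a=a, b=b, c=c, d=d)
        except ValueError:
            return None
        got = (ror_stats(t)[0], *prr_stats(t))
        if all(abs(g - want) <= rel_tol * want for g, want in zip(got, target)):
            return t
        return None

    # deterministic ladder: b near a/(something), c from prr at several
    # assumed background scales, d spanning 1e3..1e7 pairs
    starts: List[np.ndarray] = []
    for b0 in (5 * a, 20 * a, 100 * a, 400 * a):
        for d0 in (1e3, 1e4, 1e5, 1e6, 1e7):
            c0 = max(a * d0 / (b0 * ror), 1e-3)
            starts.append(np.log(np.array([b0, c0, d0])))
    for x0 in starts:
        t = solve_from(x0)
        if t is not None:
            return t
    rng = np.random.default_rng(seed)
    for _ in range(60):
        x0 = rng.uniform(np.log([a, a / 10, 1e2]), np.log([1e6, 1e5, 1e8]))
        t = solve_from(x0)
        if t is not None:
            return t
    raise ReconstructionError(
        f"no positive (b,c,d) reproduces (ROR={ror}, PRR={prr}, chi2={chi2}) "
        f"for a={a} within {rel_tol:.1%}")


# ---------------------------------------------------------------------------
# Output


def signals_to_frame(signals: Sequence[SignalStats]) -> pd.DataFrame:
    """Flatten SignalStats to the output-table schema (2-decimal, half-up)."""

    def r2(x: Optional[float]) -> Optional[float]:
        return None if x is None else round_half_up(x)

    rows = []
    for s in signals:
        lo, hi = s.ror_ci95 if s.ror_ci95 else (None, None)
        rows.append({
            "soc": s.soc or "", "pt": s.pt, "a": s.a,
            "ror": r2(s.ror), "ror_ci_low": r2(lo), "ror_ci_high": r2(hi),
            "prr": r2(s.prr), "chi2": r2(s.chi2),
            "ic": r2(s.ic), "ic025": r2(s.ic025),
            "ebgm": r2(s.ebgm), "ebgm05": r2(s.ebgm05),
            "is_signal": s.is_signal,
            "excluded_reason": s.excluded_reason or "",
        })
    return pd.DataFrame(rows)
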