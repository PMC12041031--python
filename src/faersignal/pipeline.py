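"""End-to-end orchestration: config, full pipeline run, artifact output,
and validation of published rows via the reconstruction oracle.

The pipeline stages are load -> dedup -> cohort -> disproportionality
(+blocklist, +SOC aggregation) -> onset -> outcomes -> subgroups ->
sensitivity. Every stage logs input/output/dropped counts so the study
flow diagram can be regenerated from the run log alone, and identical
inputs and config produce byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import disprop, onset, strata
from .faers_io import load_quarters

__all__ = ["RunConfig", "run_pipeline", "validate_against_paper"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML."""

    quarters: List[str]
    data_dir: str
    drug_dictionary_path: str
    output_dir: str
    pt_soc_map_path: Optional[str] = None
    blocklist_path: Optional[str] = None
    io_strict: bool = True
    background_ps_only: bool = False
    tto_per_event: bool = False
    subgroups: List[str] = field(default_factory=lambda: ["F", "M"])
    sensitivity_enabled: bool = True
    haldane: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        flat = dict(raw)
        for section, prefix in (("io", "io"), ("background", "background"),
                                ("tto", "tto"), ("sensitivity", "sensitivity")):
            sub = flat.pop(section, {}) or {}
            for key, value in sub.items():
                flat[f"{prefix}_{key}"] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def validate(self) -> None:
        for path in (self.data_dir, self.drug_dictionary_path,
                     self.pt_soc_map_path, self.blocklist_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Dict[str, str]:
    """Execute the full analysis; returns {artifact name: path}."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, str] = {}
    log_lines: List[str] = []

    def stage(name: str, n_in: int, n_out: int, dropped: str = "") -> None:
        line = f"stage={name}\tin={n_in}\tout={n_out}"
        if dropped:
            line += f"\tdropped={dropped}"
        log_lines.append(line)
        log.info(line)

    # --- load
    quarters = load_quarters(config.data_dir, config.quarters,
                             strict=config.io_strict)
    demo_rows = [r for q in quarters for r in q.rows_by_table.get("DEMO", [])]
    stage("load", len(config.quarters), sum(
        sum(q.row_counts.values()) for q in quarters))

    # --- dedup
    dedup_map = cohort_mod.deduplicate(demo_rows)
    stage("dedup", len(demo_rows), len(dedup_map),
          dropped=f"duplicate_versions:{len(demo_rows) - len(dedup_map)}")

    # --- cohort
    dictionary = cohort_mod.load_drug_dictionary(config.drug_dictionary_path)
    cohort = cohort_mod.build_cohort(quarters, dedup_map, dictionary)
    if config.background_ps_only:
        kept = [r for r in cohort.background_reports
                if any(d.role == "PS" for d in r.drugs)]
        cohort = cohort_mod.Cohort(cohort.target_reports, kept,
                                   cohort.drug_dictionary)
    stage("cohort", len(dedup_map), len(cohort.target_reports),
          dropped=f"background:{len(cohort.background_reports)}")

    char = cohort_mod.characteristics_table(cohort)
    _write_tsv(char, out_dir / "characteristics.tsv")
    artifacts["characteristics"] = str(out_dir / "characteristics.tsv")

    # --- disproportionality
    pt_to_soc = (disprop.load_pt_soc_map(config.pt_soc_map_path)
                 if config.pt_soc_map_path else {})
    tables = disprop.build_tables(cohort)
    signals = disprop.score_tables(tables, pt_to_soc=pt_to_soc,
                                   haldane=config.haldane)
    if config.blocklist_path:
        blocklist = disprop.load_blocklist(config.blocklist_path)
        signals = disprop.apply_blocklist(signals, blocklist)
    stage("disprop", len(tables),
          sum(s.is_signal and not s.excluded_reason for s in signals))
    _write_tsv(disprop.signals_to_frame(signals), out_dir / "signals.tsv")
    artifacts["signals"] = str(out_dir / "signals.tsv")
    soc_df = disprop.aggregate_by_soc(signals, pt_to_soc)
    _write_tsv(soc_df, out_dir / "soc_summary.tsv")
    artifacts["soc_summary"] = str(out_dir / "soc_summary.tsv")

    # --- onset
    records = [onset.compute_onset(r) for r in cohort.target_reports]
    if config.tto_per_event:
        expanded = []
        for record, report in zip(records, cohort.target_reports):
            expanded.extend([record] * max(len(report.events), 1))
        records_for_summary = expanded
    else:
        records_for_summary = records
    summary = onset.summarize_onset(records_for_summary)
    stage("onset", len(records), summary.n_included,
          dropped=";".join(f"{reason}:{n}" for reason, n in sorted(
              pd.Series([r.exclusion_reason for r in records
                         if not r.included]).value_counts().items())))
    onset_df = pd.DataFrame(summary.bins, columns=["bin", "n", "percent"])
    _write_tsv(onset_df, out_dir / "onset.tsv")
    _write_tsv(onset.onset_audit_frame(records), out_dir / "onset_audit.tsv")
    artifacts["onset"] = str(out_dir / "onset.tsv")

    # --- outcomes
    outc = onset.outcome_proportions(cohort)
    _write_tsv(outc, out_dir / "outcomes.tsv")
    artifacts["outcomes"] = str(out_dir / "outcomes.tsv")

    # --- subgroups
    for sex in config.subgroups:
        sub = strata.subgroup_analysis(cohort, sex, pt_to_soc=pt_to_soc)
        name = f"subgroup_{sex}"
        _write_tsv(disprop.signals_to_frame(sub), out_dir / f"{name}.tsv")
        artifacts[name] = str(out_dir / f"{name}.tsv")
        stage(name, len(cohort.target_reports),
              sum(1 for r in cohort.target_reports if r.sex == sex))
    if len(config.subgroups) >= 2:
        male = strata.subgroup_analysis(cohort, "M", pt_to_soc=pt_to_soc)
        female = strata.subgroup_analysis(cohort, "F", pt_to_soc=pt_to_soc)
        _write_tsv(strata.subgroup_table(male, female),
                   out_dir / "subgroup_male_female.tsv")
        artifacts["subgroup_male_female"] = str(
            out_dir / "subgroup_male_female.tsv")

    # --- sensitivity
    if config.sensitivity_enabled:
        sens = strata.sensitivity_exclude_concomitant(cohort)
        stage("sensitivity", len(cohort.target_reports),
              len(sens.target_reports))
        if sens.target_reports:
            sens_signals = disprop.score_tables(disprop.build_tables(sens),
                                                pt_to_soc=pt_to_soc)
            _write_tsv(disprop.signals_to_frame(sens_signals),
                       out_dir / "sensitivity_signals.tsv")
            artifacts["sensitivity_signals"] = str(
                out_dir / "sensitivity_signals.tsv")

    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n",
                                         encoding="utf-8")
    artifacts["run_log"] = str(out_dir / "run_log.txt")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(artifacts, fh, indent=2, sort_keys=True)
    return artifacts


def validate_against_paper(rows_file: str | Path,
                           rel_tol_ebgm: float = 0.02,
                           abs_tol_ic: float = 0.03,
                           rel_tol_ci: float = 0.02) -> pd.DataFrame:
    """Check published signal rows against the reconstruction oracle.

    ``rows_file`` is a TSV with columns label, a, ror, ci_low, ci_high,
    prr, chi2, ic, ebgm (ci/ic/ebgm columns optional). For each row the
    2x2 table is completed from (a, ror, prr, chi2) and the remaining
    statistics re-evaluated; the report lists reproduced values, relative
    errors and pass/fail at the given tolerances. Rows whose statistics
    admit no positive completion are reported as non-convergent, never
    silently passed.
    """
    rows = pd.read_csv(rows_file, sep="\t", comment="#")
    out = []
    for _, row in rows.iterrows():
        result: Dict[str, object] = {"label": row["label"]}
        try:
            t = disprop.reconstruct_table(float(row["a"]), float(row["ror"]),
                                          float(row["prr"]), float(row["chi2"]))
        except (disprop.ReconstructionError, ValueError) as err:
            result.update(converged=False, note=str(err), ok=False)
            out.append(result)
            continue
        result.update(converged=True, b=t.b, c=t.c, d=t.d)
        ebgm, _ = disprop.ebgm_stats(t)
        ic, _ = disprop.ic_stats(t)
        _, lo, hi = disprop.ror_stats(t)
        result["ebgm_recomputed"] = ebgm
        result["ic_recomputed"] = ic
        checks: List[bool] = []
        if "ebgm" in row and pd.notna(row.get("ebgm")):
            err_e = abs(ebgm - row["ebgm"]) / row["ebgm"]
            result["ebgm_rel_err"] = err_e
            checks.append(err_e <= rel_tol_ebgm)
        if "ic" in row and pd.notna(row.get("ic")):
            err_i = abs(ic - row["ic"])
            result["ic_abs_err"] = err_i
            checks.append(err_i <= abs_tol_ic)
        for bound, value in (("ci_low", lo), ("ci_high", hi)):
            if bound in row and pd.notna(row.get(bound)):
                err_c = abs(value - row[bound]) / row[bound]
                result[f"{bound}_rel_err"] = err_c
                checks.append(err_c <= rel_tol_ci)
        result["ok"] = all(checks) if checks else True
        out.append(result)
    return pd.DataFrame(out)
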