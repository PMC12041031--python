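# faersignal

Disproportionality-based signal detection for FAERS spontaneous
adverse-event reports.

The FDA Adverse Event Reporting System (FAERS) distributes spontaneous
reports as quarterly `$`-delimited ASCII tables (DEMO, DRUG, REAC, OUTC,
THER, INDI). Pharmacovigilance teams mine this database for drug–event
pairs reported disproportionately often relative to the database
background. `faersignal` implements that workflow end to end for a
single target drug — deduplication, primary-suspect cohort construction,
four disproportionality estimators with joint-threshold signal calling,
time-to-onset and serious-outcome summaries, sex-stratified subgroup and
monotherapy sensitivity analyses — plus a synthetic FAERS generator with
planted ground truth so every stage is testable without downloading the
real database, and a *reconstruction oracle* that completes a published
2×2 table from the statistics a paper prints.

## The statistics

For each MedDRA preferred term (PT), counting each PT at most once per
deduplicated report, form the 2×2 table over (report, PT) pairs

|                | target PT | other PTs |
|----------------|-----------|-----------|
| **target drug**| a         | b         |
| **other drugs**| c         | d         |

with N = a+b+c+d and S = 1/a + 1/b + 1/c + 1/d, and compute

- ROR = ad/(bc), 95% CI = exp(ln ROR ± 1.96·√S)
- PRR = [a/(a+b)] / [c/(c+d)], with Pearson χ² = (ad−bc)²·N / [(a+b)(c+d)(a+c)(b+d)]
- IC = log₂[ aN / ((a+c)(a+b)) ]  (information component, simplified form)
- EBGM = aN / ((a+c)(a+b)), EBGM05 = exp(ln EBGM − 1.96·√S)

A PT is called a **signal** only when all four criteria hold
simultaneously: ROR CI low > 1 with a ≥ 3; PRR ≥ 2 with χ² ≥ 4 and
a ≥ 3; IC025 > 0; EBGM05 > 2. In these simplified (non-shrunk) forms
IC ≡ log₂(EBGM); see `docs/methods.md` for the interval conventions and
the deliberate omission of Bayesian shrinkage.

## Worked example: checking a published signal row

Publications typically print a signal row as the case count plus ROR,
PRR and χ², leaving the other three cells of the 2×2 table unstated.
`reconstruct_table` solves for them, after which any remaining statistic
can be re-derived:

```python
from faersignal import ebgm_stats, ic_stats, reconstruct_table

t = reconstruct_table(a=58, ror=8.13, prr=7.99, chi2=353.46)
print(t.b, t.c, t.d)          # 2895.9  9774.4  3967617.3
print(ebgm_stats(t)[0])        # 7.9488  — published as 7.95
print(ic_stats(t)[0])          # 2.9907  — published as 2.99
```

Running `python examples/02_reconstruct_published_row.py` prints:

```
completed table: a=58, b=2895.9, c=9774.4, d=3967617.3 (N=3,980,346 report-PT pairs)
re-derived EBGM = 7.95 (published 7.95), IC = 2.99 (published 2.99)
re-derived ROR 95% CI = (6.26, 10.55) (published 6.26-10.55)
```

i.e. the published Bayesian statistics and CI bounds are exactly what
the estimator formulas yield on the completed table — the row is
internally consistent, and our implementation of all four estimators
agrees with it to the printed precision.

The other scripts in `examples/` walk through the synthetic pipeline
(generation → dedup → cohort → signal calling), the time-to-onset and
serious-outcome summaries, and the subgroup/sensitivity analyses.

## Command line

```
faersignal synth -o data/            # synthetic quarter set + truth manifest
faersignal run -c config.yml         # full pipeline -> TSV artifacts
faersignal validate --rows rows.tsv  # check published rows via the oracle
```

`run` writes `characteristics.tsv`, `signals.tsv`, `soc_summary.tsv`,
`onset.tsv`, `outcomes.tsv`, per-stratum subgroup tables,
`sensitivity_signals.tsv` and a `run_log.txt` with stage-by-stage row
counts.

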