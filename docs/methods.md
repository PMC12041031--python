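# Methods

## Data model and counting unit

A FAERS *case* (CASEID) may appear as several versions (PRIMARYID)
across quarterly files as follow-up reports arrive. Deduplication keeps,
per case, the version with the most recent FDA_DT, breaking FDA_DT ties
toward the numerically larger PRIMARYID; versions whose FDA_DT does not
parse lose to any version with a valid one. Reports with a missing
CASEID are treated as singleton cases and counted in the log.

All disproportionality counting uses the **(deduplicated report,
distinct PT) pair**: each preferred term counts at most once per report.
This is the only unit under which a cohort can simultaneously have a
report total and a larger adverse-event total (e.g. ~4.1 events per
report), and it makes a+b constant across PTs for a fixed cohort — a
property the tests assert.

A report enters the *target* cohort iff at least one DRUG row has role
PS and a name matching the drug dictionary (whole-word-prefix matching
by default, so a dictionary entry `EFGARTIGIMOD` matches
`EFGARTIGIMOD ALFA-FCAB` but `VYVGART` never matches `VYVANSE`). All
other deduplicated reports form the background. Whether the background
is restricted to reports that themselves have a PS drug is a config
switch (`background.ps_only`, default off: all deduplicated reports).

## Estimators

With cells (a, b, c, d), N = a+b+c+d and S = 1/a+1/b+1/c+1/d:

| estimator | formula | 95% interval | criterion |
|---|---|---|---|
| ROR | ad/(bc) | exp(ln ROR ± 1.96√S) | CI low > 1, a ≥ 3 |
| PRR | [a/(a+b)]/[c/(c+d)] | — (paired with χ²) | PRR ≥ 2, χ² ≥ 4, a ≥ 3 |
| χ² | (ad−bc)²N/[(a+b)(c+d)(a+c)(b+d)] | — | (Pearson, no continuity corr.) |
| IC | log₂[aN/((a+c)(a+b))] | IC ± 2√V, V = S/ln²2 | IC025 > 0 |
| EBGM | aN/((a+c)(a+b)) | exp(ln EBGM ± 1.96√S) | EBGM05 > 2 |

A PT is a signal only when **all four** criteria hold simultaneously;
boundary conventions are a ≥ 3, PRR ≥ 2 and χ² ≥ 4 inclusive, the
interval bounds strict. The joint rule is conservative by construction
(its false-positive set is the intersection of the four single-criterion
sets), which the null-replicate test demonstrates empirically.

Two deliberate departures from the estimators' eponymous method families:

- **No Bayesian shrinkage.** IC and EBGM are implemented in their
  simplified, non-shrunk forms — both are the relative reporting ratio
  aN/((a+c)(a+b)), on log₂ and natural scales — not the BCPNN posterior
  or DuMouchel's empirical-Bayes geometric mean. Consequently
  IC ≡ log₂(EBGM), an identity the tests check exactly. For signal-rich
  cells (a ≥ 3, as the criteria require) the shrunk and non-shrunk forms
  are close; for a ≤ 2 they are not, but such cells can never signal.
- **IC interval.** Interval conventions for the IC vary across the
  literature and published IC025 values are often irreproducible from
  any closed-form variance. We use the delta-method variance
  V(IC) = S/ln²2 (so IC025 = IC − 2√V), document it, and treat IC025 as
  implementation-defined: it participates in the signal rule but is not
  validated against any published value.

**Zero cells** yield null statistics rather than continuity-corrected
ones by default: a zero-a PT cannot meet a ≥ 3 anyway, and the threshold
set was defined for uncorrected estimates. A Haldane–Anscombe +0.5
correction is available (`haldane=True`) for exploration.

## Reconstruction oracle

Given a published row (a, ROR, PRR, χ²), the oracle solves the three
estimator equations for positive (b, c, d) by Levenberg–Marquardt least
squares on log-scale residuals, from a deterministic ladder of starting
points spanning plausible database scales (b/a ∈ 5…400, d ∈ 10³…10⁷)
with a seeded random multi-start fallback. A solution is accepted only
if it reproduces all three inputs within 0.5% relative error; otherwise
the oracle raises, never fabricating a table. Empirically the solution
is unique: round-trips on random tables recover (b, c, d) to machine
precision (the suite asserts 0.1%).

Feasibility note: any positive table with ROR > 1 satisfies ROR > PRR
(ad > bc ⟹ a/b > c/d), so a row claiming PRR ≥ ROR is genuinely
infeasible and is the canonical non-convergence case in the tests. A
merely *wrong* ROR (with a, PRR, χ² held) is usually still feasible —
three unknowns can match three generic constraints — so oracle
convergence alone does not certify a row; agreement of the re-derived
EBGM/IC/CI with their published values does.

## Time to onset and outcomes

Onset is the calendar-day difference EVENT_DT − START_DT, where
START_DT is the earliest *day-precision* therapy start among the
report's target-drug THER rows. Exclusions are applied in a fixed,
exhaustive order — `missing_date`, `partial_date`, `invalid_date`
(calendar-impossible components such as month 13 are demoted to
missing-equivalent rather than truncated to a coarser precision),
`event_before_start` — and recorded per report, so
n_included + Σ exclusions = cohort size. Same-day onset (0 days) is
valid. Quartiles use linear interpolation (type 7); the histogram bins
are fixed at 0–30 / 31–90 / 91–180 / 181–365 / >365 days and exposed in
config. Serious-outcome proportions divide each outcome code's report
count by the total target-report count; a report with several codes
appears in several rows, so the column may sum past 100%.

The onset unit is per report by default; `tto.per_event` weights each
report by its distinct-PT count instead (the underlying dates are
per-report in DEMO, so the per-event variant only reweights).

## Subgroups and sensitivity

Sex strata (F/M) re-run the whole disproportionality pipeline with both
target and background restricted to the stratum (default
`within_stratum`): comparing a female-only numerator against a mixed
background would conflate drug effects with sex-specific reporting
patterns. The `full_database` scope is available for comparison with
studies that do not restrict the background.

The monotherapy sensitivity analysis keeps only target reports in which
*every* DRUG row matches the target dictionary — dropping reports with
concomitant, interacting, secondary-suspect, or second non-target
primary-suspect medications (the last a fortiori: such a report involves
another suspect drug). The background is left unchanged; purging
polypharmacy reports from the background as well is a defensible
alternative we did not adopt, since the restriction is meant to isolate
the target drug's numerator.

## Synthetic generator

`SynthConfig` defaults encode the study conditions the package is
designed around:

| parameter | default | rationale |
|---|---|---|
| n_cases / n_quarters | 20,000 / 10 (2022Q1–2024Q2) | the study window at desk scale |
| target_share | 0.05 | keeps absolute per-PT target counts (tens) comparable to published rows at 20k cases; the real database fraction (~0.08%) is only meaningful at millions of reports |
| duplicate_version_rate | 0.10 | dedup stress at the rate used in the contract tests |
| events_per_report | NB(mean 4.1, size 3), truncated ≥ 1 | ≈ observed events/report |
| sex / age missingness | 0.7554 / 0.9155 | observed demographic missingness |
| outcome_rates | HO .5322, OT .4763, DE .0888, LT .0572, RI .0026, DS .0023 | observed serious-outcome mix |
| onset | log-normal, median 81 d, σ = 2 | observed median; σ chosen between the values implied by the observed lower (≈2.5) and upper (≈1.5) quartile ratios, as a log-normal cannot match an asymmetric IQR exactly |
| date quality | 40% full / 10% partial / 50% missing event dates; 85% full therapy starts; 2% inverted | yields ≈⅓ of target reports with a usable onset, matching the observed fraction |
| planted_signals | NEPHROLITHIASIS at ρ = 5, vocabulary share ≈ 0.002 | see power analysis below |

PT draws use Gumbel top-k weighted sampling without replacement over a
40-term vocabulary; target reports use rates multiplied by the planted
ρ. Planting at a *small* vocabulary share matters: the per-draw rate
ratio is ρ/(1 + (ρ−1)w) for planted share w, and drawing k terms per
report compresses the report-level ratio further (1−(1−p)^k saturation).
At w ≈ 0.002 and ρ = 5 the combined bias on the recovered ROR is ≈ 1.3%
against a CI half-width of ≈ 35% (a ≈ 40 at default volumes), so
nominal 95% CI coverage is essentially undisturbed — this is why the
100-replicate coverage test can demand ≥ 90/100 honestly. At w ≈ 0.01
the bias would already be a quarter of the CI width.

Randomness: one `default_rng((seed, quarter_index))` stream per quarter.
Identical (config, seed) pairs produce byte-identical directories.
Earlier quarters are unperturbed by later ones as long as per-quarter
volumes are unchanged; since n_cases is split across quarters, *growing*
n_quarters at fixed n_cases does re-split the volumes.

What the generator does **not** emulate: free-text drug-name noise
beyond case/spacing variants, country–reporter joint structure,
MedDRA hierarchy beyond a flat PT→SOC map, reporting-rate drift over
calendar time, and correlated event co-occurrence. Tests passing on
synthetic data therefore certify the bookkeeping and the estimators,
not robustness to real FAERS string dirt.

The deterministic validation fixture plants the published count ratios
directly (402/3040 female, 1618/3040 hospitalised, 270/3040 deaths,
onset bins 342 and 137 of 992) at full target-cohort scale with a
1,000-report background, so the descriptive machinery can be checked for
exact two-decimal, half-up agreement.

## Problem sizes and numerics

Default test volumes: 2,000-case file-backed sets for IO/dedup/pipeline
contracts, 20,000-case in-memory cohorts for estimator and subgroup
behaviour, 100 × 20,000 cases for planted-signal coverage and 200 ×
2,000 for null calibration. Percentages and estimates are rendered
half-up to two decimals in TSVs (Python's `Decimal`; repr-roundtrip
first to avoid binary-float surprises); internal computation is double
precision throughout. Output tables are sorted (PT alphabetical, SOC by
pair count) so reruns are byte-identical.

## Known limitations

- The FDA dedup rule is the only record linkage performed; true
  duplicates with distinct CASEIDs survive it, as they do in practice.
- PT identity is the uppercased verbatim string; no MedDRA code
  resolution or LLT→PT recoding (the PT→SOC map is user-supplied, as
  MedDRA is licensed).
- Printed IC025 values from publications are not reproducible from any
  stated variance and are not validated (see the IC interval note).
- The blocklist mechanism supports, but does not reproduce, the
  clinical judgment of which disease-related PTs to exclude.
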