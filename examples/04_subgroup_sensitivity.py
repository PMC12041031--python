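"""Sex-stratified subgroup and monotherapy sensitivity analyses.

Both re-run the disproportionality pipeline on a restricted dataset:
the subgroup analysis compares each sex stratum against its own
background, and the sensitivity analysis keeps only target reports with
no concomitant medication. With no sex effect planted by the generator,
the stratified RORs should straddle the overall estimate; the
sensitivity ROR should stay close to the primary one while its case
count shrinks.
"""

from faersignal import build_tables, ror_stats, score_tables
from faersignal.strata import sensitivity_exclude_concomitant, subgroup_analysis
from faersignal.synth import SynthConfig, cases_to_reports, generate_cases

cases, manifest = generate_cases(SynthConfig(seed=5))
cohort = cases_to_reports(cases)
pt = "NEPHROLITHIASIS"

overall = {t.pt: t for t in build_tables(cohort)}
ror, lo, hi = ror_stats(overall[pt])
print(f"primary analysis {pt}: a={overall[pt].a:.0f}, "
      f"ROR={ror:.2f} ({lo:.2f}-{hi:.2f})")

for sex in ("F", "M"):
    stats = {s.pt: s for s in subgroup_analysis(cohort, sex)}
    s = stats.get(pt)
    if s is None or s.ror is None:
        print(f"  {sex} stratum: too few reports for an estimate")
        continue
    slo, shi = s.ror_ci95
    print(f"  {sex} stratum: a={s.a}, ROR={s.ror:.2f} ({slo:.2f}-{shi:.2f})")

sens = sensitivity_exclude_concomitant(cohort)
sens_stats = {s.pt: s for s in score_tables(build_tables(sens))}
s = sens_stats[pt]
slo, shi = s.ror_ci95
print(f"monotherapy sensitivity: target reports "
      f"{len(cohort.target_reports)} -> {len(sens.target_reports)}; "
      f"{pt} a={s.a}, ROR={s.ror:.2f} ({slo:.2f}-{shi:.2f})")
print("a stable ROR under the monotherapy restriction argues the signal "
      "is not driven by co-medication.")
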