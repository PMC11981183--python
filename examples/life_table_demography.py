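"""Build a cohort life table and estimate population growth parameters.

Simulates one development cohort and one fecundity assay at 25 °C with
the default generator settings, builds the age-specific lx/mx schedule,
and computes the Birch demographic parameters with bootstrap standard
errors (B kept modest here; raise it for publication-grade SEs).
"""

from thermolife import (
    GeneratorConfig,
    bootstrap_params,
    build_schedule,
    demographic_params,
    preoviposition_time,
    simulate_cohort,
    simulate_fecundity,
)

config = GeneratorConfig()
cohort = simulate_cohort(config, 25.0, seed=1)
fecundity = simulate_fecundity(config, 25.0, seed=2)

schedule = build_schedule(cohort, fecundity, sex_ratio=config.sex_ratio)
params = demographic_params(schedule)
pre = preoviposition_time(fecundity)

print(f"cohort: {len(cohort)} individuals, "
      f"{sum(r.reached_adult for r in cohort)} reached adulthood")
print(f"pre-reproduction lag: {pre.mean_days:.1f} ± {pre.se_days:.1f} d (n={pre.n})")
print(f"R0      = {params.R0:6.2f}  female offspring per female")
print(f"rm      = {params.rm:6.4f} /day  (Euler-Lotka root)")
print(f"T       = {params.T_gen:6.2f} d   (ln R0 / rm; cohort T = {params.T_cohort:.2f} d)")
print(f"DT      = {params.DT:6.2f} d   (population doubling time)")
print(f"lambda  = {params.lambda_finite:6.4f} /day (finite rate of increase)")

summaries = bootstrap_params(cohort, fecundity, config.sex_ratio, B=10_000, seed=3)
print("\nbootstrap (B=10,000, females resampled with replacement):")
for name, s in summaries.items():
    print(f"  {name:13s} {s.point_estimate:8.4f}  SE {s.se:7.4f}  "
          f"95% CI [{s.ci_low:.4f}, {s.ci_high:.4f}]")

print(
    "\nR0 > 1 and rm > 0 mean the cohort more than replaces itself; lambda"
    "\nis the daily multiplication factor and DT the days to double."
)
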