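"""Compare survival curves between temperatures with Kaplan-Meier + log-rank.

Simulates cohorts at three temperatures, estimates each group's survival
function from hatching to death, runs all pairwise log-rank tests, and
prints the compact letter display (groups sharing a letter have curves
that are not significantly different at alpha = 0.05).
"""

from thermolife import GeneratorConfig, km_fit, letter_groups, pairwise_log_rank, simulate_cohort
from thermolife.survival import survival_times_from_records

config = GeneratorConfig()
groups = {}
for temp in (15.0, 25.0, 30.0):
    records = simulate_cohort(config, temp, seed=11, include_egg_stage=False)
    groups[f"{temp:g} °C"] = survival_times_from_records(records)

for label, (times, events) in groups.items():
    curve = km_fit(times, events, label=label)
    print(f"{label}: n = {times.size}, median-ish S(30 d) = {curve.survival_at(30):.2f}, "
          f"mean survival = {curve.mean_survival():.1f} d")

pmat = pairwise_log_rank(groups)
print("\npairwise log-rank p-values:")
print(pmat.round(4).to_string())
letters = letter_groups(pmat, alpha=0.05)
print("\nletter display:", letters)
print(
    "\nWarmer cohorts die sooner; distinct letters mark temperature pairs"
    "\nwhose survival curves the log-rank test separates at p < 0.05."
)
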