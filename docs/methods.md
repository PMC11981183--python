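# Methods

## Scope and data model

The package analyses constant-temperature life-history bioassays of an
insect followed under a daily (24 h) census: a development table with one
row per individual (stage-by-stage durations for the egg and five nymphal
instars, fate, sex, adult lifespan) and a fecundity table with one row
per female per adult-age day (emerged nymphs attributed to that day).
Durations are whole days ≥ 1; stage presence must be a contiguous run
(an individual cannot have completed instar 3 without instar 2); sex is
only recorded for adults. Individuals alive at study end may be marked
censored: they are excluded from longevity means but retained in
Kaplan-Meier curves. Offspring are counted as *emerged nymphs* rather
than eggs, the standard fertility proxy for mirids whose eggs are laid
inside plant tissue and cannot be counted reliably.

## Thermal performance curves

Development rates are the reciprocal of the per-temperature **mean**
duration (not the mean of individual reciprocals): rate summaries in
results tables are means of durations, and the degree-day parameters of
interest are defined on that scale. Fits are unweighted least squares on
the rate points; per-temperature sample sizes are carried for reporting
but not used as weights.

* **Linear degree-day model** `r = a + bT`, fitted by ordinary least
  squares. Thermal constant `K = 1/b` (degree-days), lower threshold
  `t_min = −a/b`. The linear model is only meaningful over the range
  where the response is near-linear, so temperatures beyond the observed
  rate plateau are excluded; the egg series keeps 32.5 °C (eggs still
  hatch there) while nymph and total series stop at 30 °C.
* **Brière-1** `r = a·T·(T − t_min)·√(t_max − T)` on `[t_min, t_max]`,
  zero outside. Its optimum has the closed form
  `t_opt = [4 t_max + 3 t_min + √(16 t_max² + 9 t_min² − 16 t_min t_max)]/10`,
  used as a cross-check of the numerical maximization.
* **Lactin-2** `r = e^{ρT} − e^{ρ t_max_param − (t_max_param − T)/Δ} + λ`.
  Thresholds are derived numerically: `t_opt` by bounded scalar
  maximization, `t_min`/`t_max` by bisection (tolerance 1e-6 °C) on the
  sign changes below and above the optimum.

**Zero-rate anchoring of Lactin-2.** With only five viable temperatures a
four-parameter curve is underdetermined on its upper limb: the
least-squares surface develops a near-flat valley in which the descending
branch collapses just above the warmest viable point. The package's
convention is to include the *first temperature at which development
fails* as an observed rate of zero (32.5 °C for nymphal and total
development, 35 °C for eggs — the failure temperature is a real
experimental observation, not a missing value). This anchors the upper
limb, yields stable and biologically interpretable thresholds, and
reproduces published threshold estimates for this species to within a
few hundredths of a degree. The linear and Brière-1 fits never include
failure temperatures (a zero rate has no meaning in the linear model and
distorts Brière-1's polynomial limb).

**Multi-start fitting.** Nonlinear fits run Levenberg-Marquardt least
squares from a fixed grid of starts (Lactin-2: ρ ∈ {0.05, 0.1, 0.15,
0.2} × t_max_param ∈ {32, 35, 38, 41} × Δ ∈ {2, 5, 8} × λ ∈ {−1.5, −1,
−0.5, 0}; Brière-1: a ∈ {1e-5, 5e-5, 1e-4} × t_min ∈ {0, 5, 10} ×
t_max ∈ {33, 36, 40}), covering the plausible range for temperate
insects. The converged start with the lowest RSS wins; ties keep the
earlier grid position. No randomness enters, so fits are bit-reproducible.

**Model comparison.** AIC is computed as `n·ln(RSS/n) + 2k` with `k` the
number of fitted parameters; the Gaussian constant terms are identical
across models on the same points and are dropped, so only AIC
*differences* are meaningful. R² for nonlinear models is `1 − RSS/TSS`.

## Life table and demographic parameters

Ages `x` count days from egg deposition. The immature segment of `l_x`
is the empirical fraction of the development cohort not yet dead at age
`x`; the adult segment is the proportion surviving to adulthood times
the adult female survival curve from the fecundity assay. Adult-age days
are offset to cohort age by the cohort's mean immature (egg + nymph)
duration rounded to whole days; the offset is configurable for assays
with a different time origin. `m_x` is the mean emerged nymphs per
*living* female on each adult-age day multiplied by the cohort sex
ratio, so `R₀ = Σ l_x m_x` is female offspring per newborn female. With
no immature mortality this reduces exactly to sex ratio × mean lifetime
offspring, which is the identity the bootstrap tests exploit.

`r_m` is the unique root of the strictly decreasing map
`r ↦ Σ e^{−r x} l_x m_x` on `[−1, 2]`, found by Brent's method to a
residual below 1e-10. Generation time is reported under both conventions
— `T = ln R₀ / r_m` (primary) and the cohort definition
`Σ x l_x m_x / R₀` — because published tables in this field are not
always internally consistent between them (e.g. printed doubling times
that do not equal `ln 2 /` printed `r_m`, presumably computed from
unrounded bootstrap means). `DT` and `λ` are always computed from the
package's own `r_m`, so the identities `λ = e^{r_m}`, `DT = ln 2 / r_m`
hold to machine precision.

**Bootstrap.** The resampling unit is the female: each replicate redraws
females with replacement (multinomial weights, distributionally identical
to index resampling), with the immature cohort resampled as an
independent stratum (it informs immature survival and the age offset).
All five parameters are recomputed per replicate; SE is the SD of
replicates and CIs are 2.5/97.5 percentiles. The default is B = 100,000
replications, matching standard practice for these SEs; tests and
examples use B = 10,000, which this vectorized implementation (batched
multinomial weights + 64-step vectorized bisection for the Euler-Lotka
root) completes in about a second. Paired bootstrap tests resample both
groups independently on shared replicate indices; the two-sided p-value
is `2·min(P(diff ≤ 0), P(diff ≥ 0))`, floored at `1/B`. Pairwise tests
are unadjusted by default (a Bonferroni flag exists on the pairwise
log-rank matrix), mirroring the plain letter displays of life-history
tables.

## Survival analysis

Kaplan-Meier estimation and log-rank tests are delegated to lifelines;
deaths are processed before censorings tied on the same day (the
standard convention). Survival time origin is hatching for
nymph-inclusive curves or adult emergence for longevity-only curves.
The compact letter display is a clique cover: groups are nodes, an edge
joins pairs not significantly different at α, and each *maximal clique*
receives one letter, so two curves share a letter iff the log-rank test
does not separate them. Greenwood-variance confidence bands are
available through lifelines but are not part of the reported tables.

## Synthetic-cohort generator

The generator emulates the bioassay design: gamma-distributed stage
durations (CV 0.10 by default) around linear degree-day means
(K_egg = 230 DD above 6.1 °C, K_nymph = 394 DD above 4.7 °C, split
across instars in the observed proportions), integer-rounded with a
1-day minimum (daily census); Bernoulli stage survival with
per-temperature totals shaped like observed cohorts (low mortality at
15–20 °C, ≈25–50% at 25–30 °C, total failure at ≥32.5 °C); Bernoulli
sex at ratio 0.5; gamma adult lifespans (CV 0.6) with per-temperature
means of 158.6 → 13.8 days from 15 → 30 °C; and Poisson daily fecundity
with a gamma pre-reproductive lag (17.3 d at 20 °C, 8.6 d at 25 °C),
initial rates of 2.1 and 3.7 nymphs/day and exponential senescence at
0.01/day. At lethally hot temperatures a fixed low per-stage survival
(0.3) lets intermediate instars occur while no individual emerges,
mirroring the observed pattern of partial development at 32.5 °C. Death
within a stage occurs on a uniformly chosen day of that stage. Unhatched
eggs are emitted as censored records with no durations: a hatching
census cannot date an egg's death.

Duration dispersions are conventions (only SEs of stage means are
published, not individual-level spreads), and hosts are pass-through
labels with no mechanistic effect, so passing recovery tests shows the
pipeline is consistent with its own assumptions — not that real cohorts
meet them. Analytic expectations (total development time; lifetime
offspring integrated over the integer-rounded lag and lifespan
distributions) are exposed for tests. Demographic truth for recovery
experiments is defined as the generator's large-sample limit (a one-off
cohort of 20,000 individuals and 2,000 females), which treats
day-discretization identically to the analysis under test.

**Problem sizes.** The packaged recovery experiment uses 50 seeds with
50 individuals per temperature and bootstrap B = 10,000 at 25 °C — large
enough for stable coverage statistics while keeping a full run
desk-scale (about a minute). These sizes, like all generator defaults,
are fixed study conditions, not tuning knobs.

## Known limitations

* The linear-model temperature window is a judgment call near the rate
  plateau; the inclusion sets are explicit arguments and logged.
* Lactin-2 parameters (not just thresholds) are only weakly identified
  from 5–7 rate points; parameter-level checks rely on self-consistency
  on noiseless data.
* The life table assumes immature survival is sex-independent and takes
  adult survival from the female assay; no two-sex or stage-structured
  model is attempted.
* Bootstrap resampling at the female level treats each female's
  trajectory as exchangeable; day-level dependence within a female is
  preserved, but assay-level effects (cage, plant) are not modelled.
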