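"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a constant-temperature life-history bioassay for a
temperate zoophytophagous mirid under a 24 h census:

* stage durations are gamma-distributed around a linear degree-day thermal
  response (mean ``K_stage / (T − t_min_stage)``), rounded to whole days;
* stage-wise mortality rises toward the thermal extremes, with complete
  developmental failure above the viable range;
* sex is Bernoulli with a configurable cohort sex ratio;
* adult lifespan is right-skewed (gamma) with a temperature-dependent mean;
* each female's daily offspring counts are Poisson around a plateau-decay
  schedule: zero before a gamma-distributed pre-reproductive lag, then an
  initial daily rate decaying exponentially with age (senescence),
  truncated at her death.

Default magnitudes follow published life-history summaries for *Dicyphus
cerastii* on tomato (development times, mortality, longevity, lag and
daily fertility by temperature); dispersion parameters are conventions,
since only standard errors of means are published. Everything is
reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .records import CohortRecord, FecundityObservation
from .thermal import fit_linear, make_rate_points
from .lifetable import build_schedule, demographic_params, bootstrap_params

__all__ = [
    "GeneratorConfig",
    "simulate_cohort",
    "simulate_fecundity",
    "recovery_experiment",
    "large_sample_truth",
    "expected_total_duration",
    "expected_lifetime_offspring",
]

#: Share of the total nymphal thermal constant spent in each instar
#: (proportions of the five instar means at an intermediate temperature).
_INSTAR_FRACTIONS = (0.205, 0.140, 0.150, 0.180, 0.325)


@dataclass(frozen=True)
class GeneratorConfig:
    """Truth parameters for the synthetic bioassay.

    Thermal truth is a linear degree-day response per stage group; the
    per-temperature dictionaries carry the observed-magnitude defaults.
    ``duration_cv`` is the coefficient of variation of individual stage
    durations around their thermal mean (unpublished in summary tables; a
    CV of 0.10 is typical of insect development under constant
    temperature). Lifespans use a gamma with CV 0.6 (right-skewed).
    """

    temperatures: tuple[float, ...] = (15.0, 20.0, 25.0, 27.5, 30.0, 32.5, 35.0)
    k_egg: float = 230.0
    t_min_egg: float = 6.1
    k_nymph: float = 394.0
    t_min_nymph: float = 4.7
    instar_fractions: tuple[float, ...] = _INSTAR_FRACTIONS
    duration_cv: float = 0.10
    #: probability an egg fails to hatch, by temperature (default: hatch
    #: everywhere viable, total failure at 35 °C)
    egg_mortality: dict[float, float] = field(
        default_factory=lambda: {35.0: 1.0}
    )
    #: total nymphal mortality by temperature (shaped like observed
    #: cohorts: low at 15–20 °C, ≈0.25–0.5 at 25–30 °C, total at ≥32.5 °C)
    nymph_mortality: dict[float, float] = field(
        default_factory=lambda: {
            15.0: 0.12,
            20.0: 0.077,
            25.0: 0.327,
            27.5: 0.25,
            30.0: 0.519,
            32.5: 1.0,
            35.0: 1.0,
        }
    )
    #: per-stage survival used at lethally hot temperatures where total
    #: mortality is 1: intermediate instars still occur, no adult emerges
    lethal_stage_survival: float = 0.3
    sex_ratio: float = 0.5
    adult_lifespan_mean: dict[float, float] = field(
        default_factory=lambda: {15.0: 158.6, 20.0: 70.9, 25.0: 35.7, 27.5: 12.4, 30.0: 13.8}
    )
    lifespan_cv: float = 0.6
    #: reproductive-assay female lifespan means (females kept with males on
    #: whole plants live longer than the development-assay adults)
    reproductive_lifespan_mean: dict[float, float] = field(
        default_factory=lambda: {20.0: 87.8, 25.0: 41.6, 30.0: 20.0}
    )
    preoviposition_mean: dict[float, float] = field(
        default_factory=lambda: {20.0: 17.3, 25.0: 8.6, 30.0: 10.0}
    )
    preoviposition_cv: float = 0.25
    #: initial daily offspring rate (emerged nymphs per female per day)
    fecundity_rate: dict[float, float] = field(
        default_factory=lambda: {20.0: 2.1, 25.0: 3.7, 30.0: 0.01}
    )
    #: exponential senescence of the daily rate, per day of reproductive age
    senescence_rate: float = 0.01
    n_per_temperature: int = 55
    n_females: int = 20
    host: str = "tomato"
    prey: bool = True

    def stage_mean_days(self, stage: str, temperature_c: float) -> Optional[float]:
        """Expected continuous duration of a stage; None below its threshold."""
        if stage == "egg":
            k, tmin = self.k_egg, self.t_min_egg
        elif stage.startswith("n"):
            idx = int(stage[1]) - 1
            if temperature_c <= self.t_min_nymph:
                return None
            return self.instar_fractions[idx] * self.k_nymph / (temperature_c - self.t_min_nymph)
        else:
            raise ValueError(f"unknown stage {stage!r}")
        if temperature_c <= tmin:
            return None
        return k / (temperature_c - tmin)


def _gamma_days(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Integer-rounded gamma draw(s) with the given mean and CV, min 1 day."""
    if cv <= 0:
        vals = np.full(size if size is not None else (), mean)
    else:
        shape = 1.0 / cv**2
        vals = rng.gamma(shape=shape, scale=mean / shape, size=size)
    return np.maximum(1, np.rint(vals).astype(int))


def simulate_cohort(
    config: GeneratorConfig,
    temperature_c: float,
    seed: int,
    n: Optional[int] = None,
    include_egg_stage: bool = True,
) -> list[CohortRecord]:
    """Simulate one development cohort at a constant temperature.

    Records start at egg deposition (``include_egg_stage``) or at first
    instar. Individuals that die do so within the stage they failed to
    complete, at a uniformly chosen day of that stage; their ``death_day``
    is recorded and the failed stage's duration is absent, mirroring a
    daily census. Fully reproducible from ``seed``.
    """
    if temperature_c not in config.temperatures:
        raise ValueError(f"temperature {temperature_c} not in config.temperatures")
    rng = np.random.default_rng(seed)
    n = config.n_per_temperature if n is None else n
    total_mort = config.nymph_mortality.get(temperature_c, 0.0)
    if total_mort >= 1.0:
        stage_survival = config.lethal_stage_survival
        lethal = True
    else:
        stage_survival = (1.0 - total_mort) ** (1.0 / 5.0)
        lethal = False
    egg_mort = config.egg_mortality.get(temperature_c, 0.0)

    records = []
    for i in range(n):
        durations: dict[str, int] = {}
        age = 0
        dead_at: Optional[int] = None
        alive = True

        if include_egg_stage:
            mean = config.stage_mean_days("egg", temperature_c)
            if mean is None or rng.random() < egg_mort:
                # egg never hatches; the death day of an unhatched egg is
                # not observable in a hatching census — record no duration
                records.append(
                    CohortRecord(
                        individual_id=f"t{temperature_c:g}-{i}",
                        temperature_c=temperature_c,
                        host=config.host,
                        prey=config.prey,
                        stage_durations={},
                        reached_adult=False,
                        censored=True,
                    )
                )
                continue
            d = int(_gamma_days(rng, mean, config.duration_cv))
            durations["egg"] = d
            age += d

        for stage in ("n1", "n2", "n3", "n4", "n5"):
            mean = config.stage_mean_days(stage, temperature_c)
            if mean is None:
                dead_at = age + 1
                alive = False
                break
            d = int(_gamma_days(rng, mean, config.duration_cv))
            if rng.random() < 1.0 - stage_survival:
                dead_at = age + int(rng.integers(1, d + 1))
                alive = False
                break
            durations[stage] = d
            age += d
        else:
            if lethal:  # completed n5 at a lethal temperature: dies molting
                durations.pop("n5", None)
                dead_at = age
                alive = False

        if alive:
            sex = "female" if rng.random() < config.sex_ratio else "male"
            lifespan = int(
                _gamma_days(
                    rng, config.adult_lifespan_mean.get(temperature_c, 10.0), config.lifespan_cv
                )
            )
            records.append(
                CohortRecord(
                    individual_id=f"t{temperature_c:g}-{i}",
                    temperature_c=temperature_c,
                    host=config.host,
                    prey=config.prey,
                    stage_durations=durations,
                    reached_adult=True,
                    sex=sex,
                    adult_lifespan_days=lifespan,
                    death_day=age + lifespan,
                )
            )
        else:
            records.append(
                CohortRecord(
                    individual_id=f"t{temperature_c:g}-{i}",
                    temperature_c=temperature_c,
                    host=config.host,
                    prey=config.prey,
                    stage_durations=durations,
                    reached_adult=False,
                    death_day=dead_at,
                )
            )
    for r in records:
        r.validate()
    return records


def simulate_fecundity(
    config: GeneratorConfig,
    temperature_c: float,
    n_females: Optional[int] = None,
    seed: int = 0,
) -> list[FecundityObservation]:
    """Simulate a reproduction assay: daily emerged-nymph counts per female.

    One observation per female per adult-age day from day 1 until her
    death, zeros included, so the female's lifespan is recoverable from
    her trajectory.
    """
    rng = np.random.default_rng(seed)
    n_females = config.n_females if n_females is None else n_females
    if n_females < 1:
        raise ValueError("n_females must be >= 1")
    rate = config.fecundity_rate.get(temperature_c, 0.0)
    lag_mean = config.preoviposition_mean.get(temperature_c, 10.0)
    life_mean = config.reproductive_lifespan_mean.get(
        temperature_c, config.adult_lifespan_mean.get(temperature_c, 20.0)
    )
    observations = []
    for i in range(n_females):
        lag = int(_gamma_days(rng, lag_mean, config.preoviposition_cv))
        lifespan = int(_gamma_days(rng, life_mean, config.lifespan_cv))
        for day in range(1, lifespan + 1):
            if day >= lag and rate > 0:
                mu = rate * math.exp(-config.senescence_rate * (day - lag))
                count = int(rng.poisson(mu))
            else:
                count = 0
            observations.append(
                FecundityObservation(
                    female_id=f"f{temperature_c:g}-{i}",
                    temperature_c=temperature_c,
                    adult_age_day=day,
                    nymphs_emerged=count,
                )
            )
    return observations


# ---------------------------------------------------------------------------
# Analytic expectations (generator truth)
# ---------------------------------------------------------------------------


def expected_total_duration(config: GeneratorConfig, temperature_c: float) -> float:
    """Expected continuous egg + nymph development time at a temperature."""
    egg = config.stage_mean_days("egg", temperature_c)
    if egg is None or temperature_c <= config.t_min_nymph:
        raise ValueError(f"no development at {temperature_c} °C under this config")
    nymph = config.k_nymph / (temperature_c - config.t_min_nymph)
    return egg + nymph


def expected_lifetime_offspring(
    config: GeneratorConfig, temperature_c: float, max_days: int = 2000
) -> float:
    """Expected lifetime emerged nymphs per female under the generator.

    Computed by numerically integrating the plateau-decay fertility
    schedule over the integer-rounded gamma distributions of the
    pre-reproductive lag and the reproductive lifespan (the same rounding
    the simulator applies), so it is the exact mean of the simulated
    lifetime totals up to truncation at ``max_days``.
    """
    from scipy import stats as sps

    rate = config.fecundity_rate.get(temperature_c, 0.0)
    if rate == 0.0:
        return 0.0
    lag_mean = config.preoviposition_mean.get(temperature_c, 10.0)
    life_mean = config.reproductive_lifespan_mean.get(
        temperature_c, config.adult_lifespan_mean.get(temperature_c, 20.0)
    )

    def int_pmf(mean, cv):
        shape = 1.0 / cv**2
        dist = sps.gamma(a=shape, scale=mean / shape)
        ks = np.arange(1, max_days + 1)
        # P(round(X) = k) with the min-1 clamp folding mass below 1.5 into k=1
        upper = dist.cdf(ks + 0.5)
        lower = dist.cdf(ks - 0.5)
        pmf = upper - lower
        pmf[0] = dist.cdf(1.5)
        return pmf / pmf.sum()

    lag_pmf = int_pmf(lag_mean, config.preoviposition_cv)
    life_pmf = int_pmf(life_mean, config.lifespan_cv)
    days = np.arange(1, max_days + 1)
    life_sf = 1.0 - np.cumsum(life_pmf) + life_pmf  # P(lifespan >= day)
    s = config.senescence_rate
    # E[total] = Σ_day P(alive) · rate · E[e^{−s(day−lag)} 1{day ≥ lag}]
    total = 0.0
    decay_by_lag = np.exp(-s * np.arange(max_days))  # index: day − lag
    for lag_idx, p_lag in enumerate(lag_pmf):
        if p_lag < 1e-12:
            continue
        lag = lag_idx + 1
        contrib = life_sf[lag - 1 :] * rate * decay_by_lag[: max_days - lag + 1]
        total += p_lag * contrib.sum()
    return float(total)


def large_sample_truth(
    config: GeneratorConfig,
    temperature_c: float,
    seed: int = 0,
    n_cohort: int = 20_000,
    n_females: int = 2_000,
):
    """Demographic-parameter truth as the generator's large-sample limit.

    Simulates one very large cohort and fecundity assay and runs the life
    table on them; sampling error at these sizes is negligible relative to
    the uncertainty of a realistic assay, and all day-discretization
    effects are treated identically to the analysis under test.
    """
    cohort = simulate_cohort(config, temperature_c, seed=seed, n=n_cohort)
    fecundity = simulate_fecundity(config, temperature_c, n_females=n_females, seed=seed + 1)
    schedule = build_schedule(cohort, fecundity, sex_ratio=config.sex_ratio)
    return demographic_params(schedule)


# ---------------------------------------------------------------------------
# Parameter-recovery experiment
# ---------------------------------------------------------------------------


def recovery_experiment(
    config: GeneratorConfig,
    seeds: Sequence[int],
    n_per_temperature: int = 50,
    demography_temperature: float = 25.0,
    bootstrap_B: int = 10_000,
    truth=None,
):
    """Estimate − truth errors of the full pipeline over seeded replicates.

    For each seed: simulate cohorts at the linear-range temperatures,
    recover the nymphal degree-day parameters (K, t_min) from the
    empirical per-temperature mean durations, and run the life table plus
    bootstrap at ``demography_temperature``, recording whether the
    recovered ``rm`` falls within two bootstrap SEs of the generator truth.

    Returns a dict with per-seed errors, bias/RMSE per parameter and the
    rm coverage fraction. ``truth`` (a :class:`DemographicParams`) may be
    passed to reuse a precomputed large-sample truth.
    """
    if len(seeds) < 10:
        raise ValueError("recovery_experiment needs at least 10 seeds")
    fit_temps = [t for t in (15.0, 20.0, 25.0, 27.5, 30.0) if t in config.temperatures]
    if truth is None:
        truth = large_sample_truth(config, demography_temperature)
    tmin_errors, k_errors, rm_errors, rm_covered = [], [], [], []
    for seed in seeds:
        means = {}
        for j, t in enumerate(fit_temps):
            cohort = simulate_cohort(
                config, t, seed=seed * 1009 + j, n=n_per_temperature, include_egg_stage=False
            )
            durs = [
                sum(r.stage_durations[s] for s in ("n1", "n2", "n3", "n4", "n5"))
                for r in cohort
                if r.reached_adult
            ]
            if durs:
                means[t] = sum(durs) / len(durs)
        fit = fit_linear(make_rate_points(means))
        tmin_errors.append(fit.t_min_c - config.t_min_nymph)
        k_errors.append(fit.K_degree_days - config.k_nymph)

        cohort = simulate_cohort(
            config, demography_temperature, seed=seed * 1009 + 101, n=n_per_temperature
        )
        fecundity = simulate_fecundity(
            config, demography_temperature, n_females=config.n_females, seed=seed * 1009 + 202
        )
        summaries = bootstrap_params(
            cohort, fecundity, sex_ratio=config.sex_ratio, B=bootstrap_B, seed=seed
        )
        rm_hat = summaries["rm"].point_estimate
        rm_se = summaries["rm"].se
        rm_errors.append(rm_hat - truth.rm)
        rm_covered.append(abs(rm_hat - truth.rm) <= 2.0 * rm_se)

    def _stats(errors):
        arr = np.asarray(errors)
        return {
            "bias": float(arr.mean()),
            "rmse": float(np.sqrt(np.mean(arr**2))),
            "median_abs_error": float(np.median(np.abs(arr))),
        }

    return {
        "n_seeds": len(seeds),
        "t_min": _stats(tmin_errors) | {"errors": list(map(float, tmin_errors))},
        "K": _stats(k_errors) | {"errors": list(map(float, k_errors))},
        "rm": _stats(rm_errors) | {"errors": list(map(float, rm_errors))},
        "rm_within_2se_fraction": float(np.mean(rm_covered)),
        "truth_rm": truth.rm,
    }
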