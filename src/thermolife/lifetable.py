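"""Cohort life tables and Birch demographic parameters.

Combines a development cohort (immature survival) with a female fecundity
assay (age-specific offspring production) into an age-indexed schedule of

* ``lx`` — proportion of the initial cohort alive at age ``x`` days from
  egg deposition,
* ``mx`` — female offspring per female per day at age ``x`` (emerged
  nymphs per living female × cohort sex ratio),

and derives the classic demographic parameters:

* net reproductive rate ``R0 = Σ lx·mx`` (female offspring per female),
* intrinsic rate of increase ``rm`` solving the Euler-Lotka equation
  ``Σ exp(−rm·x)·lx·mx = 1`` by bracketed root finding,
* generation time ``T = ln(R0)/rm`` (with the cohort definition
  ``Σ x·lx·mx / R0`` also reported),
* doubling time ``DT = ln 2 / rm`` and finite rate ``λ = exp(rm)``.

Uncertainty comes from a nonparametric bootstrap resampling females (each
female carries her whole survival + fecundity trajectory) with the
immature cohort resampled as an independent stratum; temperatures are
compared with paired bootstrap tests on shared replicate indices. The
bootstrap is vectorized: resampling weights are drawn as multinomial
counts, and the Euler-Lotka equation is solved for all replicates at once
by monotone bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .records import (
    NYMPHAL_STAGES,
    STAGES,
    CohortRecord,
    FecundityObservation,
)

__all__ = [
    "LifeSchedule",
    "DemographicParams",
    "BootstrapSummary",
    "PairedBootstrapTest",
    "PreovipositionSummary",
    "build_schedule",
    "demographic_params",
    "euler_lotka_solve",
    "bootstrap_params",
    "paired_bootstrap_test",
    "preoviposition_time",
    "DegenerateScheduleError",
]

PARAMETER_NAMES = ("R0", "T_gen", "rm", "DT", "lambda_finite")

_EULER_BRACKET = (-1.0, 2.0)
_EULER_TOL = 1e-12


class DegenerateScheduleError(ValueError):
    """The schedule has no reproduction (R0 = 0); growth rates are undefined."""


@dataclass(frozen=True)
class LifeSchedule:
    """Age-indexed lx/mx schedule; ``age_days[0]`` is age 0 (egg deposition)."""

    age_days: np.ndarray
    lx: np.ndarray
    mx: np.ndarray

    def __post_init__(self):
        if not (len(self.age_days) == len(self.lx) == len(self.mx)):
            raise ValueError("age_days, lx and mx must have equal length")
        if np.any(self.lx < -1e-12) or np.any(self.lx > 1 + 1e-12):
            raise ValueError("lx must lie in [0, 1]")
        if np.any(np.diff(self.lx) > 1e-12):
            raise ValueError("lx must be non-increasing")
        if np.any(self.mx < 0):
            raise ValueError("mx must be non-negative")

    @property
    def lxmx(self) -> np.ndarray:
        return self.lx * self.mx

    @property
    def R0(self) -> float:
        return float(np.sum(self.lxmx))


@dataclass(frozen=True)
class DemographicParams:
    R0: float
    T_gen: float  # ln(R0)/rm, the Birch definition
    T_cohort: float  # Σ x·lx·mx / R0
    rm: float
    DT: float
    lambda_finite: float


@dataclass(frozen=True)
class BootstrapSummary:
    point_estimate: float
    se: float
    ci_low: float
    ci_high: float
    B: int
    seed: int


@dataclass(frozen=True)
class PairedBootstrapTest:
    parameter: str
    estimate_diff: float  # group A − group B point estimates
    p_value: float
    B: int
    seed: int


@dataclass(frozen=True)
class PreovipositionSummary:
    mean_days: float
    se_days: float
    n: int
    n_excluded: int  # females with zero lifetime offspring


# ---------------------------------------------------------------------------
# Schedule construction
# ---------------------------------------------------------------------------


def _immature_offset(cohort: Sequence[CohortRecord]) -> int:
    """Mean egg + nymphal duration among completers, rounded to whole days."""
    totals = []
    for r in cohort:
        if r.reached_adult:
            dur = sum(r.stage_durations.values())
            totals.append(dur)
    if not totals:
        raise DegenerateScheduleError("no individual completed immature development")
    return int(round(sum(totals) / len(totals)))


def _immature_survival(cohort: Sequence[CohortRecord]) -> float:
    return sum(r.reached_adult for r in cohort) / len(cohort)


def _female_arrays(
    fecundity: Sequence[FecundityObservation],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-female (counts, alive) matrices over adult-age days 1..A.

    A female is alive on every day up to her last observation day (the
    assay follows females daily until death).
    """
    females: dict[str, dict[int, int]] = {}
    for obs in fecundity:
        females.setdefault(obs.female_id, {})[obs.adult_age_day] = (
            females.get(obs.female_id, {}).get(obs.adult_age_day, 0) + obs.nymphs_emerged
        )
    ids = sorted(females)
    A = max((max(days) for days in females.values()), default=0)
    counts = np.zeros((len(ids), A), dtype=float)
    alive = np.zeros((len(ids), A), dtype=float)
    for i, fid in enumerate(ids):
        days = females[fid]
        last = max(days)
        alive[i, :last] = 1.0
        for day, c in days.items():
            counts[i, day - 1] = c
    return counts, alive, ids


def build_schedule(
    cohort: Sequence[CohortRecord],
    fecundity: Sequence[FecundityObservation],
    sex_ratio: float,
    age_offset_days: Optional[int] = None,
) -> LifeSchedule:
    """Age-specific lx/mx schedule from egg deposition.

    ``lx`` combines immature survival (from the development cohort) with
    adult female survival (from the fecundity assay); ``mx`` is the mean
    number of emerged nymphs per *living* female on each adult-age day,
    multiplied by ``sex_ratio`` to express female offspring. Adult-age days
    are offset to cohort age by ``age_offset_days``, defaulting to the
    cohort's mean immature (egg + nymph) duration rounded to whole days.

    An empty fecundity assay yields a schedule with ``R0 = 0``.
    """
    if not 0.0 <= sex_ratio <= 1.0:
        raise ValueError("sex_ratio must lie in [0, 1]")
    if not cohort:
        raise ValueError("cohort must be non-empty")
    offset = _immature_offset(cohort) if age_offset_days is None else int(age_offset_days)

    # immature part of lx: fraction of the cohort not yet dead at age x
    n = len(cohort)
    imm_death_ages = []
    for r in cohort:
        if not r.reached_adult and not r.censored and r.death_day is not None:
            imm_death_ages.append(r.death_day)
    p_adult = _immature_survival(cohort)

    if fecundity:
        counts, alive, _ = _female_arrays(fecundity)
        n_alive = alive.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx_adult = np.where(n_alive > 0, counts.sum(axis=0) / np.maximum(n_alive, 1), 0.0)
        mx_adult = mx_adult * sex_ratio
        surv_adult = n_alive / alive.shape[0]
        A = counts.shape[1]
    else:
        mx_adult = np.zeros(0)
        surv_adult = np.zeros(0)
        A = 0

    ages = np.arange(0, offset + A + 1)
    lx = np.empty_like(ages, dtype=float)
    death_ages = np.asarray(imm_death_ages, dtype=float)
    for x in range(offset + 1):
        # alive at age x: reached adulthood eventually, or died later than x
        lx[x] = (n - np.sum(death_ages <= x)) / n
    for a in range(1, A + 1):
        lx[offset + a] = p_adult * surv_adult[a - 1]
    # guard against tiny non-monotonicity at the immature/adult seam caused
    # by the two assays estimating survival on different cohorts
    lx = np.minimum.accumulate(lx)
    mx = np.zeros_like(lx)
    if A:
        mx[offset + 1 :] = mx_adult
    return LifeSchedule(age_days=ages, lx=lx, mx=mx)


# ---------------------------------------------------------------------------
# Demographic parameters
# ---------------------------------------------------------------------------


def euler_lotka_solve(schedule: LifeSchedule) -> float:
    """Intrinsic rate of increase: the root of Σ e^{−r·x}·lx·mx = 1.

    The map is strictly decreasing in r wherever reproduction occurs, so
    the root on the bracket [−1, 2] is unique. The returned root has
    |residual| < 1e-10.
    """
    phi = schedule.lxmx
    x = schedule.age_days.astype(float)
    if schedule.R0 <= 0:
        raise DegenerateScheduleError("R0 = 0: the Euler-Lotka equation has no root")

    def f(r):
        return np.sum(np.exp(-r * x) * phi) - 1.0

    lo, hi = _EULER_BRACKET
    if f(lo) < 0 or f(hi) > 0:
        raise RuntimeError(f"no sign change for Euler-Lotka on bracket {_EULER_BRACKET}")
    return float(brentq(f, lo, hi, xtol=_EULER_TOL, rtol=8.9e-16))


def demographic_params(schedule: LifeSchedule) -> DemographicParams:
    """Birch demographic parameters of a life schedule.

    Raises :class:`DegenerateScheduleError` when R0 = 0. For R0 exactly 1
    the intrinsic rate is 0 and doubling time is infinite.
    """
    R0 = schedule.R0
    rm = euler_lotka_solve(schedule)
    x = schedule.age_days.astype(float)
    T_cohort = float(np.sum(x * schedule.lxmx) / R0)
    if rm != 0.0:
        T_gen = math.log(R0) / rm
        DT = math.log(2) / rm
    else:
        T_gen = T_cohort
        DT = math.inf
    return DemographicParams(
        R0=R0,
        T_gen=T_gen,
        T_cohort=T_cohort,
        rm=rm,
        DT=DT,
        lambda_finite=math.exp(rm),
    )


# ---------------------------------------------------------------------------
# Bootstrap inference
# ---------------------------------------------------------------------------


def _bootstrap_replicates(
    cohort: Sequence[CohortRecord],
    fecundity: Sequence[FecundityObservation],
    sex_ratio: float,
    B: int,
    rng: np.random.Generator,
    age_offset_days: Optional[int] = None,
) -> dict[str, np.ndarray]:
    """B bootstrap replicates of each demographic parameter, vectorized.

    Females and immature-cohort individuals are resampled with replacement
    as independent strata; multinomial draws give the per-replicate
    resampling weights. The Euler-Lotka root is found for all replicates at
    once by 200 steps of bisection on [−1, 2] (interval width < 1e-13).
    """
    counts, alive, _ = _female_arrays(fecundity)
    nf, A = counts.shape
    if nf < 2:
        raise ValueError("bootstrap needs at least 2 females")
    completers = np.array(
        [sum(r.stage_durations.values()) for r in cohort if r.reached_adult], dtype=float
    )
    adult_flags = np.array([r.reached_adult for r in cohort], dtype=float)
    nc = len(cohort)

    Wf = rng.multinomial(nf, np.full(nf, 1.0 / nf), size=B).astype(float)  # female weights
    Wc = rng.multinomial(nc, np.full(nc, 1.0 / nc), size=B).astype(float)  # cohort weights

    sum_counts = Wf @ counts  # (B, A)
    n_alive = Wf @ alive
    with np.errstate(invalid="ignore", divide="ignore"):
        mx_b = np.where(n_alive > 0, sum_counts / np.maximum(n_alive, 1e-300), 0.0) * sex_ratio
    surv_b = n_alive / nf
    p_adult_b = (Wc @ adult_flags) / nc

    if age_offset_days is None:
        # per-replicate offset from the resampled completers' mean duration;
        # replicates with no completer fall back to the point-estimate offset
        # map completers back onto cohort indices
        comp_idx = [i for i, r in enumerate(cohort) if r.reached_adult]
        w_comp = Wc[:, comp_idx]
        tot_w = w_comp.sum(axis=1)
        base = _immature_offset(cohort)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_dur = np.where(tot_w > 0, (w_comp @ completers) / np.maximum(tot_w, 1e-300), base)
        offset_b = np.round(mean_dur)
    else:
        offset_b = np.full(B, float(age_offset_days))

    phi = (p_adult_b[:, None] * surv_b) * mx_b  # (B, A): lx·mx on adult-age days
    adult_age = np.arange(1, A + 1, dtype=float)

    R0_b = phi.sum(axis=1)
    ages_b = offset_b[:, None] + adult_age[None, :]

    # vectorized monotone bisection for rm on [-1, 2]
    lo = np.full(B, _EULER_BRACKET[0])
    hi = np.full(B, _EULER_BRACKET[1])
    ok = R0_b > 0
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        val = np.einsum("ba,ba->b", np.exp(-mid[:, None] * ages_b), phi) - 1.0
        go_right = val > 0  # f decreasing: root above mid
        lo = np.where(go_right, mid, lo)
        hi = np.where(go_right, hi, mid)
    rm_b = np.where(ok, 0.5 * (lo + hi), np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        T_b = np.where(ok, np.log(np.maximum(R0_b, 1e-300)) / rm_b, np.nan)
        DT_b = math.log(2) / rm_b
    return {
        "R0": R0_b,
        "T_gen": T_b,
        "rm": rm_b,
        "DT": DT_b,
        "lambda_finite": np.exp(rm_b),
    }


def bootstrap_params(
    cohort: Sequence[CohortRecord],
    fecundity: Sequence[FecundityObservation],
    sex_ratio: float,
    B: int = 100_000,
    seed: int = 0,
    age_offset_days: Optional[int] = None,
) -> dict[str, BootstrapSummary]:
    """Bootstrap SEs and percentile 95% CIs for all demographic parameters.

    ``B`` defaults to 100,000 replications; the SE is the standard
    deviation of the replicate estimates and the CI the 2.5/97.5
    percentiles. Replicates where resampling removed all reproduction are
    dropped from the summaries (they are rare unless R0 is near zero).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    reps = _bootstrap_replicates(cohort, fecundity, sex_ratio, B, rng, age_offset_days)
    point = demographic_params(
        build_schedule(cohort, fecundity, sex_ratio, age_offset_days)
    )
    point_values = {
        "R0": point.R0,
        "T_gen": point.T_gen,
        "rm": point.rm,
        "DT": point.DT,
        "lambda_finite": point.lambda_finite,
    }
    out = {}
    for name in PARAMETER_NAMES:
        values = reps[name]
        values = values[np.isfinite(values)]
        out[name] = BootstrapSummary(
            point_estimate=point_values[name],
            se=float(values.std(ddof=1)) if values.size > 1 else 0.0,
            ci_low=float(np.percentile(values, 2.5)) if values.size else math.nan,
            ci_high=float(np.percentile(values, 97.5)) if values.size else math.nan,
            B=B,
            seed=seed,
        )
    return out


def paired_bootstrap_test(
    group_a: tuple[Sequence[CohortRecord], Sequence[FecundityObservation], float],
    group_b: tuple[Sequence[CohortRecord], Sequence[FecundityObservation], float],
    parameter: str,
    B: int = 100_000,
    seed: int = 0,
) -> PairedBootstrapTest:
    """Two-sided paired bootstrap test of a demographic parameter.

    Each group is ``(cohort, fecundity, sex_ratio)``. Both groups are
    resampled independently on shared replicate indices; the two-sided
    p-value is ``2·min(P(diff ≤ 0), P(diff ≥ 0))`` over replicates,
    floored at 1/B.
    """
    if parameter not in PARAMETER_NAMES:
        raise ValueError(f"parameter must be one of {PARAMETER_NAMES}")
    rng = np.random.default_rng(seed)
    reps_a = _bootstrap_replicates(*group_a[:2], group_a[2], B, rng)
    reps_b = _bootstrap_replicates(*group_b[:2], group_b[2], B, rng)
    diff = reps_a[parameter] - reps_b[parameter]
    diff = diff[np.isfinite(diff)]
    if diff.size == 0:
        raise ValueError("all bootstrap replicates degenerate; cannot test")
    p = 2.0 * min(np.mean(diff <= 0), np.mean(diff >= 0))
    p = min(1.0, max(p, 1.0 / B))
    est_a = demographic_params(build_schedule(*group_a[:2], group_a[2]))
    est_b = demographic_params(build_schedule(*group_b[:2], group_b[2]))
    point_diff = getattr(est_a, parameter) - getattr(est_b, parameter)
    return PairedBootstrapTest(
        parameter=parameter, estimate_diff=point_diff, p_value=p, B=B, seed=seed
    )


# ---------------------------------------------------------------------------
# Pre-oviposition period
# ---------------------------------------------------------------------------


def preoviposition_time(
    fecundity: Sequence[FecundityObservation],
) -> Optional[PreovipositionSummary]:
    """Mean ± SE of each female's first adult-age day with offspring.

    Measured to first *emerged nymphs* (the fertility proxy for insects
    whose eggs are laid inside plant tissue and cannot be counted). Females
    with zero lifetime output are excluded and counted in ``n_excluded``;
    returns None when no female reproduced.
    """
    first_day: dict[str, int] = {}
    all_females = set()
    for obs in sorted(fecundity, key=lambda o: o.adult_age_day):
        all_females.add(obs.female_id)
        if obs.nymphs_emerged > 0 and obs.female_id not in first_day:
            first_day[obs.female_id] = obs.adult_age_day
    n_excluded = len(all_females) - len(first_day)
    if not first_day:
        return None
    days = list(first_day.values())
    n = len(days)
    mean = sum(days) / n
    se = (
        math.sqrt(sum((d - mean) ** 2 for d in days) / (n - 1) / n) if n > 1 else 0.0
    )
    return PreovipositionSummary(mean_days=mean, se_days=se, n=n, n_excluded=n_excluded)
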