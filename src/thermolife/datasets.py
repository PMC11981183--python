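"""Reference life-history summaries for *Dicyphus cerastii* on tomato.

Published per-temperature summary statistics for the predatory mirid
*Dicyphus cerastii* reared on tomato with factitious prey, across constant
temperatures from 15.0 to 35.0 °C. These printed means are the canonical
worked-example inputs for the thermal-model fitters: individual-level raw
records for this species are unpublished, so development-rate modelling
starts from stage means exactly as a practitioner would read them off a
results table.

Durations are days (mean over individuals completing the stage); ``n`` is
the number of individuals entering the stage at that temperature; ``None``
marks temperatures where no development occurred.
"""

from __future__ import annotations

from .thermal import RatePoint

__all__ = [
    "EGG_DURATION_DAYS",
    "NYMPH_DURATION_DAYS",
    "INSTAR_DURATION_DAYS",
    "NYMPH_MORTALITY_PERCENT",
    "SEX_RATIO",
    "ADULT_LONGEVITY_DAYS",
    "DEVELOPMENT_FAILURE_TEMP_C",
    "reference_rate_points",
]

#: Mean egg (embryonic) duration in days: temperature -> (mean, n entering).
EGG_DURATION_DAYS: dict[float, tuple[float | None, int]] = {
    15.0: (30.6, 204),
    20.0: (16.5, 111),
    25.0: (11.2, 98),
    27.5: (9.8, 88),
    30.0: (9.6, 49),
    32.5: (9.7, 49),
    35.0: (None, 40),  # eggs do not hatch
}

#: Mean total nymphal (post-embryonic) duration in days: temperature -> (mean, n).
NYMPH_DURATION_DAYS: dict[float, tuple[float | None, int]] = {
    15.0: (40.0, 50),
    20.0: (25.1, 52),
    25.0: (20.0, 55),
    27.5: (16.1, 52),
    30.0: (16.4, 54),
    32.5: (None, 52),  # some nymphs reach the 3rd instar but none complete
    35.0: (None, 40),
}

#: Mean duration of each nymphal instar in days, by temperature.
INSTAR_DURATION_DAYS: dict[float, tuple[float, float, float, float, float]] = {
    15.0: (7.5, 6.4, 6.2, 7.4, 12.6),
    20.0: (4.5, 3.7, 3.7, 4.7, 8.0),
    25.0: (4.1, 2.8, 3.0, 3.6, 6.5),
    27.5: (3.0, 2.3, 2.5, 3.2, 5.0),
    30.0: (3.1, 2.7, 2.7, 3.3, 4.6),
}

#: Percentage of nymphs dying before adulthood, by temperature.
NYMPH_MORTALITY_PERCENT: dict[float, float] = {
    15.0: 12.0,
    20.0: 7.7,
    25.0: 32.7,
    27.5: 25.0,
    30.0: 51.9,
    32.5: 100.0,
    35.0: 100.0,
}

#: Proportion of females among emerging adults, by temperature.
SEX_RATIO: dict[float, float] = {15.0: 0.32, 20.0: 0.60, 25.0: 0.57, 27.5: 0.51, 30.0: 0.42}

#: Mean adult longevity in days, by temperature.
ADULT_LONGEVITY_DAYS: dict[float, float] = {
    15.0: 158.6,
    20.0: 70.9,
    25.0: 35.7,
    27.5: 12.4,
    30.0: 13.8,
}

#: Lowest temperature at which each stage group fails to complete
#: development. Used as the zero-rate anchor when fitting Lactin-2 curves:
#: the failure temperature carries real information about the upper thermal
#: limit and is included as an observed rate of zero.
DEVELOPMENT_FAILURE_TEMP_C: dict[str, float] = {"egg": 35.0, "nymph": 32.5, "total": 32.5}


def reference_rate_points(stage: str, include_failure_zero: bool = False) -> list[RatePoint]:
    """Development-rate points (1/mean duration vs temperature) for a stage group.

    ``stage`` is ``"egg"``, ``"nymph"`` or ``"total"`` (egg plus nymph means
    summed per temperature). Temperatures with no completed development are
    excluded, unless ``include_failure_zero`` is set, in which case the
    lowest failure temperature is appended as a zero-rate point — the
    convention used for Lactin-2 fits, whose upper thermal limit is
    identified by that anchor.

    Note the inclusion sets differ by stage for *linear* fits: eggs hatch
    up to 32.5 °C so the egg series has six points, while nymph and total
    series stop at 30.0 °C.
    """
    if stage == "egg":
        means = {t: m for t, (m, _) in EGG_DURATION_DAYS.items() if m is not None}
        ns = {t: n for t, (m, n) in EGG_DURATION_DAYS.items() if m is not None}
    elif stage == "nymph":
        means = {t: m for t, (m, _) in NYMPH_DURATION_DAYS.items() if m is not None}
        ns = {t: n for t, (m, n) in NYMPH_DURATION_DAYS.items() if m is not None}
    elif stage == "total":
        means, ns = {}, {}
        for t, (egg_m, _) in EGG_DURATION_DAYS.items():
            nym_m, nym_n = NYMPH_DURATION_DAYS.get(t, (None, 0))
            if egg_m is not None and nym_m is not None:
                means[t] = egg_m + nym_m
                ns[t] = nym_n
    else:
        raise ValueError(f"stage must be egg/nymph/total, got {stage!r}")
    points = [
        RatePoint(temperature_c=t, mean_duration_days=means[t], n=ns[t])
        for t in sorted(means)
    ]
    if include_failure_zero:
        points.append(RatePoint.zero_rate(DEVELOPMENT_FAILURE_TEMP_C[stage]))
    return points
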