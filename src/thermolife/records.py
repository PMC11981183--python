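"""Individual-level cohort and fecundity records.

The package's two input tables mirror the two bioassay designs common in
insect life-history work under a 24 h census interval:

* a *development* table with one row per individual, carrying stage-by-stage
  durations (egg and five nymphal instars), the individual's fate, sex and
  adult lifespan; and
* a *fecundity* table with one row per female per observation day, carrying
  the number of emerged nymphs attributed to that day.

Durations are whole days (closed counts of days spent in the stage) because
individuals are checked once every 24 h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "STAGES",
    "NYMPHAL_STAGES",
    "CohortRecord",
    "FecundityObservation",
    "StageSummary",
    "SchemaError",
    "RecordValidationError",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_fecundity_csv",
    "write_fecundity_csv",
    "summarize_stage",
    "mortality_percent",
]

#: Canonical developmental stages, in order of occurrence.
STAGES: tuple[str, ...] = ("egg", "n1", "n2", "n3", "n4", "n5")

#: The five nymphal instars (post-embryonic stages).
NYMPHAL_STAGES: tuple[str, ...] = STAGES[1:]

#: Pseudo-stages accepted by :func:`summarize_stage` for pooled durations.
COMPOSITE_STAGES: tuple[str, ...] = ("nymph_total", "immature_total", "adult")

_DURATION_COLUMNS = {s: f"{s}_days" for s in STAGES}


class SchemaError(ValueError):
    """A CSV file does not match the documented column schema."""


class RecordValidationError(ValueError):
    """One or more rows violate record invariants; message names the rows."""


@dataclass
class CohortRecord:
    """One individual followed from entry into the bioassay until death.

    ``stage_durations`` holds whole-day durations for the stages the
    individual completed; a stage that was entered but not completed (the
    stage of death) is absent. ``death_day`` is the age in days from cohort
    start (first tracked stage) at death, absent when right-censored.
    """

    individual_id: str
    temperature_c: float
    host: str = "tomato"
    prey: bool = True
    stage_durations: dict[str, int] = field(default_factory=dict)
    reached_adult: bool = False
    sex: str = "unknown"  # {female, male, unknown}
    adult_lifespan_days: Optional[int] = None
    death_day: Optional[int] = None
    censored: bool = False

    def validate(self) -> None:
        """Raise :class:`RecordValidationError` on any invariant violation."""
        problems = []
        for stage, dur in self.stage_durations.items():
            if stage not in STAGES:
                problems.append(f"unknown stage {stage!r}")
            elif not (isinstance(dur, (int,)) and dur >= 1):
                problems.append(f"duration for {stage!r} must be an integer >= 1, got {dur!r}")
        # stage presence must be a contiguous run: a later nymphal stage
        # cannot be present without its predecessors
        present = [s for s in NYMPHAL_STAGES if s in self.stage_durations]
        for i, s in enumerate(NYMPHAL_STAGES):
            if s in self.stage_durations:
                missing = [p for p in NYMPHAL_STAGES[:i] if p not in self.stage_durations]
                if missing:
                    problems.append(f"stage {s!r} present but earlier stage(s) {missing} absent")
                    break
        if self.reached_adult:
            missing = [s for s in NYMPHAL_STAGES if s not in self.stage_durations]
            if missing:
                problems.append(f"reached_adult but nymphal stage(s) {missing} absent")
        if self.sex not in ("female", "male", "unknown"):
            problems.append(f"sex must be female/male/unknown, got {self.sex!r}")
        if self.sex != "unknown" and not self.reached_adult:
            problems.append("sex can only be recorded for individuals that reached adulthood")
        if self.adult_lifespan_days is not None and not self.reached_adult:
            problems.append("adult_lifespan_days present but reached_adult is False")
        if (
            self.death_day is not None
            and self.reached_adult
            and self.adult_lifespan_days is not None
        ):
            expected = sum(self.stage_durations.values()) + self.adult_lifespan_days
            if self.death_day != expected:
                problems.append(
                    f"death_day {self.death_day} != stage durations + adult lifespan = {expected}"
                )
        if self.censored and self.death_day is not None:
            problems.append("censored individuals must not carry a death_day")
        if problems:
            raise RecordValidationError(
                f"record {self.individual_id!r}: " + "; ".join(problems)
            )

    def total_duration(self, stages: Sequence[str]) -> Optional[int]:
        """Summed duration over ``stages``, or None unless all are present."""
        if all(s in self.stage_durations for s in stages):
            return sum(self.stage_durations[s] for s in stages)
        return None

    def entered_stage(self, stage: str) -> bool:
        """Whether the individual is known to have entered ``stage``.

        An individual entered a nymphal stage if it completed every earlier
        nymphal stage (the egg stage is not required: development bioassays
        typically start at the first instar). Every record counts as having
        entered the egg stage. A record with no durations at all counts as
        an entrant of any queried first stage — the data cannot distinguish
        where it started.
        """
        if stage == "egg":
            return True
        if stage not in NYMPHAL_STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        idx = NYMPHAL_STAGES.index(stage)
        return all(s in self.stage_durations for s in NYMPHAL_STAGES[:idx])

    def completed_stage(self, stage: str) -> bool:
        if stage == "adult":
            return bool(self.reached_adult and self.adult_lifespan_days is not None)
        return stage in self.stage_durations


@dataclass
class FecundityObservation:
    """Nymphs emerged attributable to one female on one adult-age day."""

    female_id: str
    temperature_c: float
    adult_age_day: int
    nymphs_emerged: int

    def validate(self) -> None:
        problems = []
        if not self.adult_age_day >= 1:
            problems.append(f"adult_age_day must be >= 1, got {self.adult_age_day}")
        if not self.nymphs_emerged >= 0:
            problems.append(f"nymphs_emerged must be >= 0, got {self.nymphs_emerged}")
        if problems:
            raise RecordValidationError(
                f"observation for female {self.female_id!r}: " + "; ".join(problems)
            )


@dataclass(frozen=True)
class StageSummary:
    """Mean stage duration among completers at one temperature."""

    mean_days: float
    se_days: float  # sample SD / sqrt(n); 0.0 when n == 1 (documented convention)
    n: int


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    ["individual_id", "temperature_c", "host", "prey"]
    + [_DURATION_COLUMNS[s] for s in STAGES]
    + ["reached_adult", "sex", "adult_lifespan_days", "death_day", "censored"]
)

FECUNDITY_COLUMNS = ["female_id", "temperature_c", "adult_age_day", "nymphs_emerged"]


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return int(value)


def _to_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")


def read_cohort_csv(path) -> list[CohortRecord]:
    """Read and validate a development table (one row per individual).

    Raises :class:`SchemaError` if required columns are missing and
    :class:`RecordValidationError` naming the offending rows (1-based, not
    counting the header) if any row violates an invariant.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records, errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        durations = {}
        for s in STAGES:
            v = _opt_int(getattr(row, _DURATION_COLUMNS[s]))
            if v is not None:
                durations[s] = v
        rec = CohortRecord(
            individual_id=str(row.individual_id),
            temperature_c=float(row.temperature_c),
            host=str(row.host),
            prey=_to_bool(row.prey),
            stage_durations=durations,
            reached_adult=_to_bool(row.reached_adult),
            sex=str(row.sex) if str(row.sex) in ("female", "male") else "unknown",
            adult_lifespan_days=_opt_int(row.adult_lifespan_days),
            death_day=_opt_int(row.death_day),
            censored=_to_bool(row.censored),
        )
        try:
            rec.validate()
        except RecordValidationError as exc:
            errors.append(f"row {i}: {exc}")
        else:
            records.append(rec)
    if errors:
        raise RecordValidationError("; ".join(errors))
    return records


def write_cohort_csv(records: Iterable[CohortRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "individual_id": r.individual_id,
            "temperature_c": r.temperature_c,
            "host": r.host,
            "prey": r.prey,
            "reached_adult": r.reached_adult,
            "sex": r.sex,
            "adult_lifespan_days": r.adult_lifespan_days,
            "death_day": r.death_day,
            "censored": r.censored,
        }
        for s in STAGES:
            row[_DURATION_COLUMNS[s]] = r.stage_durations.get(s)
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def read_fecundity_csv(path) -> list[FecundityObservation]:
    """Read and validate a fecundity table (one row per female-day)."""
    df = pd.read_csv(path)
    missing = [c for c in FECUNDITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    observations, errors = [], []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        obs = FecundityObservation(
            female_id=str(row.female_id),
            temperature_c=float(row.temperature_c),
            adult_age_day=int(row.adult_age_day),
            nymphs_emerged=int(row.nymphs_emerged),
        )
        try:
            obs.validate()
        except RecordValidationError as exc:
            errors.append(f"row {i}: {exc}")
        else:
            observations.append(obs)
    if errors:
        raise RecordValidationError("; ".join(errors))
    return observations


def write_fecundity_csv(observations: Iterable[FecundityObservation], path) -> None:
    rows = [
        {
            "female_id": o.female_id,
            "temperature_c": o.temperature_c,
            "adult_age_day": o.adult_age_day,
            "nymphs_emerged": o.nymphs_emerged,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=FECUNDITY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def _stage_duration(record: CohortRecord, stage: str) -> Optional[int]:
    if stage in STAGES:
        return record.stage_durations.get(stage)
    if stage == "nymph_total":
        return record.total_duration(NYMPHAL_STAGES)
    if stage == "immature_total":
        return record.total_duration(STAGES)
    if stage == "adult":
        return record.adult_lifespan_days if not record.censored else None
    raise ValueError(f"unknown stage {stage!r}")


def summarize_stage(
    records: Iterable[CohortRecord], stage: str, temperature_c: float
) -> Optional[StageSummary]:
    """Mean ± SE duration of ``stage`` among completers at one temperature.

    ``stage`` is one of the canonical stages, ``"nymph_total"`` (sum of the
    five instars), ``"immature_total"`` (egg through fifth instar) or
    ``"adult"`` (adult lifespan, censored individuals excluded). Returns
    None when no individual completed the stage — distinct from a zero mean.
    """
    durations = [
        d
        for r in records
        if r.temperature_c == temperature_c and (d := _stage_duration(r, stage)) is not None
    ]
    n = len(durations)
    if n == 0:
        return None
    mean = sum(durations) / n
    if n == 1:
        se = 0.0
    else:
        var = sum((d - mean) ** 2 for d in durations) / (n - 1)
        se = math.sqrt(var / n)
    return StageSummary(mean_days=mean, se_days=se, n=n)


def mortality_percent(
    records: Iterable[CohortRecord],
    stage_range: tuple[str, str],
    temperature_c: float,
) -> Optional[float]:
    """Percentage mortality across a contiguous range of stages.

    ``100 × (entrants − completers of the last stage) / entrants`` where
    entrants are individuals known to have entered the first stage of the
    range (see :meth:`CohortRecord.entered_stage`). Returns None when no
    individual entered the range — distinct from zero mortality.
    """
    first, last = stage_range
    order = ("egg",) + NYMPHAL_STAGES + ("adult",)
    if first not in order[:-1] or last not in order:
        raise ValueError(f"invalid stage range {stage_range!r}")
    if order.index(first) > order.index(last):
        raise ValueError(f"stage range out of order: {stage_range!r}")
    group = [r for r in records if r.temperature_c == temperature_c]
    entrants = [r for r in group if r.entered_stage(first)]
    if not entrants:
        return None
    if last == "adult":
        completers = sum(1 for r in entrants if r.reached_adult)
    else:
        completers = sum(1 for r in entrants if r.completed_stage(last))
    return 100.0 * (len(entrants) - completers) / len(entrants)
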