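import numpy as np
import pytest

from thermolife import CohortRecord, FecundityObservation, GeneratorConfig


@pytest.fixture
def gen_config():
    return GeneratorConfig()


def make_adult(i, temp=25.0, durations=None, sex="female", lifespan=10):
    """A valid record that completed development."""
    durations = durations or {"n1": 4, "n2": 3, "n3": 3, "n4": 4, "n5": 6}
    return CohortRecord(
        individual_id=f"a{i}",
        temperature_c=temp,
        stage_durations=dict(durations),
        reached_adult=True,
        sex=sex,
        adult_lifespan_days=lifespan,
        death_day=sum(durations.values()) + lifespan,
    )


def make_nymph_death(i, temp=25.0, completed=("n1",), death_day=6):
    durations = {}
    d = {"n1": 4, "n2": 3, "n3": 3, "n4": 4, "n5": 6}
    for s in completed:
        durations[s] = d[s]
    return CohortRecord(
        individual_id=f"d{i}",
        temperature_c=temp,
        stage_durations=durations,
        reached_adult=False,
        death_day=death_day,
    )


def constant_fecundity(n_females, days, count, temp=25.0, start_day=1):
    """Every female lives `days` adult days producing `count` nymphs/day
    from `start_day` onwards."""
    obs = []
    for i in range(n_females):
        for day in range(1, days + 1):
            obs.append(
                FecundityObservation(
                    female_id=f"f{i}",
                    temperature_c=temp,
                    adult_age_day=day,
                    nymphs_emerged=count if day >= start_day else 0,
                )
            )
    return obs
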