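"""Analysis configuration: a small validated key-value structure.

Loaded from a YAML file by the command-line layer; library users normally
pass the equivalent keyword arguments directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """Run-level settings shared by the pipeline stages."""

    #: temperatures (°C) to include per analysis stage group
    temperature_sets: dict[str, list[float]] = field(
        default_factory=lambda: {
            "egg": [15.0, 20.0, 25.0, 27.5, 30.0, 32.5],
            "nymph": [15.0, 20.0, 25.0, 27.5, 30.0],
            "total": [15.0, 20.0, 25.0, 27.5, 30.0],
        }
    )
    bootstrap_replications: int = 100_000
    rng_seed: int = 0
    alpha: float = 0.05
    report_decimals: int = 4
    #: life-table age origin: offset adult ages by the cohort's mean
    #: immature duration ("auto") or a fixed integer day count
    offspring_development_lag: int | str = "auto"

    def __post_init__(self):
        if self.bootstrap_replications < 1:
            raise ValueError("bootstrap_replications must be >= 1")
        for stage, temps in self.temperature_sets.items():
            if not temps:
                raise ValueError(f"temperature set for {stage!r} is empty")

    @property
    def age_offset_days(self):
        return None if self.offspring_development_lag == "auto" else int(self.offspring_development_lag)


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return AnalysisConfig(**data)
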