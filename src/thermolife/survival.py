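"""Nonparametric survival comparison between rearing conditions.

Kaplan-Meier product-limit curves and log-rank tests, the standard way to
compare survival of insect cohorts across temperature × host × prey
treatments, plus the compact-letter display used in results tables, where
curves sharing a letter are not significantly different.

Estimation and testing are delegated to lifelines; this module adapts
cohort records to (time, event) form and adds the letter-grouping logic.
Ties between deaths and censorings on the same day follow the standard
convention: deaths are processed first.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_lowercase
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

from .records import CohortRecord

__all__ = [
    "KMCurve",
    "LogRankResult",
    "km_fit",
    "log_rank",
    "pairwise_log_rank",
    "letter_groups",
    "survival_times_from_records",
]


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier estimate of one group's survival function."""

    event_times: np.ndarray  # ordered distinct observation times (days)
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival_prob: np.ndarray  # S(t) just after each time
    label: str = ""

    def survival_at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous step)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])

    def mean_survival(self) -> float:
        """Area under the KM curve up to the last observed time.

        With no censoring this equals the arithmetic mean of the times.
        """
        times = np.concatenate([[0.0], self.event_times])
        S = np.concatenate([[1.0], self.survival_prob])
        return float(np.sum(S[:-1] * np.diff(times)))


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    groups: tuple[str, ...]


def km_fit(
    times: Sequence[float],
    event_observed: Optional[Sequence[bool]] = None,
    label: str = "",
) -> KMCurve:
    """Product-limit estimate from times and event indicators.

    ``event_observed`` defaults to all-events (no censoring). Censored
    observations carry ``False``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("km_fit needs at least one observation")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    events = (
        np.ones_like(times, dtype=bool)
        if event_observed is None
        else np.asarray(event_observed, dtype=bool)
    )
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, label=label or None)
    # lifelines inserts a t=0 row; keep it only if the data contain t=0
    table = kmf.event_table
    if table.index[0] == 0.0 and not np.any(times == 0.0):
        table = table.iloc[1:]
    surv = kmf.survival_function_.iloc[:, 0]
    return KMCurve(
        event_times=table.index.to_numpy(dtype=float),
        n_at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
        n_censored=table["censored"].to_numpy(dtype=int),
        survival_prob=np.array([surv.loc[t] for t in table.index], dtype=float),
        label=label,
    )


def log_rank(groups: Mapping[str, tuple[Sequence[float], Sequence[bool]]]) -> LogRankResult:
    """Log-rank test over two or more labelled (times, events) groups."""
    if len(groups) < 2:
        raise ValueError("log_rank needs at least two groups")
    labels, durations, events, membership = [], [], [], []
    for label, (t, e) in groups.items():
        t = np.asarray(t, dtype=float)
        e = np.ones_like(t, dtype=bool) if e is None else np.asarray(e, dtype=bool)
        if t.size == 0:
            raise ValueError(f"group {label!r} has no observations")
        labels.append(label)
        durations.append(t)
        events.append(e)
        membership.append(np.full(t.size, label, dtype=object))
    if len(groups) == 2:
        res = logrank_test(
            durations[0], durations[1], event_observed_A=events[0], event_observed_B=events[1]
        )
        chi2, p = res.test_statistic, res.p_value
    else:
        res = multivariate_logrank_test(
            np.concatenate(durations),
            np.concatenate(membership),
            np.concatenate(events),
        )
        chi2, p = res.test_statistic, res.p_value
    return LogRankResult(
        chi_square=float(chi2),
        df=len(groups) - 1,
        p_value=float(p),
        groups=tuple(labels),
    )


def pairwise_log_rank(
    groups: Mapping[str, tuple[Sequence[float], Sequence[bool]]],
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise log-rank p-values.

    Unadjusted by default, matching the plain letter displays of
    life-history tables; set ``bonferroni`` to multiply each p-value by the
    number of comparisons (capped at 1).
    """
    labels = list(groups)
    k = len(labels)
    n_comparisons = k * (k - 1) // 2
    mat = pd.DataFrame(np.ones((k, k)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            p = log_rank({a: groups[a], b: groups[b]}).p_value
            if bonferroni:
                p = min(1.0, p * n_comparisons)
            mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def letter_groups(pairwise_p: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from a pairwise p-value matrix.

    Builds the graph connecting groups that are *not* significantly
    different (p > alpha) and assigns one letter per maximal clique, so two
    groups share a letter iff they are statistically indistinguishable.
    Cliques are ordered by their first member's position in the matrix,
    making the lettering deterministic.
    """
    labels = list(pairwise_p.index)
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if pairwise_p.loc[a, b] > alpha:
                g.add_edge(a, b)
    order = {lab: i for i, lab in enumerate(labels)}
    cliques = sorted(
        (sorted(c, key=order.get) for c in nx.find_cliques(g)),
        key=lambda c: [order[x] for x in c],
    )
    assigned: dict[str, list[str]] = {lab: [] for lab in labels}
    for letter, clique in zip(_letter_stream(), cliques):
        for member in clique:
            assigned[member].append(letter)
    return {lab: "".join(sorted(ls)) for lab, ls in assigned.items()}


def _letter_stream():
    for letter in ascii_lowercase:
        yield letter
    for a in ascii_lowercase:  # a2, b2, ... if more than 26 cliques
        for i in range(2, 10):
            yield f"{a}{i}"


def survival_times_from_records(
    records: Iterable[CohortRecord],
    origin: str = "cohort_start",
) -> tuple[np.ndarray, np.ndarray]:
    """Extract (times, event_observed) pairs from cohort records.

    ``origin`` selects the time zero: ``"cohort_start"`` (first tracked
    stage, e.g. hatching for nymph cohorts) or ``"adult_emergence"``
    (adult lifespan only; pre-adult deaths are excluded). Individuals alive
    at study end enter as censored at their last observed age.
    """
    times, events = [], []
    for r in records:
        if origin == "cohort_start":
            if r.death_day is not None:
                times.append(float(r.death_day))
                events.append(True)
            elif r.censored:
                last_seen = sum(r.stage_durations.values()) + (r.adult_lifespan_days or 0)
                if last_seen > 0:
                    times.append(float(last_seen))
                    events.append(False)
        elif origin == "adult_emergence":
            if r.reached_adult and r.adult_lifespan_days is not None:
                times.append(float(r.adult_lifespan_days))
                events.append(not r.censored)
        else:
            raise ValueError(f"unknown origin {origin!r}")
    return np.asarray(times), np.asarray(events, dtype=bool)
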