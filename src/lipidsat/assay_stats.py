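"""Organism-assay statistics: survival, cold-stress recovery and feeding.

Survival comparisons use the standard two-group log-rank test: at each
distinct event day the observed deaths in one group are compared with their
hypergeometric expectation given the risk sets, tied deaths handled through
the hypergeometric variance, and the variance-weighted sum is referred to a
χ² distribution with one degree of freedom.  Median survival follows the
step-function convention — the smallest day by which at least half the group
has died — and lifespan-extension percentages are reported to the nearest
integer.

Cold-stress recovery outcomes (full recovery / partial recovery / dead) are
compared across conditions with a Pearson χ² test of independence without
continuity correction.  Feeding behaviour is summarised as scored feeding
events over total feeding opportunities (flies per vial × vials × rounds of
observation), with per-vial totals retained so group comparisons can be made
at the vial level and avoid pseudoreplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalDataset",
    "RecoveryCounts",
    "FeedingObservation",
    "median_survival",
    "median_survival_change",
    "logrank_test",
    "LogrankResult",
    "cold_stress_test",
    "ChiSquareResult",
    "feeding_proportion",
    "FeedingResult",
]


@dataclass(frozen=True)
class SurvivalDataset:
    """Event days for one group of individuals.

    ``events`` flags deaths; False marks right-censored individuals
    (supported in the data model although fly lifespans here are fully
    observed).
    """

    days: np.ndarray
    events: np.ndarray = field(default=None)  # type: ignore[assignment]
    group: str = ""

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        if days.size == 0:
            raise ValueError("survival dataset has no individuals")
        if (days < 1).any():
            raise ValueError("event days must be >= 1")
        events = (
            np.ones(days.shape, dtype=bool)
            if self.events is None
            else np.asarray(self.events, dtype=bool)
        )
        if events.shape != days.shape:
            raise ValueError("days and events must have the same length")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return int(self.days.size)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group: str | None = None) -> "SurvivalDataset":
        """Build from long-format records with columns day, [event], [group]."""
        sub = frame if group is None else frame[frame["group"] == group]
        events = sub["event"] if "event" in sub.columns else None
        return cls(
            days=sub["day"].to_numpy(),
            events=None if events is None else events.to_numpy(),
            group=group or "",
        )


def median_survival(dataset: SurvivalDataset) -> float:
    """Smallest day by which at least 50% of the group has died.

    Raises when censoring keeps the death fraction below one half, in which
    case the median is undefined.
    """
    n = len(dataset)
    event_days = np.sort(dataset.days[dataset.events])
    if event_days.size < 0.5 * n:
        raise ValueError(
            "median undefined: fewer than half the individuals have died"
        )
    return float(event_days[int(np.ceil(0.5 * n)) - 1])


def median_survival_change(
    control: SurvivalDataset | float, treated: SurvivalDataset | float
) -> int:
    """Percent change in median survival, rounded to the nearest integer.

    Accepts datasets or direct numeric medians (fractional medians such as
    27.5 d arise from averaging replicate-vial medians and are passed in as
    numbers).
    """
    m_control = (
        median_survival(control)
        if isinstance(control, SurvivalDataset)
        else float(control)
    )
    m_treated = (
        median_survival(treated)
        if isinstance(treated, SurvivalDataset)
        else float(treated)
    )
    if m_control <= 0:
        raise ValueError("control median must be positive")
    return int(round(100.0 * (m_treated - m_control) / m_control))


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    observed: float  # deaths observed in the first group
    expected: float  # deaths expected in the first group under the null


def logrank_test(a: SurvivalDataset, b: SurvivalDataset) -> LogrankResult:
    """Two-group log-rank test with hypergeometric tie handling.

    At each distinct event time ``t`` with ``d`` total deaths, ``n1`` of
    ``n`` individuals at risk in group ``a``, the contribution is
    ``O − E = d1 − d·n1/n`` with variance
    ``d·(n1/n)·(1 − n1/n)·(n − d)/(n − 1)``.  The squared variance-weighted
    sum is χ²(1).  Symmetric in the two groups.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one individual")
    if not (a.events.any() and b.events.any()):
        raise ValueError("both groups need at least one event")

    days = np.concatenate([a.days, b.days])
    events = np.concatenate([a.events, b.events])
    in_a = np.concatenate(
        [np.ones(len(a), dtype=bool), np.zeros(len(b), dtype=bool)]
    )
    o_minus_e = 0.0
    var = 0.0
    observed = 0.0
    expected = 0.0
    for t in np.unique(days[events]):
        at_risk = days >= t
        n = at_risk.sum()
        n1 = (at_risk & in_a).sum()
        dead_now = events & (days == t)
        d = dead_now.sum()
        d1 = (dead_now & in_a).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        observed += d1
        expected += e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        # no between-group information (e.g. everyone dies at one shared day)
        return LogrankResult(0.0, 1.0, observed, expected)
    statistic = o_minus_e**2 / var
    return LogrankResult(
        statistic=float(statistic),
        p_value=float(stats.chi2.sf(statistic, df=1)),
        observed=float(observed),
        expected=float(expected),
    )


@dataclass(frozen=True)
class RecoveryCounts:
    """Condition × outcome counts for the cold-stress recovery assay."""

    table: pd.DataFrame  # rows: conditions; columns: outcome categories

    def __post_init__(self) -> None:
        values = self.table.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.table.shape[0] < 2 or self.table.shape[1] < 2:
            raise ValueError("need at least two conditions and two outcomes")
        row_totals = values.sum(axis=1)
        if (row_totals == 0).any():
            bad = self.table.index[row_totals == 0].tolist()
            raise ValueError(f"conditions with zero total counts: {bad}")


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: pd.DataFrame
    low_expected_cells: int  # expected counts below 5


def cold_stress_test(counts: RecoveryCounts | pd.DataFrame) -> ChiSquareResult:
    """Pearson χ² of independence on the conditions × outcomes table.

    No continuity correction (the tables here are 2×3 / 3×3).  A zero
    marginal column raises; expected counts below five trigger a warning and
    are counted in the result.
    """
    table = counts.table if isinstance(counts, RecoveryCounts) else counts
    counts = counts if isinstance(counts, RecoveryCounts) else RecoveryCounts(table)
    values = table.to_numpy(dtype=float)
    col_totals = values.sum(axis=0)
    if (col_totals == 0).any():
        bad = table.columns[col_totals == 0].tolist()
        raise ValueError(f"outcome categories never observed: {bad}")

    statistic, p, df, expected = stats.chi2_contingency(values, correction=False)
    expected_df = pd.DataFrame(expected, index=table.index, columns=table.columns)
    low = int((expected < 5).sum())
    if low:
        warnings.warn(
            f"{low} cells have expected counts below 5; the χ² approximation "
            "may be poor",
            stacklevel=2,
        )
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
        expected=expected_df,
        low_expected_cells=low,
    )


@dataclass(frozen=True)
class FeedingObservation:
    """Scored feeding events for one experimental group.

    ``per_vial_events`` (optional) holds the event totals of each vial; the
    vial, not the fly, is the replication unit for group comparisons.
    """

    events: int
    flies_per_vial: int
    n_vials: int
    n_observations: int
    per_vial_events: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for name in ("flies_per_vial", "n_vials", "n_observations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.events < 0:
            raise ValueError("events must be non-negative")
        if self.events > self.opportunities:
            raise ValueError(
                f"{self.events} events exceed "
                f"{self.opportunities} feeding opportunities"
            )
        if self.per_vial_events is not None:
            if len(self.per_vial_events) != self.n_vials:
                raise ValueError("per_vial_events must have one entry per vial")
            if sum(self.per_vial_events) != self.events:
                raise ValueError("per_vial_events must sum to events")

    @property
    def opportunities(self) -> int:
        return self.flies_per_vial * self.n_vials * self.n_observations


@dataclass(frozen=True)
class FeedingResult:
    proportion: float
    opportunities: int
    per_vial_events: tuple[int, ...] | None
    per_vial_proportions: tuple[float, ...] | None


def feeding_proportion(obs: FeedingObservation) -> FeedingResult:
    """Feeding events over total feeding opportunities, with vial summaries."""
    per_vial_props = None
    if obs.per_vial_events is not None:
        per_vial_opps = obs.flies_per_vial * obs.n_observations
        per_vial_props = tuple(e / per_vial_opps for e in obs.per_vial_events)
    return FeedingResult(
        proportion=obs.events / obs.opportunities,
        opportunities=obs.opportunities,
        per_vial_events=obs.per_vial_events,
        per_vial_proportions=per_vial_props,
    )
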