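"""Cost schedules for delay, probability, and effort discounting tasks.

A discounting task presents choices between a smaller cheap reward and a
larger reward carrying a *cost*: a delay to receipt, odds against receipt,
or physical effort.  Each task uses five cost levels.  This module defines
the :class:`CostSchedule` container, the default schedules (2 weeks to
3 years of delay; 90% down to 10% chance expressed as odds against;
10 to 120 minutes of walking), and the encodings of the cost axis used
downstream: raw numeric values, values normalized to [0, 1], and ordinal
ranks 1..5.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TaskKind",
    "CostSchedule",
    "odds_against",
    "probability_from_odds",
    "effort_costs",
    "ordinal_ranks",
    "normalize_costs",
    "delay_schedule",
    "probability_schedule",
    "effort_schedule",
    "default_schedules",
]

N_LEVELS = 5


class TaskKind(str, enum.Enum):
    """The three cost dimensions a reward can be discounted along."""

    DELAY = "delay"
    PROBABILITY = "probability"
    EFFORT = "effort"


@dataclass(frozen=True)
class CostSchedule:
    """Five strictly increasing, strictly positive cost levels for one task.

    Parameters
    ----------
    task_kind
        Which cost dimension the schedule parameterizes.
    level_labels
        Human-readable labels, one per level (e.g. ``"2 weeks"``).
    raw_costs
        Numeric cost values: delay in days, probability as odds against,
        effort in minutes of walking.  The zero-cost anchor used when
        integrating the discounting curve is *not* a level.
    units
        Unit string for ``raw_costs``.
    """

    task_kind: TaskKind
    level_labels: tuple[str, ...]
    raw_costs: tuple[float, ...]
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "task_kind", TaskKind(self.task_kind))
        object.__setattr__(self, "level_labels", tuple(self.level_labels))
        object.__setattr__(self, "raw_costs", tuple(float(c) for c in self.raw_costs))
        if len(self.raw_costs) != N_LEVELS:
            raise ValueError(
                f"a cost schedule has exactly {N_LEVELS} levels, got {len(self.raw_costs)}"
            )
        if len(self.level_labels) != len(self.raw_costs):
            raise ValueError("one label per cost level required")
        if any(c <= 0 for c in self.raw_costs):
            raise ValueError("all cost levels must be strictly positive")
        if any(b <= a for a, b in zip(self.raw_costs, self.raw_costs[1:])):
            raise ValueError("cost levels must be strictly increasing")

    def normalized(self, include_anchor: bool = False) -> np.ndarray:
        """Costs divided by the maximum cost, optionally with a 0 prepended."""
        return normalize_costs(self.raw_costs, include_anchor=include_anchor)

    def to_dict(self) -> dict:
        return {
            "task_kind": self.task_kind.value,
            "level_labels": list(self.level_labels),
            "raw_costs": list(self.raw_costs),
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CostSchedule":
        return cls(
            task_kind=TaskKind(d["task_kind"]),
            level_labels=tuple(d["level_labels"]),
            raw_costs=tuple(d["raw_costs"]),
            units=d.get("units", ""),
        )


def odds_against(p: float) -> float:
    """Convert a probability of receipt into odds against receipt, (1-p)/p.

    A 10% chance corresponds to 9 odds against; certainty (p = 1) to 0.

    Parameters
    ----------
    p
        Probability of receiving the reward, in (0, 1].
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must lie in (0, 1], got {p!r}")
    return (1.0 - p) / p


def probability_from_odds(theta: float) -> float:
    """Inverse of :func:`odds_against`: p = 1/(1+theta)."""
    if theta < 0:
        raise ValueError(f"odds against must be nonnegative, got {theta!r}")
    return 1.0 / (1.0 + theta)


def effort_costs(
    mean_steps_per_min: float, minutes: Sequence[float]
) -> list[int]:
    """Individualized step counts for the effort task's display layer.

    The number of steps shown to a participant at each effort level is their
    calibrated walking rate multiplied by the level's duration.  The analysis
    cost axis stays in minutes — durations are common across participants
    while step counts are not — so the returned values are presentation-layer
    only.

    Parameters
    ----------
    mean_steps_per_min
        Calibrated mean steps per minute, > 0.
    minutes
        Increasing walking durations in minutes, all > 0.

    Returns
    -------
    list of int
        Step counts, rounded to the nearest whole step.
    """
    if mean_steps_per_min <= 0:
        raise ValueError("mean_steps_per_min must be positive")
    minutes = list(minutes)
    if not minutes:
        raise ValueError("minutes must be nonempty")
    if any(m <= 0 for m in minutes):
        raise ValueError("all durations must be positive")
    if any(b <= a for a, b in zip(minutes, minutes[1:])):
        raise ValueError("durations must be increasing")
    return [int(round(mean_steps_per_min * m)) for m in minutes]


def ordinal_ranks(schedule: "CostSchedule | Sequence[float]") -> list[int]:
    """Ordinal recoding of cost levels: the cheapest level becomes 1.

    Ranks follow the sorted order of the raw costs, so any strictly monotone
    re-encoding of the cost axis yields the same ranks.
    """
    costs = (
        schedule.raw_costs if isinstance(schedule, CostSchedule) else list(schedule)
    )
    order = np.argsort(np.asarray(costs, dtype=float), kind="stable")
    ranks = np.empty(len(costs), dtype=int)
    ranks[order] = np.arange(1, len(costs) + 1)
    return ranks.tolist()


def normalize_costs(
    costs: Sequence[float], include_anchor: bool = False
) -> np.ndarray:
    """Divide costs by the maximum cost, mapping the axis onto (0, 1].

    With ``include_anchor`` a leading 0 is prepended, which is how the
    x-axis of the discounting curve is laid out before integration.
    """
    arr = np.asarray(list(costs), dtype=float)
    if arr.size == 0:
        raise ValueError("costs must be nonempty")
    if arr.max() <= 0:
        raise ValueError("maximum cost must be positive")
    if np.any(np.diff(arr) <= 0):
        raise ValueError("costs must be strictly increasing")
    out = arr / arr.max()
    if include_anchor:
        out = np.concatenate([[0.0], out])
    return out


# -- default study schedules -------------------------------------------------

#: Probabilities of receipt defining the probability task, largest chance first.
PROBABILITY_LEVELS = (0.90, 0.75, 0.50, 0.25, 0.10)

#: Walking durations (minutes) defining the effort task.
EFFORT_MINUTES = (10.0, 20.0, 60.0, 90.0, 120.0)


def delay_schedule(days_per_month: int = 30, days_per_year: int = 365) -> CostSchedule:
    """Delays of 2 weeks, 2 months, 6 months, 1 year, and 3 years, in days.

    Calendar words are encoded with the plain conventions month = 30 d and
    year = 365 d by default; any monotone encoding leaves the ordinal
    analyses unchanged.
    """
    costs = (
        14.0,
        2.0 * days_per_month,
        6.0 * days_per_month,
        1.0 * days_per_year,
        3.0 * days_per_year,
    )
    return CostSchedule(
        task_kind=TaskKind.DELAY,
        level_labels=("2 weeks", "2 months", "6 months", "1 year", "3 years"),
        raw_costs=costs,
        units="days",
    )


def probability_schedule() -> CostSchedule:
    """Chances of 90, 75, 50, 25, and 10 percent, as odds against receipt.

    Odds against are kept at full precision (1/9, 1/3, 1, 3, 9); the display
    values 0.11 and 0.33 are roundings only.
    """
    costs = tuple(odds_against(p) for p in PROBABILITY_LEVELS)
    return CostSchedule(
        task_kind=TaskKind.PROBABILITY,
        level_labels=("90%", "75%", "50%", "25%", "10%"),
        raw_costs=costs,
        units="odds against",
    )


def effort_schedule() -> CostSchedule:
    """Walking durations of 10, 20, 60, 90, and 120 minutes.

    The analysis axis is the duration; individualized step counts from
    :func:`effort_costs` are what a participant would see on screen.
    """
    return CostSchedule(
        task_kind=TaskKind.EFFORT,
        level_labels=tuple(f"{int(m)} min" for m in EFFORT_MINUTES),
        raw_costs=EFFORT_MINUTES,
        units="minutes",
    )


def default_schedules() -> dict[TaskKind, CostSchedule]:
    """The three default task schedules keyed by task kind."""
    return {
        TaskKind.DELAY: delay_schedule(),
        TaskKind.PROBABILITY: probability_schedule(),
        TaskKind.EFFORT: effort_schedule(),
    }
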