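"""Adjusting-amount (titration) staircase and indifference-point extraction.

Each cost level is probed with a six-trial binary-choice staircase.  The
smaller, cheap amount starts at half the larger amount A and moves toward
the point of subjective equality by halving adjustments: after trial t the
offer changes by A / 2**(t+1) — up if the larger costly reward was chosen,
down otherwise.  The offer presented on the sixth trial is coded as the
indifference point (IP).  Displayed and recorded offers are rounded to
whole currency units; internal arithmetic is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import pandas as pd

from .schedules import TaskKind

__all__ = [
    "TitrationError",
    "IncompleteBlockError",
    "TitrationState",
    "ChoiceRecord",
    "IndifferenceCurve",
    "next_offer",
    "run_titration",
    "extract_ips",
    "records_to_frame",
    "curves_to_frame",
    "N_TRIALS",
]

N_TRIALS = 6

#: Columns of the canonical trial table.
TRIAL_COLUMNS = [
    "participant_id",
    "timepoint",
    "task",
    "level_index",
    "cost_value",
    "trial",
    "offer_small",
    "amount_large",
    "chose_larger",
]

IP_COLUMNS = ["participant_id", "timepoint", "task", "level_index", "cost_value", "ip"]


class TitrationError(RuntimeError):
    """Raised when the staircase or a choice log violates the task structure."""


class IncompleteBlockError(TitrationError):
    """A (participant, timepoint, task) block is malformed; names the block."""

    def __init__(self, block: tuple, reason: str):
        self.block = block
        super().__init__(f"block {block!r}: {reason}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TitrationState:
    """Staircase state before a trial is presented.

    ``offer`` is the exact (unrounded) smaller amount about to be offered on
    trial ``trial_index``; ``adjustment`` is the step applied after that
    trial, always ``amount_large / 2**(trial_index + 1)``.
    """

    amount_large: float
    offer: float
    adjustment: float
    trial_index: int = 1

    @classmethod
    def initial(cls, amount_large: float) -> "TitrationState":
        if amount_large <= 0:
            raise ValueError("amount_large must be positive")
        return cls(
            amount_large=amount_large,
            offer=amount_large / 2.0,
            adjustment=amount_large / 4.0,
            trial_index=1,
        )

    @property
    def offer_recorded(self) -> int:
        """The offer as displayed and logged: rounded to a whole amount."""
        return _round_half_up(self.offer)


def next_offer(
    state: TitrationState, chose_larger: bool, round_then_adjust: bool = False
) -> TitrationState:
    """Advance the staircase by one choice.

    Choosing the larger costly reward signals the offer was too low, so the
    offer increases by the current adjustment; choosing the smaller amount
    decreases it.  The adjustment halves and the trial index increments.

    ``round_then_adjust`` bases the next offer on the rounded recorded value
    instead of the exact one (a sensitivity variant; the default keeps
    internal arithmetic unrounded).
    """
    if state.trial_index >= N_TRIALS:
        raise TitrationError(
            f"staircase already completed trial {N_TRIALS}; no further offers"
        )
    base = float(state.offer_recorded) if round_then_adjust else state.offer
    delta = state.adjustment if chose_larger else -state.adjustment
    return replace(
        state,
        offer=base + delta,
        adjustment=state.adjustment / 2.0,
        trial_index=state.trial_index + 1,
    )


@dataclass(frozen=True)
class ChoiceRecord:
    """One titration trial as recorded in the choice log."""

    participant_id: str
    timepoint: int
    task: TaskKind
    level_index: int
    cost_value: float
    trial: int
    offer_small: int
    amount_large: float
    chose_larger: bool

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["task"] = self.task.value
        d["chose_larger"] = int(self.chose_larger)
        return d


@dataclass(frozen=True)
class IndifferenceCurve:
    """Five (cost, IP) pairs for one participant × task × time point."""

    participant_id: str
    timepoint: int
    task: TaskKind
    costs: tuple[float, ...]
    ips: tuple[float, ...]
    amount_large: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "task", TaskKind(self.task))
        object.__setattr__(self, "costs", tuple(float(c) for c in self.costs))
        object.__setattr__(self, "ips", tuple(float(v) for v in self.ips))
        if len(self.costs) != len(self.ips):
            raise ValueError("costs and ips must align")
        if any(not 0 <= v <= self.amount_large for v in self.ips):
            raise ValueError("every IP must lie in [0, amount_large]")


ChoiceFn = Callable[[float, float, float], bool]


def run_titration(
    choice_fn: ChoiceFn,
    cost: float,
    amount_large: float,
    *,
    participant_id: str = "agent",
    timepoint: int = 1,
    task: TaskKind = TaskKind.DELAY,
    level_index: int = 1,
    ip_rule: str = "sixth_offer",
    round_then_adjust: bool = False,
) -> tuple[list[ChoiceRecord], int]:
    """Run one six-trial staircase and return its trials and IP.

    Parameters
    ----------
    choice_fn
        Called as ``choice_fn(offer_small, amount_large, cost)``; returns
        True if the agent chooses the larger costly reward.  The offer passed
        is the rounded recorded value, as a participant would see it.
    cost
        The level's cost value (days, odds against, or minutes).
    amount_large
        The fixed larger amount A (3000 by default at the task level).
    ip_rule
        ``"sixth_offer"`` codes the offer presented on the final trial as
        the IP; ``"post_final_adjustment"`` applies one further halving
        adjustment after the sixth choice before coding.

    Returns
    -------
    (records, ip)
        The six :class:`ChoiceRecord` rows and the rounded IP.
    """
    if ip_rule not in ("sixth_offer", "post_final_adjustment"):
        raise ValueError(f"unknown ip_rule {ip_rule!r}")
    state = TitrationState.initial(amount_large)
    records: list[ChoiceRecord] = []
    last_choice = False
    for _ in range(N_TRIALS):
        offer_rec = state.offer_recorded
        try:
            chose_larger = bool(choice_fn(float(offer_rec), amount_large, cost))
        except Exception as exc:  # annotate with trial context
            raise TitrationError(
                f"choice_fn failed on trial {state.trial_index} "
                f"(cost {cost}, offer {offer_rec})"
            ) from exc
        records.append(
            ChoiceRecord(
                participant_id=participant_id,
                timepoint=timepoint,
                task=task,
                level_index=level_index,
                cost_value=cost,
                trial=state.trial_index,
                offer_small=offer_rec,
                amount_large=amount_large,
                chose_larger=chose_larger,
            )
        )
        last_choice = chose_larger
        if state.trial_index < N_TRIALS:
            state = next_offer(state, chose_larger, round_then_adjust)
    if ip_rule == "sixth_offer":
        ip = records[-1].offer_small
    else:
        delta = state.adjustment if last_choice else -state.adjustment
        ip = _round_half_up(state.offer + delta)
    return records, ip


def records_to_frame(records: Iterable[ChoiceRecord]) -> pd.DataFrame:
    """Choice records as the canonical trial table."""
    return pd.DataFrame([r.to_dict() for r in records], columns=TRIAL_COLUMNS)


def curves_to_frame(curves: Iterable[IndifferenceCurve]) -> pd.DataFrame:
    """Indifference curves in long form (one row per cost level)."""
    rows = []
    for c in curves:
        for i, (cost, ip) in enumerate(zip(c.costs, c.ips), start=1):
            rows.append(
                {
                    "participant_id": c.participant_id,
                    "timepoint": c.timepoint,
                    "task": c.task.value,
                    "level_index": i,
                    "cost_value": cost,
                    "ip": ip,
                }
            )
    return pd.DataFrame(rows, columns=IP_COLUMNS)


def extract_ips(
    trials: pd.DataFrame, ip_rule: str = "sixth_offer", n_levels: int = 5
) -> list[IndifferenceCurve]:
    """Extract one indifference curve per (participant, timepoint, task).

    Each block must contain ``n_levels`` complete six-trial staircases with
    a constant larger amount.  Incomplete or inconsistent blocks raise
    :class:`IncompleteBlockError` naming the block rather than being
    silently dropped.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TitrationError(f"trial table lacks columns {missing}")
    curves = []
    for key, block in trials.groupby(["participant_id", "timepoint", "task"], sort=True):
        amounts = block["amount_large"].unique()
        if len(amounts) != 1:
            raise IncompleteBlockError(key, f"amount_large not constant: {sorted(amounts)}")
        amount = float(amounts[0])
        levels = block.groupby("level_index", sort=True)
        if len(levels) != n_levels:
            raise IncompleteBlockError(
                key, f"expected {n_levels} cost levels, found {len(levels)}"
            )
        costs, ips = [], []
        for level_index, level in levels:
            trials_seen = sorted(level["trial"].tolist())
            if trials_seen != list(range(1, N_TRIALS + 1)):
                raise IncompleteBlockError(
                    key,
                    f"level {level_index} has trials {trials_seen}, "
                    f"expected 1..{N_TRIALS}",
                )
            if level["cost_value"].nunique() != 1:
                raise IncompleteBlockError(
                    key, f"level {level_index} has inconsistent cost values"
                )
            costs.append(float(level["cost_value"].iloc[0]))
            final = level.loc[level["trial"] == N_TRIALS].iloc[0]
            if ip_rule == "sixth_offer":
                ip = float(final["offer_small"])
            elif ip_rule == "post_final_adjustment":
                adj = amount / 2.0 ** (N_TRIALS + 1)
                sign = 1.0 if bool(final["chose_larger"]) else -1.0
                ip = float(_round_half_up(final["offer_small"] + sign * adj))
            else:
                raise ValueError(f"unknown ip_rule {ip_rule!r}")
            ips.append(ip)
        order = sorted(range(len(costs)), key=costs.__getitem__)
        curves.append(
            IndifferenceCurve(
                participant_id=str(key[0]),
                timepoint=int(key[1]),
                task=TaskKind(key[2]),
                costs=tuple(costs[i] for i in order),
                ips=tuple(ips[i] for i in order),
                amount_large=amount,
            )
        )
    return curves
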