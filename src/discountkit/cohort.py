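"""Synthetic cohorts of discounting agents.

Generates trial-level choice data with the statistical structure the
downstream stability analysis assumes: each simulated participant carries a
*trait* discounting rate b per task, drawn lognormally across the cohort;
each session perturbs it multiplicatively (*state* noise); and choices are
stochastic through a logistic rule on the subjective-value difference.  The
default design mirrors a three-session study of 23 participants completing
delay, probability, and effort tasks, five cost levels each, six titration
trials per level, with the larger amount fixed at 3,000.

The subjective value of the larger reward follows one of three forms:

* hyperbolic:   V = A / (1 + bX)
* hyperboloid:  V = A / (1 + bX**s)
* power:        V = A - bX**s

where X is the cost, b the discounting rate, and s a scaling exponent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .schedules import CostSchedule, TaskKind, default_schedules
from .titration import ChoiceRecord, records_to_frame, run_titration

__all__ = [
    "ModelForm",
    "AgentSpec",
    "CohortSpec",
    "subjective_value",
    "choice_prob",
    "make_choice_fn",
    "simulate_cohort",
    "TRUTH_COLUMNS",
]

MODEL_FORMS = ("hyperbolic", "hyperboloid", "power")

TRUTH_COLUMNS = [
    "participant_id",
    "timepoint",
    "task",
    "model_form",
    "b_session",
    "s",
    "temperature",
    "trait_b",
]


def subjective_value(
    model_form: str,
    amount: float,
    cost: float,
    b: float,
    s: float = 1.0,
    floor_at_zero: bool = False,
) -> float:
    """Subjective value of an amount at a given cost under a discounting form.

    ``floor_at_zero`` clips the power form at 0, which is how simulated
    agents treat it (a negative value is behaviorally meaningless); model
    fitting uses the raw formula.
    """
    if amount <= 0:
        raise ValueError("amount must be positive")
    if cost < 0:
        raise ValueError("cost must be nonnegative")
    if b < 0:
        raise ValueError("b must be nonnegative")
    if s <= 0:
        raise ValueError("s must be positive")
    if model_form == "hyperbolic":
        v = amount / (1.0 + b * cost)
    elif model_form == "hyperboloid":
        v = amount / (1.0 + b * cost**s)
    elif model_form == "power":
        v = amount - b * cost**s
    else:
        raise ValueError(f"unknown model_form {model_form!r}")
    if floor_at_zero:
        v = max(v, 0.0)
    return v


def choice_prob(
    v_larger: float, v_smaller: float, temperature: float, amount: float
) -> float:
    """Probability of choosing the larger costly reward.

    Logistic in the subjective-value difference scaled by ``temperature * A``
    so that the noise level is independent of the currency scale.  At zero
    temperature the choice is the deterministic argmax, with ties broken
    toward the smaller (immediate / certain / easy) option.
    """
    if temperature < 0:
        raise ValueError("temperature must be nonnegative")
    diff = v_larger - v_smaller
    if temperature == 0:
        return 1.0 if diff > 0 else 0.0
    z = diff / (temperature * amount)
    # guard against overflow for extreme differences
    if z > 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


@dataclass(frozen=True)
class AgentSpec:
    """One session-level agent: a discounting form plus its parameters."""

    model_form: str = "hyperbolic"
    b: float = 0.01
    s: float = 1.0
    temperature: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_form not in MODEL_FORMS:
            raise ValueError(f"unknown model_form {self.model_form!r}")
        if self.b <= 0:
            raise ValueError("b must be positive")
        if self.s <= 0:
            raise ValueError("s must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be nonnegative")


def make_choice_fn(agent: AgentSpec, rng: np.random.Generator | None):
    """Build a ``choice_fn(offer, amount, cost)`` for :func:`run_titration`.

    The larger reward's value follows the agent's discounting form (power
    floored at 0); the smaller offer is taken at face value.  With a ``rng``
    and positive temperature the choice is sampled; otherwise deterministic.
    """

    def choice_fn(offer: float, amount: float, cost: float) -> bool:
        v_larger = subjective_value(
            agent.model_form, amount, cost, agent.b, agent.s, floor_at_zero=True
        )
        p = choice_prob(v_larger, offer, agent.temperature, amount)
        if agent.temperature == 0 or rng is None:
            return p > 0.5
        return bool(rng.random() < p)

    return choice_fn


# Default trait medians of b per task, in the units of each cost axis
# (1/day, 1/odds-against, 1/minute).  Chosen to put typical ordinal AUC
# values in the mid-range of [0, 1] for the default schedules.
DEFAULT_TRAIT_LOG_MEAN: dict[str, float] = {
    "delay": math.log(0.01),
    "probability": math.log(1.0),
    "effort": math.log(0.03),
}


@dataclass(frozen=True)
class CohortSpec:
    """Design and population parameters for a simulated cohort.

    ``trait_log_sd`` controls between-participant (trait) spread of the
    discounting rate; ``state_log_sd`` the session-to-session (state)
    perturbation within a participant.  Both act multiplicatively on b,
    keeping it positive.  With the default temperature the stochastic
    choice rule adds further trial-level noise.
    """

    n_participants: int = 23
    n_timepoints: int = 3
    model_form: str = "hyperbolic"
    trait_log_mean: Mapping[str, float] | None = None
    trait_log_sd: float = 0.8
    state_log_sd: float = 0.4
    s_log_mean: float = 0.0
    s_log_sd: float = 0.0
    temperature: float = 0.1
    amount_large: float = 3000.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.n_timepoints < 1:
            raise ValueError("need at least 1 timepoint")
        for name in ("trait_log_sd", "state_log_sd", "s_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.model_form not in MODEL_FORMS:
            raise ValueError(f"unknown model_form {self.model_form!r}")
        if self.temperature < 0:
            raise ValueError("temperature must be nonnegative")
        if self.amount_large <= 0:
            raise ValueError("amount_large must be positive")

    def resolved_trait_log_mean(self) -> dict[str, float]:
        base = dict(DEFAULT_TRAIT_LOG_MEAN)
        if self.trait_log_mean is not None:
            base.update({str(k): float(v) for k, v in dict(self.trait_log_mean).items()})
        return base

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["trait_log_mean"] = self.resolved_trait_log_mean()
        return d


def simulate_cohort(
    spec: CohortSpec,
    schedules: Mapping[TaskKind, CostSchedule] | None = None,
    ip_rule: str = "sixth_offer",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort; returns (trial table, true-parameter table).

    Seeds are spawned hierarchically (master → participant → session →
    trial stream), so the same ``master_seed`` reproduces the tables
    bit-for-bit and per-participant streams are independent.
    """
    if schedules is None:
        schedules = default_schedules()
    tasks = sorted(schedules, key=lambda t: t.value)
    trait_means = spec.resolved_trait_log_mean()

    master = np.random.SeedSequence(spec.master_seed)
    participant_seeds = master.spawn(spec.n_participants)

    all_records: list[ChoiceRecord] = []
    truth_rows: list[dict] = []
    width = len(str(spec.n_participants))
    for p_idx, p_seed in enumerate(participant_seeds):
        pid = f"P{p_idx + 1:0{width}d}"
        p_rng = np.random.Generator(np.random.PCG64(p_seed))
        traits = {
            task: float(
                np.exp(trait_means[task.value] + spec.trait_log_sd * p_rng.normal())
            )
            for task in tasks
        }
        s_value = float(np.exp(spec.s_log_mean + spec.s_log_sd * p_rng.normal()))
        session_seeds = p_seed.spawn(spec.n_timepoints)
        for t_idx, s_seed in enumerate(session_seeds):
            timepoint = t_idx + 1
            s_rng = np.random.Generator(np.random.PCG64(s_seed))
            for task in tasks:
                b_session = traits[task] * float(
                    np.exp(spec.state_log_sd * s_rng.normal())
                )
                agent = AgentSpec(
                    model_form=spec.model_form,
                    b=b_session,
                    s=s_value,
                    temperature=spec.temperature,
                )
                schedule = schedules[task]
                for level_index, cost in enumerate(schedule.raw_costs, start=1):
                    trial_rng = np.random.Generator(np.random.PCG64(s_seed.spawn(1)[0]))
                    records, _ = run_titration(
                        make_choice_fn(agent, trial_rng),
                        cost,
                        spec.amount_large,
                        participant_id=pid,
                        timepoint=timepoint,
                        task=task,
                        level_index=level_index,
                        ip_rule=ip_rule,
                    )
                    all_records.extend(records)
                truth_rows.append(
                    {
                        "participant_id": pid,
                        "timepoint": timepoint,
                        "task": task.value,
                        "model_form": spec.model_form,
                        "b_session": b_session,
                        "s": s_value,
                        "temperature": spec.temperature,
                        "trait_b": traits[task],
                    }
                )
    trials = records_to_frame(all_records)
    trials["seed"] = spec.master_seed
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return trials, truth
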