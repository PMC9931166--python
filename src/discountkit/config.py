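"""Run configuration: serializable settings for the full pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .cohort import CohortSpec
from .schedules import CostSchedule, TaskKind, default_schedules

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    Defaults mirror the reference study design: 23 participants, 3 time
    points, 3 tasks x 5 levels x 6 trials, larger amount 3,000.
    """

    amount: float = 3000.0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    schedules: dict = field(default_factory=lambda: {
        k.value: v.to_dict() for k, v in default_schedules().items()
    })
    ip_rule: str = "sixth_offer"
    anchor: bool = True
    anchor_y: float = 1.0
    kappa: float = 1.0
    zscore_scope: str = "pooled"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortSpec(**self.cohort)
        # keep the cohort's seed and amount in lockstep with the run's
        if (
            self.cohort.master_seed != self.master_seed
            or self.cohort.amount_large != self.amount
        ):
            d = self.cohort.to_dict()
            d["master_seed"] = self.master_seed
            d["amount_large"] = self.amount
            self.cohort = CohortSpec(**d)

    def schedule_objects(self) -> dict[TaskKind, CostSchedule]:
        return {
            TaskKind(k): CostSchedule.from_dict(v) for k, v in self.schedules.items()
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable hash of the canonical JSON form, for provenance stamps."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
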