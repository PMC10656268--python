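"""Object Space task bookkeeping: exploration totals and discrimination index.

The task presents two objects per trial; across five training trials and a
24 h test, preference for the object in the novel location indexes memory.
The discrimination index is

    DI = (t_novel - t_familiar) / (t_novel + t_familiar)

with DI > 0 a novel-location preference, DI = 0 no preference.  Conditions:
``Stable`` (simple location memory), ``Overlapping`` (cumulative memory) and
``HomeCage`` (no-learning control); treatments ``VEH``/``CBD``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import InvalidArgumentError

__all__ = ["BehaviorTrial", "discrimination_index", "session_table"]


@dataclass(frozen=True)
class BehaviorTrial:
    animal: str
    condition: str  # Stable | Overlapping | HomeCage
    treatment: str  # VEH | CBD
    trial: str  # "1".."5" or "TEST"
    t_novel: float  # s
    t_familiar: float  # s

    def __post_init__(self) -> None:
        if self.t_novel < 0 or self.t_familiar < 0:
            raise InvalidArgumentError("exploration times must be non-negative")


def discrimination_index(t_novel: float, t_familiar: float) -> float:
    """(novel - familiar) / total exploration; NaN when total is zero."""
    if t_novel < 0 or t_familiar < 0:
        raise InvalidArgumentError("exploration times must be non-negative")
    total = t_novel + t_familiar
    if total == 0:
        return float("nan")
    return (t_novel - t_familiar) / total


def session_table(trials: Sequence[BehaviorTrial]) -> pd.DataFrame:
    """Tidy long table of DI and total exploration per trial.

    Columns: animal, condition, treatment, trial, t_novel_s, t_familiar_s,
    total_exploration_s, di, is_test, vehicle_memory.  ``vehicle_memory``
    marks animals whose vehicle-condition test DI is positive (the "showed
    memory in the vehicle condition" inclusion filter) as a column only —
    never applied silently.
    """
    keys = [(t.animal, t.condition, t.treatment, t.trial) for t in trials]
    if len(set(keys)) != len(keys):
        raise InvalidArgumentError("duplicate (animal, condition, treatment, trial)")
    df = pd.DataFrame(
        {
            "animal": [t.animal for t in trials],
            "condition": [t.condition for t in trials],
            "treatment": [t.treatment for t in trials],
            "trial": [str(t.trial) for t in trials],
            "t_novel_s": [t.t_novel for t in trials],
            "t_familiar_s": [t.t_familiar for t in trials],
        }
    )
    df["total_exploration_s"] = df.t_novel_s + df.t_familiar_s
    df["di"] = [
        discrimination_index(a, b) for a, b in zip(df.t_novel_s, df.t_familiar_s)
    ]
    df["is_test"] = df.trial.str.upper() == "TEST"
    veh_test = df[(df.treatment == "VEH") & df.is_test]
    remembered = set(veh_test.loc[veh_test.di > 0, "animal"])
    df["vehicle_memory"] = df.animal.isin(remembered)
    return df


def read_trials_csv(path) -> list[BehaviorTrial]:
    df = pd.read_csv(path)
    return [
        BehaviorTrial(
            animal=str(r.animal),
            condition=str(r.condition),
            treatment=str(r.treatment),
            trial=str(r.trial),
            t_novel=float(r.t_novel_s),
            t_familiar=float(r.t_familiar_s),
        )
        for r in df.itertuples()
    ]
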