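"""Stochastic simulation of individual nurse-year trajectories.

Each trajectory makes one categorical draw per daily cycle from the current
state's transition row and stops early on absorption into the quit state
(departed staff contribute nothing for the rest of the year).  The
HIE-related cost of a trajectory is sick days times the daily leave cost
plus, if the nurse resigned, the one-time replacement cost; the program
participation fee is not part of HIE-related cost.

Reproducibility: every trajectory gets its own RNG sub-stream derived from
a master seed and a (stream, index) counter, so batches are bitwise
reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import CohortConfig, CostParameters, TransitionMatrix

__all__ = [
    "TrajectoryRecord",
    "trajectory_rng",
    "simulate_trajectory",
    "simulate_batch",
    "batch_to_frame",
    "no_effect_fraction_analytic",
]


@dataclass(frozen=True)
class TrajectoryRecord:
    """Outcome of one simulated nurse-year."""

    sick_days: int
    quit: bool
    quit_day: Optional[int]
    hie_cost: float

    def __post_init__(self) -> None:
        if (self.quit_day is not None) != self.quit:
            raise ValueError("quit_day must be present iff the trajectory quit")
        if self.sick_days < 0 or self.hie_cost < 0:
            raise ValueError("sick_days and hie_cost must be nonnegative")


def trajectory_rng(master_seed: int, stream: int, index: int) -> np.random.Generator:
    """Counter-based sub-stream: reproducible independent of draw order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(stream, index))
    )


def simulate_trajectory(
    matrix: TransitionMatrix,
    config: CohortConfig,
    costs: CostParameters,
    rng: np.random.Generator,
) -> TrajectoryRecord:
    """Simulate one nurse-year: one categorical draw per cycle, early stop on quit."""
    p = matrix.probs
    p_stay = p[0, 0]
    p_stay_or_leave = p[0, 0] + p[0, 1]
    p_recover = p[1, 0]

    init = config.initial_distribution
    if init[0] == 1.0:
        state = 0
    else:
        u0 = rng.random()
        state = 0 if u0 < init[0] else (1 if u0 < init[0] + init[1] else 2)

    sick_days = 0
    quit_day: Optional[int] = 0 if state == 2 else None
    if state != 2:
        u = rng.random(config.horizon_days)
        for t in range(1, config.horizon_days + 1):
            ut = u[t - 1]
            if state == 0:
                if ut < p_stay:
                    continue
                if ut < p_stay_or_leave:
                    state = 1
                    sick_days += 1
                else:
                    quit_day = t
                    break
            else:  # on leave; no direct quit from this state
                if ut < p_recover:
                    state = 0
                else:
                    sick_days += 1

    quit = quit_day is not None
    cost = sick_days * costs.cost_per_sick_day + (costs.cost_per_quit if quit else 0.0)
    return TrajectoryRecord(sick_days=sick_days, quit=quit, quit_day=quit_day, hie_cost=cost)


def simulate_batch(
    matrix: TransitionMatrix,
    config: CohortConfig,
    costs: CostParameters,
    n: int,
    master_seed: int,
    stream: int = 0,
) -> list[TrajectoryRecord]:
    """Simulate ``n`` independent trajectories under one parameter set."""
    return [
        simulate_trajectory(matrix, config, costs, trajectory_rng(master_seed, stream, i))
        for i in range(n)
    ]


def batch_to_frame(records: list[TrajectoryRecord], scenario: str) -> pd.DataFrame:
    """Flat table of a batch, one row per trajectory, ready for CSV export."""
    return pd.DataFrame(
        {
            "scenario": scenario,
            "replicate": np.arange(len(records)),
            "sick_days": [r.sick_days for r in records],
            "quit": [r.quit for r in records],
            "quit_day": [r.quit_day for r in records],
            "hie_cost": [r.hie_cost for r in records],
        }
    )


def no_effect_fraction_analytic(matrix: TransitionMatrix, horizon: int) -> float:
    """Probability of a fully uneventful year: never leaving the unaffected state.

    Equals the stay-unaffected probability raised to the number of cycles.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    return float(matrix.probs[0, 0]) ** horizon
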