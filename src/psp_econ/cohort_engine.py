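"""Deterministic expectation engine: cohort propagation and budget impact.

Expected state occupancies are obtained by repeated left-multiplication of
the state distribution with the daily transition kernel.  Costs follow the
occupancy-counting convention: one cycle spent in the leave state is one
sick day; absorption into the quit state is charged the one-time
replacement cost, with no proration for when in the year it happens and no
backfilling of departed staff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import CohortConfig, CostParameters, TransitionMatrix

__all__ = [
    "OccupancySeries",
    "ScenarioResult",
    "ComparisonResult",
    "ConfigurationError",
    "propagate",
    "expected_sick_days",
    "expected_quit_fraction",
    "scenario_costs",
    "compare_scenarios",
]

_OCC_TOL = 1e-10


class ConfigurationError(ValueError):
    """Scenario results were produced under incompatible configurations."""


@dataclass(frozen=True)
class OccupancySeries:
    """State-distribution trajectory: row t is the distribution after t cycles."""

    occupancy: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        occ = np.array(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 3 or occ.shape[0] < 1:
            raise ValueError(f"occupancy must be (T+1, 3), got {occ.shape}")
        if np.any(occ < -_OCC_TOL):
            raise ValueError("occupancies must be nonnegative")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > _OCC_TOL:
            raise ValueError("each occupancy vector must sum to 1")
        if np.any(np.diff(occ[:, 2]) < -_OCC_TOL):
            raise ValueError("quit-state occupancy must be nondecreasing")
        occ.setflags(write=False)
        object.__setattr__(self, "occupancy", occ)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1


def propagate(matrix: TransitionMatrix, config: CohortConfig) -> OccupancySeries:
    """Propagate the initial distribution over ``horizon_days`` daily cycles."""
    occ = np.empty((config.horizon_days + 1, 3))
    occ[0] = config.initial_distribution
    kernel = matrix.probs
    for t in range(1, config.horizon_days + 1):
        occ[t] = occ[t - 1] @ kernel
    return OccupancySeries(occ)


def expected_sick_days(series: OccupancySeries) -> float:
    """Expected number of cycles spent on leave, summed over cycles 1..T.

    Cycle 0 holds the initial distribution and is not counted; under the
    base case it carries no leave occupancy anyway.
    """
    return float(series.occupancy[1:, 1].sum())


def expected_quit_fraction(series: OccupancySeries) -> float:
    """Probability of having been absorbed into the quit state by the horizon."""
    return float(series.occupancy[-1, 2])


@dataclass(frozen=True)
class ScenarioResult:
    """Budget-impact summary of one scenario (one column of the annual report).

    ``cost_hie_total`` (sick days + replacements) is the institution's
    HIE-attributable loss; ``cost_total`` additionally includes the program
    participation fee.  Per-person figures divide by the cohort size.
    """

    n_staff: int
    expected_sick_days_per_person: float
    expected_quit_fraction: float
    sick_days_total: float
    dropouts_total: float
    cost_sick_days: float
    cost_dropouts: float
    cost_program: float
    cost_hie_total: float
    cost_total: float
    cost_per_person: float
    hie_cost_per_person: float


def scenario_costs(
    series: OccupancySeries, costs: CostParameters, config: CohortConfig
) -> ScenarioResult:
    """Scale per-person expectations to the institution and attach costs.

    All fields are exact (unrounded); display rounding is left to report
    writers.
    """
    n = config.n_staff
    esd = expected_sick_days(series)
    eqf = expected_quit_fraction(series)
    cost_sick = esd * n * costs.cost_per_sick_day
    cost_drop = eqf * n * costs.cost_per_quit
    cost_prog = costs.psp_cost_per_person * n
    cost_hie = cost_sick + cost_drop
    total = cost_hie + cost_prog
    return ScenarioResult(
        n_staff=n,
        expected_sick_days_per_person=esd,
        expected_quit_fraction=eqf,
        sick_days_total=esd * n,
        dropouts_total=eqf * n,
        cost_sick_days=cost_sick,
        cost_dropouts=cost_drop,
        cost_program=cost_prog,
        cost_hie_total=cost_hie,
        cost_total=total,
        cost_per_person=total / n,
        hie_cost_per_person=cost_hie / n,
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Scenario comparison at the institutional scale.

    The gross saving compares HIE-attributable per-person costs only; the
    net saving additionally charges the program fee difference.  The
    published headline figures are gross.
    """

    saving_per_person_gross: float
    saving_per_person_net: float
    budget_impact_total: float


def compare_scenarios(no_psp: ScenarioResult, psp: ScenarioResult) -> ComparisonResult:
    if no_psp.n_staff != psp.n_staff:
        raise ConfigurationError(
            f"scenarios were run with different cohort sizes: "
            f"{no_psp.n_staff} vs {psp.n_staff}"
        )
    n = no_psp.n_staff
    gross = no_psp.hie_cost_per_person - psp.hie_cost_per_person
    net = gross - (psp.cost_program - no_psp.cost_program) / n
    return ComparisonResult(
        saving_per_person_gross=gross,
        saving_per_person_net=net,
        budget_impact_total=gross * n,
    )
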