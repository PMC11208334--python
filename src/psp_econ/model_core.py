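"""Parameter types and the daily transition kernel of the workforce model.

The model tracks one nurse through three states on a daily cycle:

* state 1 — unaffected (at work),
* state 2 — on sick leave,
* state 3 — has quit (absorbing).

Each day carries an identical, independent risk ``q_hie`` of a high-impact
event (HIE): a stressful incident such as involvement in an adverse patient
event.  Conditional on whether an HIE occurred, the nurse may start a sick
leave or resign; a peer support program (PSP) lowers the post-HIE hazards.
The unconditional daily transition probabilities are the event-probability
mixtures of the high- and low-impact hazards, and together they define a
row-stochastic 3x3 kernel.

States are numbered 1..3 in the public vocabulary (reports, accessors);
internal arrays are zero-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "N_STATES",
    "STATE_LABELS",
    "DomainError",
    "InfeasibleParametersError",
    "HazardParameters",
    "CostParameters",
    "CohortConfig",
    "TransitionMatrix",
    "combine_event_probability",
    "build_transition_matrix",
]

N_STATES = 3
STATE_LABELS = ("unaffected", "leave", "quit")

_ROW_SUM_TOL = 1e-12


class DomainError(ValueError):
    """A parameter lies outside its mathematical domain."""


class InfeasibleParametersError(ValueError):
    """Hazards imply a total daily outflow probability above one."""


def _require_probability(name: str, value: float) -> None:
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise DomainError(f"{name} must be a probability in [0, 1], got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0.0:
        raise DomainError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class HazardParameters:
    """Event-conditioned daily hazards for one scenario.

    Parameters
    ----------
    q_hie
        Daily probability of a high-impact event (base case 0.02).
    p_dayoff_high, p_dayoff_low
        Probability of starting a sick leave on an HIE day / non-HIE day.
    p_quit_high, p_quit_low
        Probability of resigning on an HIE day / non-HIE day.
    recovery_prob
        Daily probability of returning from leave to the unaffected state.
        The base case is 1/7, i.e. a mean leave length of seven days.
    """

    q_hie: float
    p_dayoff_high: float
    p_dayoff_low: float
    p_quit_high: float
    p_quit_low: float
    recovery_prob: float

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_probability(f.name, getattr(self, f.name))
        outflow = combine_event_probability(
            self.q_hie, self.p_dayoff_high, self.p_dayoff_low
        ) + combine_event_probability(self.q_hie, self.p_quit_high, self.p_quit_low)
        if outflow > 1.0:
            raise InfeasibleParametersError(
                f"combined daily leave+quit probability {outflow} exceeds 1"
            )


@dataclass(frozen=True)
class CostParameters:
    """Unit costs, in whatever currency the configuration declares.

    ``psp_cost_per_person`` is the annual program participation fee; it is
    zero in a no-program scenario and never enters per-trajectory
    HIE-related costs.
    """

    cost_per_sick_day: float
    cost_per_quit: float
    psp_cost_per_person: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            _require_nonnegative(f.name, getattr(self, f.name))

    def without_program_fee(self) -> "CostParameters":
        return CostParameters(self.cost_per_sick_day, self.cost_per_quit, 0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort size, horizon (in daily cycles) and initial state distribution."""

    n_staff: int = 1000
    horizon_days: int = 365
    initial_distribution: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if int(self.n_staff) != self.n_staff or self.n_staff < 1:
            raise DomainError(f"n_staff must be an integer >= 1, got {self.n_staff!r}")
        if int(self.horizon_days) != self.horizon_days or self.horizon_days < 0:
            raise DomainError(
                f"horizon_days must be an integer >= 0, got {self.horizon_days!r}"
            )
        dist = tuple(float(x) for x in self.initial_distribution)
        if len(dist) != N_STATES:
            raise DomainError("initial_distribution must have 3 entries")
        for x in dist:
            _require_probability("initial_distribution entry", x)
        if abs(sum(dist) - 1.0) > 1e-9:
            raise DomainError("initial_distribution must sum to 1")
        object.__setattr__(self, "initial_distribution", dist)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 3x3 daily transition kernel.

    Row/column order follows the state numbering: unaffected, leave, quit.
    The quit state is absorbing and there is no direct leave -> quit
    transition: a resignation can only happen from the unaffected state.
    """

    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        p = np.array(self.probs, dtype=float)
        if p.shape != (N_STATES, N_STATES):
            raise DomainError(f"transition matrix must be 3x3, got shape {p.shape}")
        if np.any(p < 0) or np.any(p > 1):
            raise DomainError("transition probabilities must lie in [0, 1]")
        row_sums = p.sum(axis=1)
        if np.max(np.abs(row_sums - 1.0)) > _ROW_SUM_TOL:
            raise DomainError(f"rows must sum to 1 within {_ROW_SUM_TOL}: {row_sums}")
        if not np.array_equal(p[2], [0.0, 0.0, 1.0]):
            raise DomainError("quit state must be absorbing: row 3 must be (0, 0, 1)")
        if p[1, 2] != 0.0:
            raise DomainError("no direct leave -> quit transition: p_23 must be 0")
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    def p(self, i: int, j: int) -> float:
        """Transition probability with 1-based state indices (``p(1, 2)`` etc.)."""
        if not (1 <= i <= N_STATES and 1 <= j <= N_STATES):
            raise DomainError(f"state indices must be in 1..{N_STATES}")
        return float(self.probs[i - 1, j - 1])

    def as_array(self) -> np.ndarray:
        return self.probs.copy()

    def rounded(self, decimals: int = 4) -> np.ndarray:
        """Matrix rounded for display, as printed in published tables."""
        return np.round(self.probs, decimals)


def combine_event_probability(q_hie: float, p_high: float, p_low: float) -> float:
    """Mix a high- and a low-impact hazard by the daily HIE probability.

    Returns ``q_hie * p_high + (1 - q_hie) * p_low``, the unconditional
    daily probability of the outcome.
    """
    _require_probability("q_hie", q_hie)
    _require_probability("p_high", p_high)
    _require_probability("p_low", p_low)
    return q_hie * p_high + (1.0 - q_hie) * p_low


def build_transition_matrix(h: HazardParameters) -> TransitionMatrix:
    """Construct the daily transition kernel from event-conditioned hazards.

    All arithmetic is unrounded: published tables show 4-decimal roundings
    of these entries, but downstream results (year-long survival powers,
    expected occupancies) are sensitive to the dropped digits, so the exact
    mixtures are kept.
    """
    p_12 = combine_event_probability(h.q_hie, h.p_dayoff_high, h.p_dayoff_low)
    p_13 = combine_event_probability(h.q_hie, h.p_quit_high, h.p_quit_low)
    if p_12 + p_13 > 1.0:
        raise InfeasibleParametersError(
            f"p_12 + p_13 = {p_12 + p_13} exceeds 1; hazards are infeasible"
        )
    r = h.recovery_prob
    probs = np.array(
        [
            [1.0 - p_12 - p_13, p_12, p_13],
            [r, 1.0 - r, 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    return TransitionMatrix(probs)
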