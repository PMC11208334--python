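"""Base-case parameter fixtures and an exact path-enumeration oracle.

`paper_base_case` returns the published base-case parameterization of the
German acute-care nursing cohort: a 1,000-nurse institution followed for
365 daily cycles, with a 2% daily high-impact-event probability, scenario
hazards for starting a leave or resigning, a mean leave length of seven
days, and unit costs of 500 per sick day, 75,000 per replacement and an
annual program fee of 550 per participant.

`enumerate_paths_oracle` is a brute-force verifier: it sums probabilities
over every possible state sequence of a short horizon and therefore checks
the matrix-propagation engine and the trajectory simulator without sharing
any code with them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    CohortConfig,
    CostParameters,
    HazardParameters,
    TransitionMatrix,
)
from .sensitivity import perturb_pair

__all__ = [
    "ORACLE_MAX_HORIZON",
    "FixtureBundle",
    "OracleResult",
    "paper_base_case",
    "make_perturbed_draws",
    "enumerate_paths_oracle",
]

# 3^8 = 6,561 paths: enumeration stays sub-second.
ORACLE_MAX_HORIZON = 8


@dataclass(frozen=True)
class FixtureBundle:
    """Base-case parameter sets plus optional labelled perturbed draws."""

    hazards_no_psp: HazardParameters
    hazards_psp: HazardParameters
    costs: CostParameters
    cohort: CohortConfig
    currency: str = "EUR"
    perturbed_draws: tuple = field(default=(), repr=False)

    def costs_for_scenario(self, psp: bool) -> CostParameters:
        """Unit costs with the program fee zeroed in the no-program arm."""
        return self.costs if psp else self.costs.without_program_fee()


def paper_base_case() -> FixtureBundle:
    """The published base-case parameter set, exact and unrounded."""
    return FixtureBundle(
        hazards_no_psp=HazardParameters(
            q_hie=0.02,
            p_dayoff_high=0.05,
            p_dayoff_low=0.002,
            p_quit_high=0.0068,
            p_quit_low=0.0003,
            recovery_prob=1.0 / 7.0,
        ),
        hazards_psp=HazardParameters(
            q_hie=0.02,
            p_dayoff_high=0.03,
            p_dayoff_low=0.002,
            p_quit_high=0.0034,
            p_quit_low=0.0001,
            recovery_prob=1.0 / 7.0,
        ),
        costs=CostParameters(
            cost_per_sick_day=500.0,
            cost_per_quit=75_000.0,
            psp_cost_per_person=550.0,
        ),
        cohort=CohortConfig(n_staff=1000, horizon_days=365),
    )


def make_perturbed_draws(
    bundle: FixtureBundle, n: int, cv: float = 0.10, seed: int = 0
) -> FixtureBundle:
    """Attach ``n`` labelled, seeded coupled parameter draws to a bundle."""
    draws = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        h_a, h_b, c = perturb_pair(
            bundle.hazards_no_psp, bundle.hazards_psp, bundle.costs, cv, rng
        )
        draws.append(
            {
                "label": f"draw_{i:05d}",
                "hazards_no_psp": h_a,
                "hazards_psp": h_b,
                "costs": c,
            }
        )
    return FixtureBundle(
        hazards_no_psp=bundle.hazards_no_psp,
        hazards_psp=bundle.hazards_psp,
        costs=bundle.costs,
        cohort=bundle.cohort,
        currency=bundle.currency,
        perturbed_draws=tuple(draws),
    )


@dataclass(frozen=True)
class OracleResult:
    expected_sick_days: float
    quit_probability: float
    no_effect_probability: float


def enumerate_paths_oracle(matrix: TransitionMatrix, horizon: int) -> OracleResult:
    """Exact expectations by summing over all 3^horizon state sequences.

    Starts from the all-unaffected state.  A sick day is one cycle spent in
    the leave state (cycles 1..horizon); a quit is absorption by the final
    cycle; no effect means never leaving the unaffected state.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if horizon > ORACLE_MAX_HORIZON:
        raise ValueError(
            f"horizon {horizon} exceeds the enumeration cap {ORACLE_MAX_HORIZON}"
        )
    kernel = matrix.as_array()
    e_sick = 0.0
    p_quit = 0.0
    p_no_effect = 1.0 if horizon == 0 else 0.0
    for path in itertools.product(range(3), repeat=horizon):
        prob = 1.0
        state = 0
        sick = 0
        for nxt in path:
            prob *= kernel[state, nxt]
            if prob == 0.0:
                break
            state = nxt
            sick += nxt == 1
        else:
            e_sick += prob * sick
            p_quit += prob * (state == 2)
            p_no_effect += prob * all(s == 0 for s in path)
    return OracleResult(
        expected_sick_days=e_sick,
        quit_probability=p_quit,
        no_effect_probability=p_no_effect,
    )
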