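"""Probabilistic sensitivity analysis (PSA) and the signed-rank robustness test.

The PSA repeats the evaluation for many pairs of trajectories (one arm with
the support program, one without).  For every pair, each scalar model
parameter is redrawn from a normal distribution centred on its base value
with a standard deviation of 10% of that value, truncated at zero by
rejection; probabilities are additionally rejected above one.  Parameters
shared by the two scenarios (HIE incidence, hazards with a common base
value, recovery rate, unit costs) take the same perturbed value in both
arms of a pair, while scenario-specific hazards are drawn around their own
base values.  Trajectory randomness is independent across arms — only the
parameters are coupled.

Robustness of the cost conclusion is assessed with a one-sided Wilcoxon
signed-rank test on the paired cost differences, and the break-even shift
is the largest uniform handicap added to the program arm's costs under
which the cost advantage stays significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .model_core import (
    CohortConfig,
    CostParameters,
    DomainError,
    HazardParameters,
    InfeasibleParametersError,
    TransitionMatrix,
    build_transition_matrix,
)
from .trajectory_sim import simulate_trajectory, trajectory_rng

__all__ = [
    "PSAConfig",
    "PSAResult",
    "SamplingError",
    "DegenerateDataError",
    "NoPositiveShiftError",
    "perturb_value",
    "perturb_parameters",
    "perturb_pair",
    "run_psa",
    "signed_rank_test",
    "find_break_even_shift",
]

_MAX_REDRAWS = 10_000

_HAZARD_FIELDS = (
    "q_hie",
    "p_dayoff_high",
    "p_dayoff_low",
    "p_quit_high",
    "p_quit_low",
    "recovery_prob",
)


class SamplingError(RuntimeError):
    """Rejection sampling failed to find a feasible draw."""


class DegenerateDataError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


class NoPositiveShiftError(ValueError):
    """The unshifted test already fails to reject at the given level."""


@dataclass(frozen=True)
class PSAConfig:
    n_pairs: int = 100_000
    cv: float = 0.10
    master_seed: int = 0
    quantile_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not 0.0 < self.quantile_level < 1.0:
            raise ValueError("quantile_level must lie in (0, 1)")


@dataclass(frozen=True)
class PSAResult:
    """Paired Monte Carlo summary; per-pair cost arrays kept for reuse."""

    no_effect_fraction_no_psp: float
    no_effect_fraction_psp: float
    cost_quantile_no_psp: float
    cost_quantile_psp: float
    signed_rank_p: float
    n_pairs_used: int
    quantile_level: float
    costs_no_psp: np.ndarray = field(repr=False)
    costs_psp: np.ndarray = field(repr=False)

    def summary(self) -> dict:
        """JSON-ready summary without the per-pair arrays."""
        return {
            "n_pairs_used": self.n_pairs_used,
            "quantile_level": self.quantile_level,
            "no_effect_fraction_no_psp": self.no_effect_fraction_no_psp,
            "no_effect_fraction_psp": self.no_effect_fraction_psp,
            "cost_quantile_no_psp": self.cost_quantile_no_psp,
            "cost_quantile_psp": self.cost_quantile_psp,
            "signed_rank_p": self.signed_rank_p,
        }


def perturb_value(
    base: float,
    cv: float,
    rng: np.random.Generator,
    upper: Optional[float] = None,
    max_redraws: int = _MAX_REDRAWS,
) -> float:
    """Draw Normal(base, cv*base) truncated to [0, upper] by rejection.

    Truncation by rejection (rather than clipping) keeps the support
    constraint without creating a point mass at the bound; at base values
    the bound sits ten standard deviations away, so the truncation bias is
    negligible.
    """
    sd = cv * base
    if sd == 0.0:
        return base
    for _ in range(max_redraws):
        x = rng.normal(base, sd)
        if x >= 0.0 and (upper is None or x <= upper):
            return x
    raise SamplingError(f"no feasible draw around {base} after {max_redraws} attempts")


def perturb_parameters(
    hazards: HazardParameters,
    costs: CostParameters,
    cv: float,
    rng: np.random.Generator,
    max_redraws: int = _MAX_REDRAWS,
) -> tuple[HazardParameters, CostParameters]:
    """Independently perturb every hazard and unit cost of one scenario.

    Hazard draws are rejected above one, and a whole draw is rejected if the
    implied transition row is infeasible.  The program fee is passed through
    unperturbed: it never enters HIE-related trajectory costs.
    """
    for _ in range(max_redraws):
        try:
            h = HazardParameters(
                **{f: perturb_value(getattr(hazards, f), cv, rng, upper=1.0) for f in _HAZARD_FIELDS}
            )
        except (DomainError, InfeasibleParametersError):
            continue
        c = CostParameters(
            cost_per_sick_day=perturb_value(costs.cost_per_sick_day, cv, rng),
            cost_per_quit=perturb_value(costs.cost_per_quit, cv, rng),
            psp_cost_per_person=costs.psp_cost_per_person,
        )
        return h, c
    raise SamplingError("no feasible joint parameter draw")


def perturb_pair(
    hazards_no_psp: HazardParameters,
    hazards_psp: HazardParameters,
    costs: CostParameters,
    cv: float,
    rng: np.random.Generator,
    max_redraws: int = _MAX_REDRAWS,
) -> tuple[HazardParameters, HazardParameters, CostParameters]:
    """One coupled parameter draw for the two arms of a PSA pair.

    A hazard whose base value coincides in the two scenarios (HIE incidence,
    the low-impact day-off hazard, the recovery rate) receives a single draw
    used in both arms; scenario-specific hazards are drawn separately around
    their own base values.  Unit costs get one draw shared by both arms.
    """
    for _ in range(max_redraws):
        draws_a: dict[str, float] = {}
        draws_b: dict[str, float] = {}
        for f in _HAZARD_FIELDS:
            base_a = getattr(hazards_no_psp, f)
            base_b = getattr(hazards_psp, f)
            if base_a == base_b:
                draws_a[f] = draws_b[f] = perturb_value(base_a, cv, rng, upper=1.0)
            else:
                draws_a[f] = perturb_value(base_a, cv, rng, upper=1.0)
                draws_b[f] = perturb_value(base_b, cv, rng, upper=1.0)
        try:
            h_a = HazardParameters(**draws_a)
            h_b = HazardParameters(**draws_b)
        except (DomainError, InfeasibleParametersError):
            continue
        c = CostParameters(
            cost_per_sick_day=perturb_value(costs.cost_per_sick_day, cv, rng),
            cost_per_quit=perturb_value(costs.cost_per_quit, cv, rng),
            psp_cost_per_person=costs.psp_cost_per_person,
        )
        return h_a, h_b, c
    raise SamplingError("no feasible joint parameter draw for the pair")


def run_psa(
    base_no_psp: HazardParameters,
    base_psp: HazardParameters,
    costs: CostParameters,
    config: CohortConfig,
    psa: PSAConfig,
) -> PSAResult:
    """Run the paired probabilistic sensitivity analysis.

    Per pair: one coupled perturbed parameter draw, then one simulated
    trajectory per arm with independent randomness.  Returns the no-effect
    fractions, the per-arm empirical cost quantiles (linear interpolation)
    and the one-sided signed-rank p-value at zero shift.
    """
    n = psa.n_pairs
    costs_a = np.empty(n)
    costs_b = np.empty(n)
    for i in range(n):
        prng = trajectory_rng(psa.master_seed, 0, i)
        h_a, h_b, c = perturb_pair(base_no_psp, base_psp, costs, psa.cv, prng)
        m_a = build_transition_matrix(h_a)
        m_b = build_transition_matrix(h_b)
        costs_a[i] = simulate_trajectory(
            m_a, config, c, trajectory_rng(psa.master_seed, 1, i)
        ).hie_cost
        costs_b[i] = simulate_trajectory(
            m_b, config, c, trajectory_rng(psa.master_seed, 2, i)
        ).hie_cost

    try:
        p_value = signed_rank_test(costs_a, costs_b, shift=0.0)
    except DegenerateDataError:
        p_value = math.nan
    return PSAResult(
        no_effect_fraction_no_psp=float(np.mean(costs_a == 0.0)),
        no_effect_fraction_psp=float(np.mean(costs_b == 0.0)),
        cost_quantile_no_psp=float(np.quantile(costs_a, psa.quantile_level)),
        cost_quantile_psp=float(np.quantile(costs_b, psa.quantile_level)),
        signed_rank_p=p_value,
        n_pairs_used=n,
        quantile_level=psa.quantile_level,
        costs_no_psp=costs_a,
        costs_psp=costs_b,
    )


def _exact_upper_tail(w_plus: float, ranks: np.ndarray) -> float:
    """Exact P(W+ >= w_plus) by dynamic programming over the rank multiset.

    Midranks are multiples of 1/2, so doubling makes them integers and the
    null distribution of 2*W+ is the coefficient sequence of
    prod_i (1 + x^(2 r_i)) over 2^n equiprobable sign assignments.
    """
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[: total + 1 - r].copy()
    w2 = int(math.ceil(2.0 * w_plus - 1e-9))
    return float(counts[w2:].sum() / 2.0 ** len(ranks))


def signed_rank_test(
    paired_costs_no_psp: np.ndarray,
    paired_costs_psp: np.ndarray,
    shift: float = 0.0,
) -> float:
    """One-sided Wilcoxon signed-rank p-value on paired cost differences.

    Tests the alternative that no-program costs exceed program-arm costs
    after the program arm is handicapped by ``shift``.  Zero differences
    are discarded; tied absolute differences receive mid-ranks.  The exact
    null distribution is enumerated for up to 25 informative pairs; beyond
    that a normal approximation with tie-corrected variance and continuity
    correction is used.
    """
    x = np.asarray(paired_costs_no_psp, dtype=float)
    y = np.asarray(paired_costs_psp, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-d arrays of equal length")
    d = x - (y + shift)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return _exact_upper_tail(w_plus, ranks)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    variance = n * (n + 1) * (2 * n + 1) / 24.0 - float(
        ((tie_counts**3 - tie_counts) / 48.0).sum()
    )
    z = (w_plus - mean - 0.5) / math.sqrt(variance)
    return float(stats.norm.sf(z))


def find_break_even_shift(
    paired_costs_no_psp: np.ndarray,
    paired_costs_psp: np.ndarray,
    alpha: float = 0.05,
    resolution: float = 0.50,
    max_shift: float = 1e9,
) -> float:
    """Largest program-arm cost handicap keeping the one-sided p-value <= alpha.

    Relies on the p-value being nondecreasing in the shift; the boundary is
    located by bracket doubling followed by bisection to ``resolution``
    currency units.
    """
    def p_at(shift: float) -> float:
        # a fully degenerate shift (all differences zero) cannot reject
        try:
            return signed_rank_test(paired_costs_no_psp, paired_costs_psp, shift)
        except DegenerateDataError:
            return 1.0

    if p_at(0.0) > alpha:
        raise NoPositiveShiftError(f"p-value at zero shift already exceeds {alpha}")
    lo, hi = 0.0, resolution
    while p_at(hi) <= alpha:
        lo = hi
        hi *= 2.0
        if hi > max_shift:
            raise RuntimeError(f"break-even shift exceeds search cap {max_shift}")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if p_at(mid) <= alpha:
            lo = mid
        else:
            hi = mid
    return math.floor(lo / resolution) * resolution
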