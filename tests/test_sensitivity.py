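"""Parameter perturbation, the signed-rank test and the break-even search."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from psp_econ import (
    PSAConfig,
    find_break_even_shift,
    no_effect_fraction_analytic,
    build_transition_matrix,
    perturb_pair,
    perturb_parameters,
    run_psa,
    signed_rank_test,
)
from psp_econ.sensitivity import (
    DegenerateDataError,
    NoPositiveShiftError,
    perturb_value,
)


def brute_force_upper_tail(d):
    """Independent oracle: enumerate all 2^n sign assignments directly."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = sum(
        1
        for signs in itertools.product((0, 1), repeat=len(d))
        if sum(r for s, r in zip(signs, ranks) if s) >= w_obs - 1e-9
    )
    return count / 2 ** len(d)


def test_all_positive_distinct_differences_give_exact_tail():
    x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
    y = np.array([9.0, 17.0, 26.0, 36.0, 45.0])
    assert signed_rank_test(x, y) == pytest.approx(1 / 32)


@given(
    d=st.lists(st.integers(-5, 5), min_size=1, max_size=12).filter(
        lambda v: any(x != 0 for x in v)
    )
)
def test_exact_tail_matches_sign_enumeration(d):
    """DP distribution equals brute-force enumeration, ties and zeros included."""
    d = np.array(d, dtype=float)
    ours = signed_rank_test(d, np.zeros_like(d))
    assert ours == pytest.approx(brute_force_upper_tail(d), abs=1e-12)


def test_large_sample_tail_matches_reference_implementation():
    """Normal approximation (tie-corrected, continuity-corrected) vs scipy."""
    rng = np.random.default_rng(11)
    for _ in range(5):
        x = rng.integers(0, 15, 80).astype(float)
        y = rng.integers(0, 15, 80).astype(float)
        d = x - y
        d = d[d != 0]
        reference = stats.wilcoxon(
            d, alternative="greater", zero_method="wilcox",
            correction=True, method="approx",
        ).pvalue
        assert signed_rank_test(x, y) == pytest.approx(reference, abs=1e-12)


def test_all_zero_differences_degenerate():
    x = np.ones(10)
    with pytest.raises(DegenerateDataError):
        signed_rank_test(x, x)


def test_p_value_monotone_in_shift():
    rng = np.random.default_rng(5)
    x = rng.exponential(1000.0, 400)
    y = rng.exponential(800.0, 400)
    grid = [0.0, 50.0, 100.0, 200.0, 400.0, 800.0]
    p_values = [signed_rank_test(x, y, s) for s in grid]
    assert p_values == sorted(p_values)


def test_break_even_equals_constant_difference():
    """With x = y + d exactly, significance is lost just above shift d."""
    rng = np.random.default_rng(2)
    y = rng.exponential(1000.0, 30)
    x = y + 100.0
    shift = find_break_even_shift(x, y, alpha=0.05)
    assert 95.0 <= shift <= 100.0


def test_break_even_requires_initial_significance():
    rng = np.random.default_rng(3)
    y = rng.exponential(1000.0, 30)
    with pytest.raises(NoPositiveShiftError):
        find_break_even_shift(y, y + 500.0, alpha=0.05)


def test_perturb_value_cv_zero_is_identity():
    rng = np.random.default_rng(0)
    assert perturb_value(0.42, 0.0, rng) == 0.42
    assert perturb_value(0.0, 0.3, rng) == 0.0


def test_perturbed_parameters_stay_in_domain(bundle):
    rng = np.random.default_rng(9)
    for _ in range(300):
        h, c = perturb_parameters(bundle.hazards_no_psp, bundle.costs, 0.5, rng)
        for name in ("q_hie", "p_dayoff_high", "p_dayoff_low",
                     "p_quit_high", "p_quit_low", "recovery_prob"):
            assert 0.0 <= getattr(h, name) <= 1.0
        assert c.cost_per_sick_day >= 0 and c.cost_per_quit >= 0
        assert c.psp_cost_per_person == bundle.costs.psp_cost_per_person


def test_perturbed_parameters_unbiased_at_base(bundle):
    """Sample means stay within 3 SE of the base values (truncation negligible)."""
    rng = np.random.default_rng(4)
    n, cv = 3000, 0.10
    draws = [perturb_parameters(bundle.hazards_no_psp, bundle.costs, cv, rng)
             for _ in range(n)]
    for attr, base in (
        ("q_hie", 0.02),
        ("p_dayoff_high", 0.05),
        ("recovery_prob", 1 / 7),
    ):
        mean = np.mean([getattr(h, attr) for h, _ in draws])
        assert abs(mean - base) < 3 * cv * base / np.sqrt(n)
    cost_mean = np.mean([c.cost_per_quit for _, c in draws])
    assert abs(cost_mean - 75_000) < 3 * cv * 75_000 / np.sqrt(n)


def test_pair_draw_couples_shared_parameters(bundle):
    rng = np.random.default_rng(6)
    for _ in range(50):
        h_a, h_b, c = perturb_pair(
            bundle.hazards_no_psp, bundle.hazards_psp, bundle.costs, 0.10, rng
        )
        # shared base values -> one draw; scenario-specific -> separate draws
        assert h_a.q_hie == h_b.q_hie
        assert h_a.p_dayoff_low == h_b.p_dayoff_low
        assert h_a.recovery_prob == h_b.recovery_prob
        assert h_a.p_dayoff_high != h_b.p_dayoff_high
        assert h_a.p_quit_high != h_b.p_quit_high


def test_psa_reproducible_under_fixed_seed(bundle):
    psa = PSAConfig(n_pairs=300, cv=0.10, master_seed=42)
    args = (bundle.hazards_no_psp, bundle.hazards_psp, bundle.costs, bundle.cohort)
    a = run_psa(*args, psa)
    b = run_psa(*args, psa)
    assert np.array_equal(a.costs_no_psp, b.costs_no_psp)
    assert np.array_equal(a.costs_psp, b.costs_psp)
    assert a.summary() == b.summary()


def test_psa_without_perturbation_matches_analytic_fractions(bundle, matrix_no_psp, matrix_psp):
    """At cv = 0 the no-effect fractions are binomial around the analytic values."""
    psa = PSAConfig(n_pairs=1500, cv=0.0, master_seed=13)
    result = run_psa(
        bundle.hazards_no_psp, bundle.hazards_psp, bundle.costs, bundle.cohort, psa
    )
    n = psa.n_pairs
    for frac, matrix in (
        (result.no_effect_fraction_no_psp, matrix_no_psp),
        (result.no_effect_fraction_psp, matrix_psp),
    ):
        p = no_effect_fraction_analytic(matrix, bundle.cohort.horizon_days)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)
    assert result.signed_rank_p < 0.05  # program arm cheaper even unperturbed
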