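# Methods

## The cohort model

The model follows one nurse (equivalently, the expectation over a cohort)
through three states on a daily cycle: unaffected, on sick leave, quit.
Quitting is absorbing — departed staff are not backfilled within the
modelled year — and a resignation can only happen from the unaffected
state: the kernel has no leave→quit entry, consistent with the published
transition table, which lists none.  Each day carries an independent
probability `q_hie` of a high-impact event; the daily leave and quit
probabilities are the event-probability mixtures of high- and low-impact
hazards.  Starting a leave and quitting on the same day are treated as
mutually exclusive competing outcomes whose probabilities add, so
`p11 = 1 − p12 − p13` with no renormalization.

Expected occupancies come from propagating the state distribution with the
kernel over the horizon.  A *sick day* is one cycle of leave-state
occupancy, summed over cycles 1..365 (cycle 0 holds the initial, all-
unaffected distribution).  Costs are linear: sick days × daily cost, plus
the one-time replacement cost weighted by the probability of having been
absorbed by year end (no proration by quit date), plus the program fee.
There is no discounting, no half-cycle correction and no terminal
valuation; the one-year horizon makes them immaterial here.

### Unrounded kernel arithmetic

The published transition table shows 4-decimal roundings.  The engine keeps
the exact mixtures (`p11 = 0.99661` without and `0.997274` with the
program; `p13 = 0.000166` with the program) because year-long quantities
amplify the dropped digits: the probability of an uneventful year is
`p11^365`, which is 36.9% at the exact value but 37.3% at the rounded
0.9973.  Likewise the recovery probability is stored as exactly 1/7 (mean
leave of seven days), not 0.1429.  Rounding the constructed kernels to four
decimals reproduces every printed table cell, which the tests assert.

### Scenario comparison

The annual report's "Total costs" and "Cost per Person" rows cover
HIE-attributable costs (sick days + replacements) only, matching the
published table's arithmetic; the per-person saving quoted as the headline
(≈ 6,672 EUR) is this gross difference.  Because the prose mentions the
program fee while the table arithmetic does not subtract it, the
comparison reports both figures explicitly: gross, and net of the 550 EUR
fee difference.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `q_hie` | 0.02 | /day | high-impact event probability |
| `p_dayoff_high` / `p_dayoff_low` | 0.05 / 0.002 (0.03 / 0.002 with PSP) | /day | leave hazard on HIE / ordinary days |
| `p_quit_high` / `p_quit_low` | 0.0068 / 0.0003 (0.0034 / 0.0001 with PSP) | /day | quit hazard on HIE / ordinary days |
| `recovery_prob` | 1/7 | /day | return from leave (7-day mean leave) |
| `cost_per_sick_day` | 500 | EUR | productivity loss per leave day |
| `cost_per_quit` | 75,000 | EUR | replacement hire (≈ annual salary) |
| `psp_cost_per_person` | 550 | EUR/year | program participation fee |
| `n_staff`, `horizon_days` | 1,000, 365 | — | institution size, daily cycles |

These defaults are the base case of the German acute-care nursing setting
the model was built for; all are exposed through the YAML/JSON
configuration.

## Trajectory simulation

`simulate_trajectory` makes one categorical draw per cycle from the current
state's kernel row and stops at absorption; a quit day contributes the
replacement cost but no sick-day cost for that cycle.  The HIE-related cost
of a trajectory excludes the program fee — this is what makes "zero-cost"
trajectories well defined (no leave, no quit), and roughly 29% (no program)
vs 37% (program) of nurse-years are of that kind, matching the analytic
`p11^365`.

Each trajectory draws from its own RNG sub-stream,
`SeedSequence(master_seed, spawn_key=(stream, index))`, so batches are
bitwise reproducible regardless of execution order or batch splitting.

## Probabilistic sensitivity analysis

Per pair, every hazard and the two unit costs are redrawn from
`Normal(base, 0.10 · base)`; draws are rejected below zero (and above one
for probabilities) rather than clipped, which keeps the support constraint
without a point mass at the bound — at these base values the bound is ten
standard deviations out, so rejection is essentially never triggered and
the truncation bias is negligible.  A draw implying an infeasible kernel
would also be rejected; that, too, is unreachable at base values.

Coupling across a pair's two arms was a genuinely open design choice; the
package couples **parameters, not trajectories**: a parameter whose base
value coincides in the two scenarios (HIE incidence, low-impact day-off
hazard, recovery rate, unit costs) takes one draw used in both arms, while
scenario-specific hazards are drawn independently around their own base
values.  Full independence would inflate the variance of the paired cost
differences; common random numbers for the trajectories themselves would
understate it.  The quit hazard on ordinary days differs between scenarios
(0.0003 vs 0.0001), so it is treated as scenario-specific even though it is
not a program lever per se.  Because the published analysis does not state
its coupling, the 95% cost quantiles are checked with a loose (5%)
tolerance; at 10,000+ pairs they land within about 2–3% of the reference
values under any seed tried.

### The signed-rank robustness test

The one-sided Wilcoxon signed-rank test is applied to the paired cost
differences, alternative "no-program costs exceed (shifted) program
costs".  Zero differences are discarded and tied absolute differences get
mid-ranks — the standard treatment; the published analysis names the test
but no variant.  For ≤ 25 informative pairs the exact null distribution is
enumerated by dynamic programming over the (doubled, hence integer) rank
multiset; above that, a normal approximation with tie-corrected variance
and a 0.5 continuity correction is used.  Both regimes agree to machine
precision with an independent full sign-enumeration oracle and with
`scipy.stats.wilcoxon`.

The *break-even shift* is the largest uniform handicap added to every
program-arm cost at which the one-sided p-value stays ≤ α.  The p-value is
nondecreasing in the shift, so the boundary is found by bracket doubling
plus bisection to a 0.50-EUR resolution.  A shift making every difference
exactly zero yields an undefined test; the search treats it as
non-significant.  The break-even point depends on the number of pairs
(more pairs → more power → a larger tolerable handicap), so it is checked
as an order-of-magnitude quantity, not a constant.

## Problem sizes

The deterministic engine is a 365-step 3-vector recursion (milliseconds).
Tests run the PSA at 10,000 pairs and the acceptance script at 20,000
pairs — at those sizes the no-effect fractions carry a binomial standard
error below 0.5 percentage points and the 95% quantile varies by well
under 1% across seeds, which is ample against the tolerances used.  The
CLI default remains 100,000 pairs (≈ 20 s).

## What the tests do and do not show

The synthetic inputs are the model's own parameter space: base-case values
and their truncated-normal perturbations.  Passing tests therefore show
that the implementation reproduces the model's arithmetic and
distributional behaviour — they say nothing about whether the hazard and
cost assumptions describe any real institution.  In particular the model
assumes i.i.d. daily events (no clustering of adverse events, no
individual frailty), a single homogeneous staff group, no backfilling
within the year, and no indirect costs (productivity or care-quality
losses), all of which bias the estimated saving conservative rather than
anti-conservative.

## Numerical notes and degenerate inputs

* Kernel rows must sum to 1 within 1e−12; occupancy vectors within 1e−10.
* The path-enumeration oracle caps at horizon 8 (3^8 paths) and agrees
  with matrix propagation to 1e−12.
* Horizon 0 is legal everywhere and yields the initial distribution, zero
  sick days and zero cost.
* Empirical quantiles use the linear-interpolation definition
  (`numpy.quantile` default).
* A PSA with a single pair produces a valid summary with the p-value
  flagged as undefined when no informative difference exists.
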