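# Published base case: 1,000-nurse institution, 365 daily cycles.
currency: EUR
cohort:
  n_staff: 1000
  horizon_days: 365
  initial_distribution: [1.0, 0.0, 0.0]
costs:
  cost_per_sick_day: 500.0
  cost_per_quit: 75000.0
  psp_cost_per_person: 550.0
hazards:
  no_psp:
    q_hie: 0.02
    p_dayoff_high: 0.05
    p_dayoff_low: 0.002
    p_quit_high: 0.0068
    p_quit_low: 0.0003
    recovery_prob: 0.14285714285714285   # exactly 1/7: mean leave of 7 days
  psp:
    q_hie: 0.02
    p_dayoff_high: 0.03
    p_dayoff_low: 0.002
    p_quit_high: 0.0034
    p_quit_low: 0.0001
    recovery_prob: 0.14285714285714285
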