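# Hypothetical multilevel diabetes-prevention trial: a six-period complete
# closed-cohort stepped wedge over 65 towns (13 per sequence), individual
# coaching (IL) randomized 50/50 within each town, ride-voucher funding (CL)
# rolled out along the wedge.  Incremental effects with a linear time trend,
# identity link for a continuous standardized outcome; time-on-treatment
# covariates scaled by 1/3 so each delta is the effect after three periods
# (six months) on that component.
design:
  n_periods: 6
  n_sequences: 5
  clusters_per_sequence: 13
  cohort_size: 15
  il_split: 0.5
  cohort_type: closed_cohort
mean_model:
  effect_model: incremental
  time_trend: linear
  link: identity
  theta: [0.0, 0.0, 0.1, 0.15, -0.1]   # (beta0, beta1, d_IL, d_CL, d_Int)
  scaling: [3.0, 3.0, 3.0]
correlation:
  family: block_exchangeable
  within_period: 0.05
  inter_period: 0.025
  within_individual: 0.5
variance:
  family: gaussian
  dispersion: 1.0
contrasts:
  - label: combined
    effects: [il, cl, interaction]
    alpha: 0.05
  - label: il
    effects: [il]
    alpha: 0.1
  - label: cl
    effects: [cl]
    alpha: 0.1
  - label: interaction
    effects: [interaction]
    alpha: 0.1
    in_goal: false   # reported alongside, not part of the 80% goal
plan:
  power_goal: 0.8
  n_max: 200
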