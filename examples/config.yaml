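# Demo pipeline configuration: simulated cohort with a planted stickiness
# shift in the MS-female cell, fitted with all three models.
#   prl-qlearn run examples/config.yaml --out run
seed: 1
task:
  p_reward_correct: 0.8
  p_reward_incorrect: 0.2
  reversal_criterion: 8
  max_trials: 200
cohort:
  n_per_cell: 4
  sessions_per_phase: 3
  phases: [pre_stress, post_stress]
  default_params: {alpha_rew: 0.451, alpha_nonrew: 0.451, beta: 0.305, kappa: 0.0}
  overrides:
    - {group: MS, sex: female, kappa: 0.3}
filters:
  max_reversals: 4
  sessions_per_phase: 3
models: [M_ab, M_abk, M_a2bk]
q0: 0.5
fdr: 0.05
measure_model: M_a2bk
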