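# Scenario 2: selection between the RW and Kalman RW models.
# Reference design: backward blocking (AB+ then A+, then non-reinforced test).
scenario: 2
description: >
  Two cues A and B plus their compound AB; datasets are simulated in equal
  proportions from the RW and KRW models and analyzed by BIC model selection.
  The utility is the correct-selection indicator.
cues: [A, B]
compounds: [[A, B]]
model_space: [rw, krw]
analysis: {procedure: bic_selection, n_starts: 5}
utility: selection
sigma_obs:
  value: 0.5
  assumed: true
  provenance: >
    not printed in the main text; chosen a priori so that single-subject
    discrimination of RW vs KRW under the backward-blocking reference design
    is imperfect, consistent with the reported near-chance reference accuracy
    and with realistic conditioned-response noise.
trials:
  stage1: 20
  stage2: 20
  test: 10
  assumed: true
  provenance: per-stage trial counts are not printed in the main text
point_priors:
  assumed: true
  provenance: >
    the source simulation study's parameter values are not printed in the
    main text; plausible Kalman-filter conditioning values assumed.
  rw: {alpha: 0.3, sigma_obs: 0.5}
  krw: {w0_var: 1.0, q_diffusion: 0.01, r_noise_var: 0.25, sigma_obs: 0.5}
vague_priors:
  rw:
    alpha: [uniform, 0.0, 1.0]
    sigma_obs: [uniform, 0.01, 1.0]
  krw:
    w0_var: [halfnormal, 1.0, 1.0e-4]
    q_diffusion: [halfnormal, 0.1, 1.0e-4]
    r_noise_var: [halfnormal, 1.0, 1.0e-4]
    sigma_obs: [uniform, 0.01, 1.0]
design_space:
  parameterization: stage_wise   # 2 stages x (2 cue + 3 contingency) = 10 vars
  trials_per_stage: [25, 25]
optimization:
  max_iterations: 300
  n_initial_points: 10
  sims_per_model: 32
evaluation:
  sims_per_combination: 256      # per (ground-truth model x design)
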