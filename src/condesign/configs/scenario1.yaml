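# Scenario 1: accurate estimation of the Rescorla-Wagner learning rate
# with a single cue whose reinforcement probability varies periodically.
scenario: 1
description: >
  One CS, conditioned responses simulated from the RW model; the analysis is
  maximum-likelihood estimation of the learning rate alpha and the utility is
  the negated absolute estimation error. The reference design is acquisition
  (P(US|CS)=0.5) followed by extinction (P(US|CS)=0) of equal length.
cues: [CS]
compounds: []
model_space: [rw]
analysis: {procedure: mle, model: rw, target_param: alpha, n_starts: 5}
utility: estimation
n_trials:
  value: 160
  assumed: true
  provenance: stage lengths are not printed in the main text; 80 + 80 assumed
sigma_obs:
  value: 0.1
  assumed: true
  provenance: described only as moderate observation noise
reference_design:
  name: acquisition_extinction
  p1: 0.5
  p2: 0.0
  half_period: 0.5
evaluation_priors:            # point ground truths (LA / MA / HA)
  LA: {alpha: 0.1}
  MA: {alpha: 0.2}
  HA: {alpha: 0.3}
design_priors:
  vague:                      # VA: uniform over alpha (and the noise level)
    rw:
      alpha: [uniform, 0.0, 1.0]
      sigma_obs: [uniform, 0.01, 1.0]
  point: from_evaluation_prior   # PA: exact ground-truth alpha
design_space: {parameterization: periodic}   # P1, P2 and T (3 variables)
optimization:
  max_iterations: 300
  n_initial_points: 10
  sims_per_model: 32
evaluation:
  sims_per_combination: 256
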