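# condesign

Simulation-based Bayesian optimization of classical-conditioning experiment
designs.

## The problem

Associative-learning theory offers a growing space of computational models —
the Rescorla-Wagner (RW) delta rule, its Kalman-filter extension (KRW) that
tracks a covariance over associative weights, and hybrid
Rescorla-Wagner/Pearce-Hall (RWPH) models with dynamic per-cue learning rates
("associabilities"). Flexible models are hard to tell apart, and their
parameters are hard to pin down, unless the experiment is designed to expose
their differences. `condesign` is for researchers planning classical
(Pavlovian) conditioning studies who want to *compute* a good design rather
than guess one.

## The method

A conditioning experiment is formalized as a trial-generating Markov chain:
on each trial a stimulus (CS) is drawn with probability P(CS) and a binary
outcome (US) follows with contingency P(US|CS). Those transition
probabilities are the design variables, in one of two low-dimensional
parameterizations — **stage-wise** (constant probabilities per block of
trials) or **periodic** (each probability is a square wave with levels P1,
P2 and half-period T).

A design d is scored by its expected utility under a prior p(m, θ) over
candidate models and parameters:

    U(d) = E[ u(analysis(D), ground truth) ],   D ~ p(D | d, m, θ)

estimated by Monte Carlo: sample a ground truth, simulate trial-wise
(CS, US, CR) triplets, run the planned analysis — bounded maximum-likelihood
estimation, or model selection by BIC = −2·logL + k·ln(n) — and score it
(negated absolute parameter-estimation error, or the correct-selection
indicator). The noisy, expensive map d ↦ U(d) is maximized with
Gaussian-process Bayesian optimization (Matérn-5/2 surrogate with a fitted
noise term, expected-improvement acquisition); simplex constraints on cue
probabilities are absorbed into a stick-breaking decoding so the optimizer
works on a plain unit box. Competing designs are then compared with effect
sizes and 95% CIs: common language effect size (CLES) with percentile
bootstrap, exact Clopper-Pearson intervals for accuracies, and Woolf
odds-ratio intervals with the Haldane-Anscombe correction.

Three shipped scenario configurations exercise the full workflow:

1. **Learning-rate estimation** — one cue, periodic reinforcement; reference
   design: acquisition (P(US|CS)=0.5) then extinction (0).
2. **RW vs KRW selection** — cues A, B and compound AB; reference:
   backward blocking (AB+ then A+ then unreinforced test).
3. **RW vs RWPH-variant selection** — models differing in learning mechanism
   *and* response mapping (weights, associabilities, or a mixture);
   reference: reversal learning at partial reinforcement.

## Worked example

Evaluate the backward-blocking reference design for the RW-vs-KRW
model-selection goal (`examples/03_expected_utility.py`):

```text
backward-blocking reference design, 64 simulations
model-selection accuracy: 0.578 +- 0.062 (SE)
  ground truth   rw: recovered 32/32 times
  ground truth  krw: recovered 5/32 times
```

The mean of the 0-1 utilities is the design's model-selection accuracy.
Near-chance overall accuracy with perfect RW recovery and poor KRW recovery
is the classic signature of an under-informative design: both models fit the
simple data about equally well, so the BIC complexity penalty defaults to
the simpler model. Optimizing the stage-wise design variables
(`examples/04_optimize_design.py`, or scenario 2's `optimize` mode) raises
this accuracy substantially.

The other examples build and simulate designs (`01`), fit and select models
(`02`), and compare designs with CLES/odds-ratio intervals (`05`). The same
workflow is scriptable from a shell:

```sh
condesign run-scenario --scenario 2 --mode evaluate-reference --seed 0 --out out/
condesign run-scenario --scenario 2 --mode optimize --seed 0 --out out/ \
    --iterations 40 --sims-per-eval 24
condesign run-scenario --scenario 2 --mode evaluate-optimized --seed 0 --out out/
condesign run-scenario --scenario 2 --mode compare --seed 0 --out out/
```

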