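# Methods

## Experiment model

A classical-conditioning experiment is a sequence of independent trials; each
trial draws one presentable stimulus (an elemental cue or a compound such as
AB) from the cue-presentation probabilities P(CS), then a binary outcome from
the contingency P(US|CS). These transition probabilities of the
trial-generating Markov chain are the design variables. Two parameterizations
keep the optimization low-dimensional:

* **stage-wise** — probabilities constant within contiguous stages; covers
  acquisition-extinction, blocking, reversal and similar classical designs.
* **periodic** — each probability is a square wave with levels P1 and P2 and
  a shared half-period T ∈ (0, 1] expressed as a fraction of the trial count.
  The block length is `ceil(T * n_trials)` (ceil so that T = 1 yields a
  constant-P1 schedule and no zero-length blocks arise); trial t (0-based)
  uses P1 when `floor(t / block)` is even.

Compound presentation is a single draw of the compound label, not
independent element draws — on an AB trial both elements are active in the
stimulus vector, but "AB" is one arm of the cue lottery. Trial indexing is
0-based internally; serialized CSVs use a 1-based `trial` column.

**Design vectors.** The optimizer sees the unit box [0,1]^d. Cue-probability
simplices are encoded with a stick-breaking transform (k−1 free coordinates
per k-simplex; the last probability is the residual), so *every* box point
decodes to a valid design and no rejection or penalty is needed. The
resulting dimensionalities: scenario 1 (periodic, one cue) d = 3 (P1, P2, T);
scenario 2 (2 stages × {A, B, AB}) d = 10; scenario 3 (2 stages × {A, B})
d = 6. For the periodic decoding, T is floored at 1/n_trials so the decoded
design is always valid.

## Learning models

All models respond to the cue *before* the outcome: the conditioned response
on trial t is the pre-outcome prediction plus homoscedastic Gaussian noise
with s.d. σ_obs. The US is coded r ∈ {0,1} with asymptote λ fixed at 1
(scale is absorbed by the weights). Initial weights are 0.

* **RW**: δ = λr − x·w; w ← w + αδx. Fitted parameters: α ∈ [0,1],
  σ_obs ∈ [0.01, 1] (k = 2).
* **KRW**: a Kalman filter over weights. Per trial: Σ ← Σ + qI (weight
  diffusion), gain k = Σx / (xᵀΣx + σ_r²), w ← w + k(r − xᵀw),
  Σ ← Σ − k xᵀΣ, symmetrized after each update so Σ stays PSD under
  round-off. Initial covariance is w0_var·I, prior mean 0. Fitted:
  w0_var, q, σ_r² ∈ [1e-4, 10], σ_obs (k = 4). The off-diagonal covariance
  learned during compound training is what produces backward blocking.
* **RWPH hybrids**: δ = r − xᵀV; for presented cues V_i ← V_i + κ·α_i·δ and
  α_i ← η|δ| + (1−η)α_i; absent cues unchanged. Response mapping: xᵀV
  (RWPH(V)), xᵀα (RWPH(α); used directly without extra scaling, any scale
  being partially absorbed by σ_obs), or (1−ω)xᵀV + ωxᵀα (RWPH(V+α)).
  Fitted: κ, η, α0 (and ω for the mixture) in [0,1], plus σ_obs
  (k = 4 or 5). With η = 0 the hybrid reduces exactly to RW with rate κ·α0;
  this nesting identity is asserted in the tests.

The exact KRW/RWPH recursions are not uniquely fixed by the surrounding
literature's prose; the forms above are frozen as this package's normative
equations and are implemented twice — readable single-step functions (the
reference, also used for simulation and latent traces) and JIT-compiled
whole-sequence kernels used inside fitting, with a test asserting agreement
to 1e-12.

## Analysis, utility, optimization

**Fitting** is bounded maximum likelihood (equivalently MAP with uniform box
priors): 5 multi-start L-BFGS-B searches by default, starts uniform in the
5–95% interior of the bounds, parameter tolerance ~1e-8, bounds enforced by
the optimizer (not penalties). σ_obs is always fitted and counted in k —
assuming the designer knows the noise level would flatter every design.
**Selection** minimizes BIC with n = number of trials (one response per
trial); ties break toward fewer parameters, then declaration order.

**Expected utility** is a Monte-Carlo mean over simulated experiments:
sample a ground truth from the design prior (balanced per-model blocks when
the model prior is uniform), simulate, analyze, score. Utilities are framed
as maximization: −|α̂ − α| for estimation, 1{selected = truth} for
selection. A failed analysis is scored as the worst case (0, or a
configurable −1 penalty for estimation) and counted — dropping failures
would bias utilities optimistically. Per-simulation utilities and records
are retained for CLES, odds ratios and confusion matrices downstream.

**Bayesian optimization** uses a GP surrogate (constant × anisotropic
Matérn-5/2 + white noise, y-normalized, hyperparameters refit each
iteration) over the unit box, with Latin-hypercube initial points (default
10) and expected improvement (exploration offset ξ = 0.01) maximized over
1024 random candidates plus L-BFGS polish from the top 3. When EI collapses
to numerical zero (a fully-explained noiseless objective) the proposal
exploits the GP posterior mean instead. Termination is a fixed iteration
budget. Because observations are Monte-Carlo noisy, the returned design is
the evaluated point with the highest GP *posterior mean*, not the highest
raw observation (the raw argmax is optimistically biased); the trace's
incumbent column is the running max of observations. Per-evaluation seeds
derive deterministically from (master seed, iteration), so runs are
reproducible without freezing the simulation noise across iterations.

## Comparison statistics

CLES is computed over all cross pairs of independent simulations (ties count
0.5); its CI is a percentile bootstrap (default 1000 resamples) resampling
the two designs' utility vectors independently, matching the unpaired CLES
definition. Accuracies get exact Clopper-Pearson beta-quantile intervals.
Odds ratios use Woolf's log-scale CI; 0.5 is added to all four cells only
when a zero cell exists (Haldane-Anscombe), with a flag to always add.
No p-values are reported: simulation counts are arbitrary, so only effect
sizes with CIs are meaningful.

## Scenario configurations and assumed values

The three shipped YAML configs define the study conditions. Values the
surrounding literature does not print are flagged `assumed: true` with a
provenance note and live in the configs, not in code:

* per-stage trial counts — scenario 1: 160 (80 + 80); scenario 2:
  20 AB+ / 20 A+ / 10 test; scenario 3: 60 + 60 at partial reinforcement
  0.7;
* observation noise — σ_obs = 0.1 in scenario 1 ("moderate" noise; yields
  learning-rate errors almost all below 0.1). For scenarios 2–3, σ_obs =
  0.5: an a priori likelihood-ratio analysis of the backward-blocking
  design shows that at σ ≈ 0.1 the ~5 unreinforced B-test trials alone
  (KRW predicts ≈ 0, RW ≈ 0.5) would overwhelm the BIC penalty and make
  reference-design discrimination nearly perfect, which contradicts the
  near-chance reference accuracies these scenarios are known to produce;
  σ = 0.5 is also a realistic single-subject signal-to-noise for
  conditioned responses;
* point-prior parameter values — scenario 2: RW α = 0.3; KRW w0_var = 1,
  q = 0.01, σ_r² = 0.25; scenario 3: κ = 0.5, η = 0.7, α0 = 0.5 → 0.7,
  ω = 0.5, with nested models using parameter subsets (RW's α = κ·α0).
  Vague priors are uniform for bounded parameters and half-normal for
  variances.

## Problem sizes

Design evaluation uses the configured 256 simulations per (ground truth ×
design) where the checks call for it (scenario 2: 512 total; scenario 3
reduced to 256 total in the shipped checks). The acceptance script and the
optimization-improvement tests run Bayesian optimization at a reduced
budget — 20–40 iterations with 16–24 simulations per evaluation, versus 300
iterations × 32 per model in a full study — chosen as this package's
desk-scale defaults; a user reproducing a full overnight optimization only
needs to raise `max_iterations` and `sims_per_evaluation`.

## What the simulations do and do not show

The generator *is* the model space: simulated responses come from the same
model families the analysis fits, so recovery results show what the designs
can distinguish *under correct specification*, plus Gaussian homoscedastic
noise and trial-level (not continuous-time) dynamics. Real conditioning data
add model misspecification, non-Gaussian and heteroscedastic response noise,
habituation/attention effects, and timing effects that trial-level models
cannot capture — passing tests here say nothing about those. Design
optimality is always relative to the declared model space, priors, analysis
and utility.

## Known limitations

* Group-level/hierarchical analyses, fully Bayesian posteriors, and
  trial-by-trial adaptive optimization are out of scope; analyses are
  single-subject MLE/BIC.
* The expected-utility surface is evaluated by independent Monte Carlo per
  iteration; common random numbers across iterations are not used (the
  per-iteration seed derivation is deterministic but distinct).
* Stochastic end-to-end results (optimized-design accuracies, CLES values)
  depend on the reduced optimization budget and the assumed config values
  above; reference-design accuracies land within ~1–2 percentage points of
  mid-50s–60% selection accuracy but their exact placement is sensitive to
  the assumed σ_obs, trial counts and point priors.
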