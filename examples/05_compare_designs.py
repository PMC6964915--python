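"""Compare two designs with effect sizes and confidence intervals.

Evaluates the backward-blocking reference design and a hand-tweaked
alternative for RW-vs-KRW model selection, then reports the common language
effect size (probability of superiority), per-design accuracies with exact
Clopper-Pearson CIs, and the odds ratio of correct identification.
"""

import numpy as np

from condesign import (
    CueSet,
    Stage,
    StageWiseDesign,
    compare_utility_vectors,
    expected_design_utility,
    load_scenario,
)

config = load_scenario(2)
prior = config.evaluation_prior()
reference = config.reference_design()

# alternative: keep presenting B alongside the A+ stage, unreinforced
z = {"A": 0.0, "B": 0.0, "AB": 0.0}
alternative = StageWiseDesign(
    CueSet(("A", "B"), (("A", "B"),)),
    (
        Stage(20, {**z, "AB": 1.0}, {"A": 0.0, "B": 0.0, "AB": 1.0}),
        Stage(30, {"A": 0.5, "B": 0.5, "AB": 0.0},
              {"A": 1.0, "B": 0.0, "AB": 0.0}),
    ),
)

utilities = {}
for name, design in (("REF", reference), ("ALT", alternative)):
    eu = expected_design_utility(design, prior, config.analysis, n_sims=64,
                                 seed=42, utility="selection")
    utilities[name] = eu.utilities
    print(f"{name}: accuracy {eu.mean:.3f} +- {eu.se:.3f}")

report = compare_utility_vectors(utilities, selection=True, seed=0)
pair = report.cles_pairs["REF vs ALT"]
print(f"\nCLES(REF beats ALT) = {pair['cles']:.3f} "
      f"(95% CI [{pair['ci'][0]:.3f}, {pair['ci'][1]:.3f}]; "
      "0.5 = equal quality)")
orx = report.odds_ratios["REF vs ALT"]
print(f"odds ratio of correct selection = {orx['or']:.2f} "
      f"(95% CI [{orx['ci'][0]:.2f}, {orx['ci'][1]:.2f}]; 1 = equal)")
for name, acc in report.accuracy.items():
    print(f"  {name}: {acc['accuracy']:.3f} "
          f"CI [{acc['ci'][0]:.3f}, {acc['ci'][1]:.3f}]")
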