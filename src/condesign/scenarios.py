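"""Reference-design library and end-to-end scenario configurations.

Three shipped configurations mirror the validation scenarios:

1. learning-rate estimation for a single periodically reinforced cue
   (reference: acquisition followed by extinction of equal length);
2. RW vs Kalman-RW model selection
   (reference: backward blocking, AB+ then A+ then non-reinforced test);
3. RW vs RWPH-variant model selection
   (reference: reversal learning with partial reinforcement).

Numeric settings that the source literature does not print (per-stage trial
counts, observation noise, point-prior parameter values) live in the YAML
configs with ``assumed: true`` provenance notes, not in code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .evaluate import compare_utility_vectors
from .experiments import (
    CueSet,
    DesignSpace,
    PeriodicDesign,
    Stage,
    StageWiseDesign,
    design_from_dict,
    design_to_dict,
)
from .models import MODEL_SPECS
from .optimize import OptimizationOptions, optimize_design
from .utility import DesignPrior, ParamPrior, expected_design_utility

__all__ = ["ScenarioConfig", "load_scenario", "build_reference_design",
           "run_scenario"]

MODES = ("evaluate_reference", "optimize", "evaluate_optimized", "compare")


def build_reference_design(name: str, trial_config: dict) -> (
        StageWiseDesign | PeriodicDesign):
    """Construct a manual design from the literature.

    ``acquisition_extinction``: one cue, reinforcement 0.5 then 0 in two
    equal halves (periodic with T = 0.5). ``backward_blocking``: AB+ trials,
    then A+ trials, then a non-reinforced test stage presenting A and B
    equiprobably. ``reversal_learning``: A partially reinforced and B never,
    then the roles swap.
    """
    if name == "acquisition_extinction":
        cue_set = CueSet((trial_config.get("cue", "CS"),))
        lab = cue_set.presentable[0]
        return PeriodicDesign(
            cue_set,
            trial_config["n_trials"],
            cue_levels={lab: (1.0, 1.0)},
            outcome_levels={lab: (trial_config.get("p1", 0.5),
                                  trial_config.get("p2", 0.0))},
            half_period=trial_config.get("half_period", 0.5),
        )
    if name == "backward_blocking":
        cue_set = CueSet(("A", "B"), (("A", "B"),))
        z = {"A": 0.0, "B": 0.0, "AB": 0.0}
        stages = (
            Stage(trial_config["stage1"], {**z, "AB": 1.0},
                  {"A": 0.0, "B": 0.0, "AB": 1.0}),
            Stage(trial_config["stage2"], {**z, "A": 1.0},
                  {"A": 1.0, "B": 0.0, "AB": 0.0}),
            Stage(trial_config["test"], {"A": 0.5, "B": 0.5, "AB": 0.0},
                  {"A": 0.0, "B": 0.0, "AB": 0.0}),
        )
        return StageWiseDesign(cue_set, stages)
    if name == "reversal_learning":
        cue_set = CueSet(("A", "B"))
        rate = trial_config.get("reinforcement_rate", 0.7)
        stages = (
            Stage(trial_config["stage1"], {"A": 0.5, "B": 0.5},
                  {"A": rate, "B": 0.0}),
            Stage(trial_config["stage2"], {"A": 0.5, "B": 0.5},
                  {"A": 0.0, "B": rate}),
        )
        return StageWiseDesign(cue_set, stages)
    raise ValueError(f"unknown reference design {name!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Parsed scenario configuration (see the shipped YAML files)."""

    raw: dict

    @property
    def scenario_id(self) -> int:
        return int(self.raw["scenario"])

    @property
    def model_space(self) -> list[str]:
        return list(self.raw["model_space"])

    @property
    def analysis(self) -> dict:
        analysis = dict(self.raw["analysis"])
        if analysis["procedure"] == "bic_selection":
            analysis.setdefault("models", self.model_space)
        return analysis

    @property
    def utility(self) -> str:
        return self.raw["utility"]

    @property
    def sigma_obs(self) -> float:
        return float(self.raw["sigma_obs"]["value"])

    @property
    def cue_set(self) -> CueSet:
        return CueSet(tuple(self.raw["cues"]),
                      tuple(tuple(c) for c in self.raw.get("compounds", [])))

    def reference_design(self):
        if self.scenario_id == 1:
            ref = self.raw["reference_design"]
            return build_reference_design(
                "acquisition_extinction",
                {"cue": self.raw["cues"][0],
                 "n_trials": int(self.raw["n_trials"]["value"]),
                 "p1": ref["p1"], "p2": ref["p2"],
                 "half_period": ref["half_period"]},
            )
        trials = {k: int(v) for k, v in self.raw["trials"].items()
                  if isinstance(v, (int, float))}
        if self.scenario_id == 2:
            return build_reference_design("backward_blocking", trials)
        trials["reinforcement_rate"] = float(
            self.raw["reinforcement_rate"]["value"])
        return build_reference_design("reversal_learning", trials)

    def design_space(self) -> DesignSpace:
        ds = self.raw["design_space"]
        if ds["parameterization"] == "periodic":
            return DesignSpace("periodic", self.cue_set,
                               n_trials=int(self.raw["n_trials"]["value"]))
        return DesignSpace("stage_wise", self.cue_set,
                           trials_per_stage=tuple(ds["trials_per_stage"]))

    # -- priors -------------------------------------------------------------

    def evaluation_prior(self, prior_id: str | None = None) -> DesignPrior:
        """Point ground-truth prior used to evaluate designs.

        Scenario 1 requires one of the named priors (e.g. LA/MA/HA);
        scenarios 2-3 use the uniform-over-models point-parameter prior.
        """
        if self.scenario_id == 1:
            if prior_id is None:
                raise ValueError("scenario 1 needs an evaluation prior id")
            alpha = float(self.raw["evaluation_priors"][prior_id]["alpha"])
            return DesignPrior.point("rw", {"alpha": alpha,
                                            "sigma_obs": self.sigma_obs})
        models = self.model_space
        weight = 1.0 / len(models)
        priors = {
            m: {p: ParamPrior("point", (float(v),))
                for p, v in self.raw["point_priors"][m].items()}
            for m in models
        }
        return DesignPrior({m: weight for m in models}, priors)

    def design_prior(self, kind: str = "vague",
                     eval_prior_id: str | None = None) -> DesignPrior:
        """Prior used while optimizing: ``vague`` (VA/VP) or ``point`` (PA/PP)."""
        if self.scenario_id == 1:
            if kind == "point":
                return self.evaluation_prior(eval_prior_id)
            specs = self.raw["design_priors"]["vague"]["rw"]
            return DesignPrior(
                {"rw": 1.0},
                {"rw": {p: ParamPrior.from_spec(s) for p, s in specs.items()}},
            )
        if kind == "point":
            return self.evaluation_prior()
        models = self.model_space
        weight = 1.0 / len(models)
        priors = {
            m: {p: ParamPrior.from_spec(s)
                for p, s in self.raw["vague_priors"][m].items()}
            for m in models
        }
        return DesignPrior({m: weight for m in models}, priors)

    @property
    def evaluation_prior_ids(self) -> list[str]:
        if self.scenario_id == 1:
            return list(self.raw["evaluation_priors"])
        return ["point"]

    def optimization_options(self, seed: int, max_iterations: int | None = None,
                             n_initial_points: int | None = None,
                             sims_per_evaluation: int | None = None
                             ) -> OptimizationOptions:
        opt = self.raw["optimization"]
        if sims_per_evaluation is None:
            sims_per_evaluation = int(opt["sims_per_model"]) * len(self.model_space)
        return OptimizationOptions(
            max_iterations=max_iterations or int(opt["max_iterations"]),
            n_initial_points=n_initial_points or int(opt["n_initial_points"]),
            sims_per_evaluation=sims_per_evaluation,
            seed=seed,
        )

    def evaluation_n_sims(self) -> int:
        per = int(self.raw["evaluation"]["sims_per_combination"])
        if self.scenario_id == 1:
            return per
        return per * len(self.model_space)


def load_scenario(which: int | str | Path) -> ScenarioConfig:
    """Load a shipped scenario (1, 2 or 3) or a YAML config file path."""
    if isinstance(which, int) or (isinstance(which, str) and which.isdigit()):
        ref = resources.files("condesign.configs") / f"scenario{which}.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(which) as fh:
            raw = yaml.safe_load(fh)
    return ScenarioConfig(raw)


def _evaluate_design(config: ScenarioConfig, design, seed: int,
                     n_sims: int | None) -> dict:
    """Evaluate one design under every evaluation prior of the scenario."""
    out: dict = {}
    for i, prior_id in enumerate(config.evaluation_prior_ids):
        prior = config.evaluation_prior(
            prior_id if config.scenario_id == 1 else None)
        eu = expected_design_utility(
            design,
            prior,
            config.analysis,
            n_sims=n_sims or config.evaluation_n_sims(),
            seed=int(np.random.SeedSequence((seed, 101 + i))
                     .generate_state(1)[0] % 2**31),
            utility=config.utility,
        )
        out[prior_id] = eu.to_dict()
    return out


def run_scenario(
    config: ScenarioConfig,
    mode: str,
    seed: int,
    out_dir: str | Path | None = None,
    n_sims: int | None = None,
    design_prior: str = "vague",
    eval_prior_id: str | None = None,
    max_iterations: int | None = None,
    n_initial_points: int | None = None,
    sims_per_evaluation: int | None = None,
    design=None,
) -> dict:
    """Run one workflow stage end-to-end and return a JSON-serializable report.

    Modes: ``evaluate_reference`` (step 2 of the workflow), ``optimize``
    (step 3), ``evaluate_optimized`` (step 4; takes the design returned by
    ``optimize`` or reads it from ``out_dir``), and ``compare`` (step 5;
    consumes the two evaluation reports from ``out_dir``).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    report: dict = {"scenario": config.scenario_id, "mode": mode, "seed": seed}

    if mode == "evaluate_reference":
        report["design"] = design_to_dict(config.reference_design())
        report["evaluations"] = _evaluate_design(
            config, config.reference_design(), seed, n_sims)
    elif mode == "optimize":
        space = config.design_space()
        prior = config.design_prior(design_prior, eval_prior_id)
        options = config.optimization_options(
            seed, max_iterations, n_initial_points, sims_per_evaluation)
        optimized, trace = optimize_design(space, prior, config.analysis,
                                           options, utility=config.utility)
        report["design_prior"] = design_prior
        report["design"] = design_to_dict(optimized.design)
        report["vector"] = [float(v) for v in optimized.vector]
        report["observed_utility"] = optimized.utility
        report["posterior_mean_utility"] = optimized.posterior_mean
        if out_path is not None:
            trace.to_frame().to_csv(out_path / "optimization_trace.csv",
                                    index=False)
    elif mode == "evaluate_optimized":
        if design is None:
            src = (out_path / "optimize.json") if out_path else None
            if src is None or not src.exists():
                raise FileNotFoundError(
                    "evaluate_optimized needs a design or a prior "
                    "'optimize.json' in out_dir")
            design = design_from_dict(json.loads(src.read_text())["design"])
        report["design"] = design_to_dict(design)
        report["evaluations"] = _evaluate_design(config, design, seed, n_sims)
    else:  # compare
        if out_path is None:
            raise ValueError("compare mode requires out_dir")
        utilities, records = {}, {}
        for did, fname in (("REF", "evaluate_reference.json"),
                           ("OPT", "evaluate_optimized.json")):
            src = out_path / fname
            if not src.exists():
                raise FileNotFoundError(f"missing upstream artifact {src}")
            doc = json.loads(src.read_text())
            evals = doc["evaluations"]
            for prior_id, eu in evals.items():
                key = did if len(evals) == 1 else f"{did}:{prior_id}"
                utilities[key] = np.array(eu["utilities"])
                records[key] = eu["records"]
        selection = config.utility == "selection"
        comparison = compare_utility_vectors(
            utilities,
            selection=selection,
            records=records if selection else None,
            model_space=config.model_space if selection else None,
            seed=seed,
        )
        report["comparison"] = comparison.to_dict()

    if out_path is not None:
        with open(out_path / f"{mode}.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
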