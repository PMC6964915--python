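"""Experiment-wise utilities and Monte-Carlo expected design utility.

A design's expected utility is estimated by repeatedly (i) sampling a ground
truth (model + parameters) from the design prior, (ii) simulating a dataset
under the evaluated design, (iii) running the planned analysis (MLE or BIC
model selection), and (iv) scoring the analysis result. Both utilities are
framed as maximization: negated absolute estimation error, and the correct
model-selection indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import fit_mle, select_model
from .models import MODEL_SPECS, simulate_dataset

__all__ = [
    "ParamPrior",
    "DesignPrior",
    "GroundTruth",
    "ExpectedUtility",
    "sample_ground_truth",
    "estimation_utility",
    "selection_utility",
    "expected_design_utility",
]


@dataclass(frozen=True)
class ParamPrior:
    """Per-parameter prior: point mass, uniform box, or half-normal."""

    kind: str  # point | uniform | halfnormal
    args: tuple[float, ...]

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return self.args[0]
        if self.kind == "uniform":
            lo, hi = self.args
            return float(rng.uniform(lo, hi))
        if self.kind == "halfnormal":
            scale = self.args[0]
            lo = self.args[1] if len(self.args) > 1 else 0.0
            return float(np.clip(abs(rng.normal(0.0, scale)), lo, None))
        raise ValueError(f"unknown prior kind {self.kind!r}")

    @classmethod
    def from_spec(cls, spec) -> "ParamPrior":
        if isinstance(spec, ParamPrior):
            return spec
        if isinstance(spec, (int, float)):
            return cls("point", (float(spec),))
        kind, *args = spec
        return cls(kind, tuple(float(a) for a in args))


@dataclass(frozen=True)
class DesignPrior:
    """Model weights plus per-model parameter priors."""

    model_weights: dict[str, float]
    param_priors: dict[str, dict[str, ParamPrior]]

    def __post_init__(self):
        total = sum(self.model_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("model weights must sum to 1")
        normed = {
            m: {p: ParamPrior.from_spec(s) for p, s in priors.items()}
            for m, priors in self.param_priors.items()
        }
        object.__setattr__(self, "param_priors", normed)

    @property
    def is_uniform_over_models(self) -> bool:
        w = list(self.model_weights.values())
        return len(w) > 1 and max(w) - min(w) < 1e-12

    @classmethod
    def point(cls, model_id: str, params: dict[str, float]) -> "DesignPrior":
        return cls({model_id: 1.0}, {model_id: {p: ParamPrior("point", (v,))
                                                for p, v in params.items()}})


@dataclass(frozen=True)
class GroundTruth:
    model_id: str
    params: dict[str, float]


@dataclass(frozen=True)
class ExpectedUtility:
    """Monte-Carlo mean utility with provenance and per-simulation detail."""

    mean: float
    se: float
    n_sims: int
    seed: int
    utilities: np.ndarray
    records: tuple[dict, ...] = ()
    n_failures: int = 0

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "se": self.se,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "n_failures": self.n_failures,
            "utilities": [float(u) for u in self.utilities],
            "records": list(self.records),
        }


def sample_ground_truth(prior: DesignPrior, rng: np.random.Generator) -> GroundTruth:
    """Draw a candidate model by its weight, then its parameters."""
    models = list(prior.model_weights)
    weights = np.array([prior.model_weights[m] for m in models])
    model_id = models[rng.choice(len(models), p=weights / weights.sum())]
    params = {p: pr.sample(rng) for p, pr in prior.param_priors[model_id].items()}
    return GroundTruth(model_id, params)


def estimation_utility(estimate: float, truth: float) -> float:
    """Negative absolute estimation error (maximization convention)."""
    return -abs(estimate - truth)


def selection_utility(selected: str, truth: str) -> float:
    """1 when the selected model is the ground truth model, else 0."""
    return 1.0 if selected == truth else 0.0


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % 2**31)


def expected_design_utility(
    design,
    prior: DesignPrior,
    analysis: dict,
    n_sims: int,
    seed: int,
    utility: str | None = None,
    penalty: float = -1.0,
) -> ExpectedUtility:
    """Monte-Carlo expected utility of a design under a design prior.

    ``analysis`` is either ``{"procedure": "mle", "model": id,
    "target_param": name, "n_starts": int}`` (estimation utility) or
    ``{"procedure": "bic_selection", "models": [...], "n_starts": int}``
    (0-1 selection utility). When the prior over models is uniform, ground
    truths are allocated in balanced per-model blocks. A failed analysis is
    scored as the worst case (0 for selection, ``penalty`` for estimation)
    and counted, never dropped.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    procedure = analysis["procedure"]
    if utility is None:
        utility = "selection" if procedure == "bic_selection" else "estimation"
    n_starts = analysis.get("n_starts", 5)
    models = list(prior.model_weights)
    balanced = prior.is_uniform_over_models
    utilities = np.empty(n_sims)
    records: list[dict] = []
    n_failures = 0
    for i in range(n_sims):
        rng = np.random.default_rng(_child_seed(seed, i))
        if balanced:
            model_id = models[i % len(models)]
            params = {p: pr.sample(rng)
                      for p, pr in prior.param_priors[model_id].items()}
            truth = GroundTruth(model_id, params)
        else:
            truth = sample_ground_truth(prior, rng)
        rec: dict = {"sim": i, "true_model": truth.model_id,
                     "true_params": truth.params}
        try:
            dataset, _ = simulate_dataset(design, truth.model_id, truth.params, rng)
            if procedure == "mle":
                fit = fit_mle(analysis["model"], dataset, n_starts=n_starts,
                              seed=rng)
                est = fit.params[analysis["target_param"]]
                rec["estimate"] = est
                u = estimation_utility(est, truth.params[analysis["target_param"]])
            elif procedure == "bic_selection":
                sel = select_model(dataset, analysis["models"], n_starts=n_starts,
                                   seed=rng)
                rec["selected_model"] = sel.winner
                u = selection_utility(sel.winner, truth.model_id)
            else:
                raise ValueError(f"unknown analysis procedure {procedure!r}")
        except ValueError:
            raise
        except Exception:  # noqa: BLE001 - scored as worst case, never dropped
            n_failures += 1
            u = 0.0 if utility == "selection" else penalty
            rec["failed"] = True
        rec["utility"] = u
        utilities[i] = u
        records.append(rec)
    mean = float(utilities.mean())
    se = float(utilities.std(ddof=1) / np.sqrt(n_sims)) if n_sims > 1 else 0.0
    return ExpectedUtility(mean, se, n_sims, seed, utilities, tuple(records),
                           n_failures)
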