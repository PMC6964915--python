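"""Planned data analyses: maximum-likelihood fits and BIC model selection.

Parameter estimation is maximum a posteriori with uniform box priors, i.e.
bounded maximum likelihood. Every model's observation-noise s.d. is a fitted
parameter and counts toward the BIC complexity penalty. The sample size in
BIC is the number of trials (one conditioned response per trial).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .models import MODEL_SPECS, Dataset, log_likelihood, response_means

__all__ = ["FitResult", "SelectionResult", "fit_mle", "bic", "select_model"]


@dataclass(frozen=True)
class FitResult:
    model_id: str
    params: dict[str, float]
    loglik: float
    n_starts: int
    converged: bool
    best_start: int

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params,
            "loglik": self.loglik,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "best_start": self.best_start,
        }


@dataclass(frozen=True)
class SelectionResult:
    winner: str
    bics: dict[str, float]
    delta_bic: float  # winner vs runner-up (non-positive by construction)
    fits: dict[str, FitResult]

    def to_dict(self) -> dict:
        return {
            "winner": self.winner,
            "bics": self.bics,
            "delta_bic": self.delta_bic,
            "fits": {m: f.to_dict() for m, f in self.fits.items()},
        }


def fit_mle(
    model_id: str,
    dataset: Dataset,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 5,
    seed: int | np.random.Generator = 0,
) -> FitResult:
    """Bounded multi-start maximum-likelihood fit.

    Starts are drawn uniformly in the 5%-95% interior of each bound and each
    is refined with L-BFGS-B; the best local optimum is returned.
    Deterministic given the seed.
    """
    if dataset.n_trials == 0:
        raise ValueError("cannot fit an empty dataset")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    spec = MODEL_SPECS[model_id]
    bounds = {**spec.bounds, **(bounds or {})}
    names = spec.param_names
    lo = np.array([bounds[p][0] for p in names])
    hi = np.array([bounds[p][1] for p in names])
    stim = dataset.encoded()
    y = dataset.responses
    n = dataset.n_trials

    def negll(theta: np.ndarray) -> float:
        p = dict(zip(names, theta))
        sigma = max(p["sigma_obs"], 1e-12)
        m = response_means(model_id, p, stim)
        resid = y - m
        return 0.5 * n * math.log(2 * math.pi * sigma**2) + 0.5 * float(
            resid @ resid
        ) / sigma**2

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = lo + (0.05 + 0.9 * rng.random((n_starts, len(names)))) * (hi - lo)
    best_val, best_x, best_i, converged = np.inf, None, -1, False
    for i, x0 in enumerate(starts):
        res = minimize(
            negll,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if res.fun < best_val:
            best_val, best_x, best_i = res.fun, res.x, i
            converged = bool(res.success)
    params = {p: float(v) for p, v in zip(names, best_x)}
    return FitResult(model_id, params, -float(best_val), n_starts, converged, best_i)


def bic(loglik: float, k_params: int, n_obs: int) -> float:
    """Bayesian information criterion: -2*loglik + k*ln(n)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik + k_params * math.log(n_obs)


def select_model(
    dataset: Dataset,
    model_space: list[str],
    n_starts: int = 5,
    seed: int | np.random.Generator = 0,
    bounds: dict[str, dict[str, tuple[float, float]]] | None = None,
) -> SelectionResult:
    """Fit every candidate model and select the minimal-BIC one.

    Ties are broken toward the model with fewer parameters, then by the order
    in which models were declared in ``model_space``.
    """
    if len(model_space) < 2:
        raise ValueError("model selection requires at least two models")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # one independent child seed per model, independent of listing order
    seeds = {m: np.random.default_rng(rng.integers(2**31)) for m in sorted(model_space)}
    fits, bics = {}, {}
    for m in model_space:
        fit = fit_mle(m, dataset, bounds=(bounds or {}).get(m), n_starts=n_starts,
                      seed=seeds[m])
        fits[m] = fit
        bics[m] = bic(fit.loglik, MODEL_SPECS[m].n_params, dataset.n_trials)
    order = {m: i for i, m in enumerate(model_space)}
    winner = min(model_space,
                 key=lambda m: (bics[m], MODEL_SPECS[m].n_params, order[m]))
    others = [bics[m] for m in model_space if m != winner]
    return SelectionResult(winner, bics, bics[winner] - min(others), fits)
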