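"""Gaussian-process Bayesian optimization of expected design utility.

The objective — Monte-Carlo expected utility — is noisy and expensive, so a
Gaussian-process surrogate (anisotropic Matérn-5/2 kernel plus a fitted white
noise term) is maintained over the unit box [0,1]^d, and the next design
vector maximizes expected improvement (with a small exploration offset) via
random candidates refined by multi-start L-BFGS. Simplex constraints never
reach the optimizer: the design space's stick-breaking decoding makes every
box point feasible.

Because observations are noisy, the returned incumbent is the evaluated
point with the highest GP posterior mean, not the highest raw observation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .experiments import DesignSpace
from .utility import DesignPrior, ExpectedUtility, expected_design_utility

__all__ = [
    "OptimizationOptions",
    "OptimizationTrace",
    "OptimizedDesign",
    "propose_next",
    "optimize_design",
    "bayes_opt_maximize",
]

logger = logging.getLogger(__name__)

_EI_XI = 0.01  # exploration offset in expected improvement


@dataclass(frozen=True)
class OptimizationOptions:
    max_iterations: int = 300
    n_initial_points: int = 10
    acquisition: str = "ei"
    sims_per_evaluation: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if not (0 < self.n_initial_points < self.max_iterations):
            raise ValueError("need 0 < n_initial_points < max_iterations")


@dataclass
class OptimizationTrace:
    vectors: np.ndarray  # (n_iter, d)
    utilities: np.ndarray
    ses: np.ndarray
    incumbents: np.ndarray  # running max of observed utilities

    @property
    def n_iterations(self) -> int:
        return len(self.utilities)

    def to_frame(self):
        import pandas as pd

        d = self.vectors.shape[1]
        frame = pd.DataFrame(
            {
                "iteration": np.arange(1, self.n_iterations + 1),
                "utility": self.utilities,
                "se": self.ses,
                "incumbent": self.incumbents,
            }
        )
        for j in range(d):
            frame[f"v{j + 1}"] = self.vectors[:, j]
        return frame


@dataclass
class OptimizedDesign:
    design: object
    vector: np.ndarray
    utility: float  # observed utility at the returned vector
    posterior_mean: float
    trace: OptimizationTrace


def _make_gp(dim: int, rng: np.random.Generator) -> GaussianProcessRegressor:
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=np.full(dim, 0.3), length_scale_bounds=(1e-2, 1e2),
                 nu=2.5)
        + WhiteKernel(1e-2, (1e-8, 1e1))
    )
    return GaussianProcessRegressor(
        kernel=kernel,
        normalize_y=True,
        n_restarts_optimizer=2,
        random_state=int(rng.integers(2**31)),
    )


def _fit_gp(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    gp = _make_gp(X.shape[1], rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    return gp


def _expected_improvement(gp, V: np.ndarray, best: float) -> np.ndarray:
    mu, sd = gp.predict(V, return_std=True)
    sd = np.maximum(sd, 1e-12)
    z = (mu - best - _EI_XI) / sd
    return (mu - best - _EI_XI) * norm.cdf(z) + sd * norm.pdf(z)


def _latin_hypercube(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    pts = np.empty((n, dim))
    for j in range(dim):
        perm = rng.permutation(n)
        pts[:, j] = (perm + rng.random(n)) / n
    return pts


def propose_next(
    X: np.ndarray,
    y: np.ndarray,
    dim: int,
    rng: np.random.Generator,
    n_candidates: int = 1024,
    n_polish: int = 3,
) -> np.ndarray:
    """Propose the next design vector by maximizing expected improvement.

    Falls back to a uniform random point if the GP fit fails.
    """
    if len(y) == 0:
        return rng.random(dim)
    try:
        gp = _fit_gp(np.atleast_2d(X), np.asarray(y, float), rng)
    except Exception:  # noqa: BLE001
        logger.warning("GP fit failed; falling back to a random proposal")
        return rng.random(dim)
    best = float(np.max(gp.predict(np.atleast_2d(X))))
    cand = rng.random((n_candidates, dim))
    ei = _expected_improvement(gp, cand, best)
    # EI can collapse to ~0 everywhere once the surrogate explains the data
    # (e.g. a noiseless objective fully explored); exploit the posterior mean
    y_scale = max(float(np.ptp(y)), 1e-8)
    if float(ei.max()) < 1e-10 * y_scale:
        acq = lambda V: gp.predict(np.atleast_2d(V))  # noqa: E731
    else:
        acq = lambda V: _expected_improvement(gp, np.atleast_2d(V), best)  # noqa: E731
    scores = acq(cand)
    order = np.argsort(scores)[::-1]
    best_x, best_score = cand[order[0]], scores[order[0]]
    for idx in order[:n_polish]:
        res = minimize(
            lambda v: -acq(v.reshape(1, -1))[0],
            cand[idx],
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * dim,
        )
        if -res.fun > best_score:
            best_score, best_x = -res.fun, np.clip(res.x, 0.0, 1.0)
    return best_x


def bayes_opt_maximize(objective, dim: int, options: OptimizationOptions):
    """Core BO loop over [0,1]^dim for a noisy objective.

    ``objective(v, iteration) -> (value, se)``. Runs exactly
    ``options.max_iterations`` evaluations: space-filling initial points
    first, acquisition-driven proposals afterwards. Returns
    ``(best_vector, observed_utility, posterior_mean, trace)``.
    """
    rng = np.random.default_rng(options.seed)
    initial = _latin_hypercube(options.n_initial_points, dim, rng)
    X: list[np.ndarray] = []
    y: list[float] = []
    ses: list[float] = []
    for t in range(options.max_iterations):
        if t < options.n_initial_points:
            v = initial[t]
        else:
            v = propose_next(np.array(X), np.array(y), dim, rng)
        val, se = objective(v, t)
        X.append(np.asarray(v, float))
        y.append(float(val))
        ses.append(float(se))
    Xa, ya = np.array(X), np.array(y)
    trace = OptimizationTrace(Xa, ya, np.array(ses), np.maximum.accumulate(ya))
    # incumbent under noise: highest GP posterior mean among evaluated points
    try:
        gp = _fit_gp(Xa, ya, rng)
        post = gp.predict(Xa)
    except Exception:  # noqa: BLE001
        post = ya
    best_idx = int(np.argmax(post))
    return Xa[best_idx], float(ya[best_idx]), float(post[best_idx]), trace


def optimize_design(
    space: DesignSpace,
    prior: DesignPrior,
    analysis: dict,
    options: OptimizationOptions,
    utility: str | None = None,
) -> tuple[OptimizedDesign, OptimizationTrace]:
    """Bayesian-optimize expected design utility over the design space.

    Each evaluation simulates ``options.sims_per_evaluation`` experiments
    with a seed derived from (master seed, iteration), so the whole run is
    reproducible without freezing the noise across iterations.
    """

    def objective(v: np.ndarray, iteration: int):
        design = space.from_vector(v)
        eu = expected_design_utility(
            design,
            prior,
            analysis,
            n_sims=options.sims_per_evaluation,
            seed=int(
                np.random.SeedSequence((options.seed, 7919, iteration))
                .generate_state(1)[0] % 2**31
            ),
            utility=utility,
        )
        return eu.mean, eu.se

    vec, observed, post_mean, trace = bayes_opt_maximize(
        objective, space.dim, options
    )
    optimized = OptimizedDesign(space.from_vector(vec), vec, observed, post_mean,
                                trace)
    return optimized, trace
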