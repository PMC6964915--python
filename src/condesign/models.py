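"""Candidate associative-learning models and dataset simulation.

The model space contains the Rescorla-Wagner delta rule (``rw``), its Kalman
filter extension tracking a full covariance over weights (``krw``), and the
hybrid Rescorla-Wagner / Pearce-Hall model with per-cue dynamic learning
rates ("associabilities") in three response variants: weights (``rwph_v``),
associabilities (``rwph_alpha``), and their convex mixture (``rwph_valpha``).

All models respond to the cue *before* the outcome arrives: the conditioned
response on trial t is the model's pre-outcome prediction plus Gaussian
observation noise with standard deviation ``sigma_obs``. Outcomes are coded
r in {0, 1} with the US asymptote fixed at 1; its scale is absorbed by the
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .experiments import (
    CueSet,
    ExperimentRealization,
    PeriodicDesign,
    StageWiseDesign,
    sample_realization,
    unroll_schedule,
)

__all__ = [
    "MODEL_IDS",
    "MODEL_SPECS",
    "ModelSpec",
    "RWParams",
    "KRWParams",
    "RWPHParams",
    "StimulusMatrix",
    "LatentTrace",
    "Dataset",
    "encode",
    "rw_step",
    "krw_step",
    "rwph_step",
    "emit_response",
    "response_means",
    "simulate_dataset",
    "log_likelihood",
]

LAMBDA_US = 1.0  # fixed US asymptote


@dataclass(frozen=True)
class RWParams:
    alpha: float
    sigma_obs: float
    w0: float = 0.0


@dataclass(frozen=True)
class KRWParams:
    w0_var: float
    q_diffusion: float
    r_noise_var: float
    sigma_obs: float
    w0_mean: float = 0.0


@dataclass(frozen=True)
class RWPHParams:
    kappa: float
    eta: float
    alpha0: float
    sigma_obs: float
    omega: float = 0.0  # used only by the V+alpha mapping


@dataclass(frozen=True)
class ModelSpec:
    """Registry entry: fitted parameter names define k for BIC."""

    model_id: str
    param_names: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    mapping: str  # response mapping: V | alpha | V_plus_alpha

    @property
    def n_params(self) -> int:
        return len(self.param_names)


_UNIT = (0.0, 1.0)
_SIGMA = (0.01, 1.0)
_VAR = (1e-4, 10.0)

MODEL_SPECS: dict[str, ModelSpec] = {
    "rw": ModelSpec("rw", ("alpha", "sigma_obs"),
                    {"alpha": _UNIT, "sigma_obs": _SIGMA}, "V"),
    "krw": ModelSpec(
        "krw",
        ("w0_var", "q_diffusion", "r_noise_var", "sigma_obs"),
        {"w0_var": _VAR, "q_diffusion": _VAR, "r_noise_var": _VAR,
         "sigma_obs": _SIGMA},
        "V",
    ),
    "rwph_v": ModelSpec(
        "rwph_v", ("kappa", "eta", "alpha0", "sigma_obs"),
        {"kappa": _UNIT, "eta": _UNIT, "alpha0": _UNIT, "sigma_obs": _SIGMA},
        "V",
    ),
    "rwph_alpha": ModelSpec(
        "rwph_alpha", ("kappa", "eta", "alpha0", "sigma_obs"),
        {"kappa": _UNIT, "eta": _UNIT, "alpha0": _UNIT, "sigma_obs": _SIGMA},
        "alpha",
    ),
    "rwph_valpha": ModelSpec(
        "rwph_valpha", ("kappa", "eta", "alpha0", "omega", "sigma_obs"),
        {"kappa": _UNIT, "eta": _UNIT, "alpha0": _UNIT, "omega": _UNIT,
         "sigma_obs": _SIGMA},
        "V_plus_alpha",
    ),
}

MODEL_IDS = tuple(MODEL_SPECS)


def params_to_dict(model_id: str, params) -> dict[str, float]:
    if isinstance(params, dict):
        return dict(params)
    from dataclasses import asdict

    return asdict(params)


@dataclass(frozen=True)
class StimulusMatrix:
    """Vector encoding of a realization: binary element activations X and
    binary outcomes r."""

    X: np.ndarray  # (n_trials, n_elements)
    r: np.ndarray  # (n_trials,)
    cue_set: CueSet
    stimulus_idx: np.ndarray


@dataclass
class LatentTrace:
    """Per-trial latent model state (pre-outcome values at each trial)."""

    V: np.ndarray | None = None  # (n_trials, n_elements) weights
    delta: np.ndarray | None = None
    assoc: np.ndarray | None = None  # RWPH associabilities
    Sigma: np.ndarray | None = None  # (n_trials, k, k) KRW covariance
    gain: np.ndarray | None = None  # (n_trials, k) KRW Kalman gain


@dataclass(frozen=True)
class Dataset:
    """A simulated experiment: realization plus conditioned responses."""

    realization: ExperimentRealization
    responses: np.ndarray
    cue_set: CueSet

    def __post_init__(self):
        if self.responses.shape[0] != self.realization.n_trials:
            raise ValueError("responses and realization lengths differ")

    @property
    def n_trials(self) -> int:
        return self.realization.n_trials

    def encoded(self) -> StimulusMatrix:
        return encode(self.realization, self.cue_set)

    def to_frame(self):
        frame = self.realization.to_frame()
        frame["response"] = self.responses
        return frame


def encode(realization: ExperimentRealization, cue_set: CueSet) -> StimulusMatrix:
    """Map presentable stimulus labels to binary element-activation rows."""
    labels = cue_set.presentable
    for lab in realization.cue_labels:
        if lab not in labels:
            raise ValueError(f"unknown stimulus label {lab!r}")
    pres_mat = cue_set.element_matrix()
    # realization labels may be ordered differently from cue_set.presentable
    idx_map = np.array([labels.index(lab) for lab in realization.cue_labels])
    rows = idx_map[realization.stimulus_idx]
    X = pres_mat[rows]
    return StimulusMatrix(X, realization.outcomes.astype(float), cue_set,
                          realization.stimulus_idx.copy())


# ---------------------------------------------------------------------------
# Single-trial updates (reference implementations)
# ---------------------------------------------------------------------------


def rw_step(w: np.ndarray, x: np.ndarray, r: float, alpha: float):
    """Delta rule: delta = lambda*r - x.w ; w' = w + alpha*delta*x."""
    delta = LAMBDA_US * r - float(x @ w)
    return w + alpha * delta * x, delta


def krw_step(w: np.ndarray, Sigma: np.ndarray, x: np.ndarray, r: float,
             params: KRWParams):
    """One Kalman recursion: diffuse, predict, correct; returns (w', Sigma', k)."""
    eig = np.linalg.eigvalsh(0.5 * (Sigma + Sigma.T))
    if eig.min() < -1e-8:
        raise ValueError("KRW covariance must be positive semidefinite")
    S = Sigma + params.q_diffusion * np.eye(len(w))
    Sx = S @ x
    gain = Sx / (float(x @ Sx) + params.r_noise_var)
    w_new = w + gain * (LAMBDA_US * r - float(x @ w))
    S_new = S - np.outer(gain, Sx)
    S_new = 0.5 * (S_new + S_new.T)
    return w_new, S_new, gain


def rwph_step(V: np.ndarray, assoc: np.ndarray, x: np.ndarray, r: float,
              params: RWPHParams):
    """Hybrid update: weights move at rate kappa*associability; presented
    cues' associabilities track |delta|."""
    delta = LAMBDA_US * r - float(x @ V)
    presented = x != 0
    V_new = V + np.where(presented, params.kappa * assoc * delta * x, 0.0)
    assoc_new = np.where(
        presented, params.eta * abs(delta) + (1.0 - params.eta) * assoc, assoc
    )
    return V_new, assoc_new, delta


def emit_response(latents: dict, mapping: str, x: np.ndarray, sigma_obs: float,
                  rng: np.random.Generator, omega: float = 0.0) -> float:
    """Draw one conditioned response from the pre-outcome latent state."""
    if mapping == "V":
        mean = float(x @ latents["V"])
    elif mapping == "alpha":
        mean = float(x @ latents["assoc"])
    elif mapping == "V_plus_alpha":
        mean = (1.0 - omega) * float(x @ latents["V"]) + omega * float(
            x @ latents["assoc"]
        )
    else:
        raise ValueError(f"unknown response mapping {mapping!r}")
    if sigma_obs == 0.0:
        return mean
    return mean + sigma_obs * float(rng.standard_normal())


# ---------------------------------------------------------------------------
# Whole-sequence mean responses and simulation
# ---------------------------------------------------------------------------

_MAPPING_CODE = {"V": 0, "alpha": 1, "V_plus_alpha": 2}


def response_means(model_id: str, params, stim: StimulusMatrix) -> np.ndarray:
    """Trial-wise mean conditioned responses (noise-free model predictions)."""
    p = params_to_dict(model_id, params)
    X = np.ascontiguousarray(stim.X, dtype=np.float64)
    r = np.ascontiguousarray(stim.r, dtype=np.float64)
    if model_id == "rw":
        return _kernels.rw_means(X, r, p["alpha"], p.get("w0", 0.0))
    if model_id == "krw":
        return _kernels.krw_means(X, r, p.get("w0_mean", 0.0), p["w0_var"],
                                  p["q_diffusion"], p["r_noise_var"])
    if model_id in ("rwph_v", "rwph_alpha", "rwph_valpha"):
        code = _MAPPING_CODE[MODEL_SPECS[model_id].mapping]
        return _kernels.rwph_means(X, r, p["kappa"], p["eta"], p["alpha0"],
                                   p.get("omega", 0.0), code)
    raise ValueError(f"unknown model_id {model_id!r}")


def _run_trace(model_id: str, params, stim: StimulusMatrix):
    """Reference per-trial loop producing latent traces and mean responses."""
    p = params_to_dict(model_id, params)
    n, k = stim.X.shape
    means = np.empty(n)
    trace = LatentTrace()
    if model_id == "rw":
        w = np.full(k, p.get("w0", 0.0))
        trace.V = np.empty((n, k))
        trace.delta = np.empty(n)
        for t in range(n):
            x = stim.X[t]
            trace.V[t] = w
            means[t] = float(x @ w)
            w, trace.delta[t] = rw_step(w, x, stim.r[t], p["alpha"])
    elif model_id == "krw":
        kp = KRWParams(p["w0_var"], p["q_diffusion"], p["r_noise_var"],
                       p["sigma_obs"], p.get("w0_mean", 0.0))
        w = np.full(k, kp.w0_mean)
        S = np.eye(k) * kp.w0_var
        trace.V = np.empty((n, k))
        trace.delta = np.empty(n)
        trace.Sigma = np.empty((n, k, k))
        trace.gain = np.empty((n, k))
        for t in range(n):
            x = stim.X[t]
            trace.V[t] = w
            trace.Sigma[t] = S
            means[t] = float(x @ w)
            trace.delta[t] = stim.r[t] - means[t]
            w, S, trace.gain[t] = krw_step(w, S, x, stim.r[t], kp)
    else:
        spec = MODEL_SPECS[model_id]
        hp = RWPHParams(p["kappa"], p["eta"], p["alpha0"], p["sigma_obs"],
                        p.get("omega", 0.0))
        V = np.zeros(k)
        assoc = np.full(k, hp.alpha0)
        trace.V = np.empty((n, k))
        trace.assoc = np.empty((n, k))
        trace.delta = np.empty(n)
        for t in range(n):
            x = stim.X[t]
            trace.V[t] = V
            trace.assoc[t] = assoc
            if spec.mapping == "V":
                means[t] = float(x @ V)
            elif spec.mapping == "alpha":
                means[t] = float(x @ assoc)
            else:
                means[t] = (1 - hp.omega) * float(x @ V) + hp.omega * float(
                    x @ assoc
                )
            V, assoc, trace.delta[t] = rwph_step(V, assoc, x, stim.r[t], hp)
    return means, trace


def simulate_dataset(
    design: StageWiseDesign | PeriodicDesign,
    model_id: str,
    params,
    seed: int | np.random.Generator,
) -> tuple[Dataset, LatentTrace]:
    """Sample a realization, run the model's recursion, emit noisy responses.

    Fully reproducible from the seed: the realization and the response noise
    are drawn from a single generator.
    """
    if model_id not in MODEL_SPECS:
        raise ValueError(f"unknown model_id {model_id!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    schedule = unroll_schedule(design)
    realization = sample_realization(schedule, rng)
    stim = encode(realization, design.cue_set)
    means, trace = _run_trace(model_id, params, stim)
    sigma = params_to_dict(model_id, params)["sigma_obs"]
    responses = means + sigma * rng.standard_normal(len(means))
    return Dataset(realization, responses, design.cue_set), trace


def log_likelihood(model_id: str, params, dataset: Dataset,
                   stim: StimulusMatrix | None = None) -> float:
    """Gaussian log-likelihood of the responses around the model means."""
    p = params_to_dict(model_id, params)
    sigma = p["sigma_obs"]
    if sigma <= 0:
        raise ValueError("sigma_obs must be positive")
    if stim is None:
        stim = dataset.encoded()
    m = response_means(model_id, p, stim)
    resid = dataset.responses - m
    n = len(resid)
    return float(-0.5 * n * np.log(2 * np.pi * sigma**2)
                 - 0.5 * np.sum(resid**2) / sigma**2)
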