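"""Trial-generating experiment structures for classical conditioning.

A conditioning experiment is formalized as a sequence of independent trials:
on each trial one presentable stimulus (an elemental cue or a compound of
cues) is drawn from the cue-presentation probabilities ``P(CS)``, and a binary
outcome (the US) is then drawn from the conditional contingency ``P(US|CS)``.
These transition probabilities of the trial-generating Markov chain are the
tunable design variables.

Two low-dimensional parameterizations are provided:

* **stage-wise** — the experiment is split into contiguous stages, each with
  constant transition probabilities (covers classical designs such as
  acquisition-extinction, blocking, and reversal learning);
* **periodic** — each probability follows a square wave that alternates
  between two levels ``P1`` and ``P2`` with half-period ``T`` (expressed as a
  fraction of the total number of trials).

Both unroll to an explicit per-trial :class:`ContingencySchedule`, from which
cue-outcome sequences (:class:`ExperimentRealization`) are sampled.
:class:`DesignSpace` maps designs to and from an unconstrained optimization
box ``[0, 1]^d`` via a stick-breaking transform, so simplex constraints on
cue probabilities hold by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "CueSet",
    "Stage",
    "StageWiseDesign",
    "PeriodicDesign",
    "ContingencySchedule",
    "ExperimentRealization",
    "DesignSpace",
    "ValidationReport",
    "validate_design",
    "unroll_schedule",
    "sample_realization",
    "InvalidDesignError",
]

_SIMPLEX_TOL = 1e-9


class InvalidDesignError(ValueError):
    """Raised when an operation requires a valid design and the input is not."""


def _compound_label(members: tuple[str, ...], elements: tuple[str, ...]) -> str:
    return "".join(sorted(members, key=elements.index))


@dataclass(frozen=True)
class CueSet:
    """Elemental cues plus any jointly-presented compounds.

    ``presentable`` orders the stimuli that can occur on a trial: the elements
    first, then the compound labels (e.g. ``("A", "B", "AB")``).
    """

    elements: tuple[str, ...]
    compounds: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.elements)) != len(self.elements):
            raise ValueError("cue labels must be unique")
        norm = []
        for comp in self.compounds:
            members = tuple(comp)
            if len(members) < 2 or not set(members) <= set(self.elements):
                raise ValueError(f"compound {members!r} must be >=2 known elements")
            norm.append(tuple(sorted(members, key=self.elements.index)))
        object.__setattr__(self, "compounds", tuple(norm))

    @property
    def presentable(self) -> tuple[str, ...]:
        labels = list(self.elements)
        labels += [_compound_label(c, self.elements) for c in self.compounds]
        return tuple(labels)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_matrix(self) -> np.ndarray:
        """Binary (n_presentable, n_elements) matrix: which elements each
        presentable stimulus activates."""
        mat = np.zeros((len(self.presentable), self.n_elements))
        for i, el in enumerate(self.elements):
            mat[i, i] = 1.0
        for j, comp in enumerate(self.compounds):
            for el in comp:
                mat[self.n_elements + j, self.elements.index(el)] = 1.0
        return mat


@dataclass(frozen=True)
class Stage:
    """One block of trials with constant transition probabilities."""

    n_trials: int
    cue_probs: dict[str, float]
    outcome_probs: dict[str, float]


@dataclass(frozen=True)
class StageWiseDesign:
    cue_set: CueSet
    stages: tuple[Stage, ...]

    @property
    def n_trials(self) -> int:
        return sum(s.n_trials for s in self.stages)


@dataclass(frozen=True)
class PeriodicDesign:
    """Square-periodic contingencies: each probability cycles between levels
    ``P1`` and ``P2`` with shared half-period ``T`` (fraction of n_trials)."""

    cue_set: CueSet
    n_trials: int
    cue_levels: dict[str, tuple[float, float]]
    outcome_levels: dict[str, tuple[float, float]]
    half_period: float

    @property
    def block_length(self) -> int:
        # ceil discretization: T=1 spans the whole experiment (constant P1)
        return max(1, math.ceil(self.half_period * self.n_trials))


@dataclass(frozen=True)
class ContingencySchedule:
    """Explicit per-trial unrolled form of either parameterization."""

    cue_labels: tuple[str, ...]
    cue_probs: np.ndarray  # (n_trials, n_presentable)
    outcome_probs: np.ndarray  # (n_trials, n_presentable)

    @property
    def n_trials(self) -> int:
        return self.cue_probs.shape[0]


@dataclass(frozen=True)
class ExperimentRealization:
    """A sampled cue-outcome sequence."""

    cue_labels: tuple[str, ...]
    stimulus_idx: np.ndarray  # (n_trials,) int, index into cue_labels
    outcomes: np.ndarray  # (n_trials,) int in {0, 1}

    @property
    def n_trials(self) -> int:
        return self.stimulus_idx.shape[0]

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(self.cue_labels[i] for i in self.stimulus_idx)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "stimulus": list(self.stimuli),
                "outcome": self.outcomes.astype(int),
            }
        )


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...] = ()


def _check_probs(probs: dict[str, float], labels: tuple[str, ...], where: str,
                 violations: list[str], simplex: bool) -> None:
    missing = set(labels) - set(probs)
    if missing:
        violations.append(f"{where}: missing probabilities for {sorted(missing)}")
        return
    vals = [probs[lab] for lab in labels]
    if any(not (0.0 <= v <= 1.0) for v in vals):
        violations.append(f"{where}: probability outside [0, 1]")
    if simplex and abs(sum(vals) - 1.0) > _SIMPLEX_TOL:
        violations.append(f"{where}: cue probabilities sum to {sum(vals):.6g}, not 1")


def validate_design(design: StageWiseDesign | PeriodicDesign) -> ValidationReport:
    """Check bounds, simplex and trial-count constraints; never raises."""
    violations: list[str] = []
    labels = design.cue_set.presentable
    if isinstance(design, StageWiseDesign):
        if not design.stages:
            violations.append("design has no stages")
        for i, st in enumerate(design.stages):
            if st.n_trials < 1:
                violations.append(f"stage {i}: n_trials must be >= 1")
            _check_probs(st.cue_probs, labels, f"stage {i} cue_probs", violations, True)
            _check_probs(st.outcome_probs, labels, f"stage {i} outcome_probs",
                         violations, False)
    elif isinstance(design, PeriodicDesign):
        if design.n_trials < 1:
            violations.append("n_trials must be >= 1")
        if not (0.0 < design.half_period <= 1.0):
            violations.append("half_period must lie in (0, 1]")
        for level in (0, 1):
            p = {lab: design.cue_levels[lab][level] for lab in labels
                 if lab in design.cue_levels}
            _check_probs(p, labels, f"cue level P{level + 1}", violations, True)
            q = {lab: design.outcome_levels[lab][level] for lab in labels
                 if lab in design.outcome_levels}
            _check_probs(q, labels, f"outcome level P{level + 1}", violations, False)
    else:  # pragma: no cover - defensive
        violations.append(f"unknown design type {type(design).__name__}")
    return ValidationReport(ok=not violations, violations=tuple(violations))


def unroll_schedule(design: StageWiseDesign | PeriodicDesign) -> ContingencySchedule:
    """Expand a design into per-trial transition probabilities.

    For periodic designs, trial ``t`` (0-based) uses level P1 when
    ``floor(t / ceil(T * n_trials))`` is even, else P2.
    """
    report = validate_design(design)
    if not report.ok:
        raise InvalidDesignError("; ".join(report.violations))
    labels = design.cue_set.presentable
    if isinstance(design, StageWiseDesign):
        cue_rows, out_rows = [], []
        for st in design.stages:
            cue = [st.cue_probs[lab] for lab in labels]
            out = [st.outcome_probs[lab] for lab in labels]
            cue_rows += [cue] * st.n_trials
            out_rows += [out] * st.n_trials
        return ContingencySchedule(labels, np.array(cue_rows, float),
                                   np.array(out_rows, float))
    block = design.block_length
    t = np.arange(design.n_trials)
    use_p2 = (t // block) % 2 == 1
    cue = np.empty((design.n_trials, len(labels)))
    out = np.empty_like(cue)
    for j, lab in enumerate(labels):
        p1, p2 = design.cue_levels[lab]
        cue[:, j] = np.where(use_p2, p2, p1)
        q1, q2 = design.outcome_levels[lab]
        out[:, j] = np.where(use_p2, q2, q1)
    return ContingencySchedule(labels, cue, out)


def sample_realization(
    schedule: ContingencySchedule, seed: int | np.random.Generator
) -> ExperimentRealization:
    """Sample a cue-outcome sequence from the trial-generating Markov chain.

    Per trial the stimulus is drawn from that trial's cue probabilities and
    the US is then Bernoulli with the stimulus's contingency. Identical seeds
    give identical realizations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = schedule.n_trials
    cum = np.cumsum(schedule.cue_probs, axis=1)
    u = rng.random(n)
    stim = (u[:, None] >= cum).sum(axis=1)
    stim = np.minimum(stim, len(schedule.cue_labels) - 1)
    p_us = schedule.outcome_probs[np.arange(n), stim]
    outcomes = (rng.random(n) < p_us).astype(np.int64)
    return ExperimentRealization(schedule.cue_labels, stim.astype(np.int64), outcomes)


# ---------------------------------------------------------------------------
# Design space: mapping designs <-> [0, 1]^d optimization vectors
# ---------------------------------------------------------------------------


def _stick_to_simplex(v: np.ndarray) -> np.ndarray:
    """Map k-1 free variables in [0,1] to a k-simplex (last coord residual)."""
    k = v.size + 1
    p = np.empty(k)
    rem = 1.0
    for i, vi in enumerate(v):
        p[i] = vi * rem
        rem -= p[i]
    p[-1] = max(rem, 0.0)
    return p


def _simplex_to_stick(p: np.ndarray) -> np.ndarray:
    v = np.empty(p.size - 1)
    rem = 1.0
    for i in range(p.size - 1):
        v[i] = p[i] / rem if rem > 1e-12 else 0.0
        rem -= p[i]
    return np.clip(v, 0.0, 1.0)


@dataclass(frozen=True)
class DesignSpace:
    """Fixed experiment structure plus the free design variables.

    ``parameterization`` is ``"stage_wise"`` or ``"periodic"``. For the
    stage-wise space each stage contributes ``k-1`` cue-probability variables
    (stick-breaking coordinates of the k-simplex) and ``k`` contingencies; the
    periodic space contributes the two levels of every probability plus the
    shared half-period.
    """

    parameterization: str
    cue_set: CueSet
    trials_per_stage: tuple[int, ...] = ()
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.parameterization not in ("stage_wise", "periodic"):
            raise ValueError(f"unknown parameterization {self.parameterization!r}")

    @property
    def _k(self) -> int:
        return len(self.cue_set.presentable)

    @property
    def dim(self) -> int:
        k = self._k
        if self.parameterization == "stage_wise":
            return len(self.trials_per_stage) * (2 * k - 1)
        # periodic: two cue simplices, two contingency levels per stimulus, T
        return 2 * (k - 1) + 2 * k + 1

    @property
    def variable_names(self) -> tuple[str, ...]:
        k = self._k
        labels = self.cue_set.presentable
        names: list[str] = []
        if self.parameterization == "stage_wise":
            for s in range(len(self.trials_per_stage)):
                names += [f"s{s + 1}_cue_stick{i + 1}" for i in range(k - 1)]
                names += [f"s{s + 1}_p_us_given_{lab}" for lab in labels]
        else:
            for lev in (1, 2):
                names += [f"cue_P{lev}_stick{i + 1}" for i in range(k - 1)]
            for lev in (1, 2):
                names += [f"p_us_P{lev}_{lab}" for lab in labels]
            names.append("half_period")
        return tuple(names)

    def from_vector(self, v: np.ndarray) -> StageWiseDesign | PeriodicDesign:
        """Decode a point of the optimizer's box into a valid design."""
        v = np.asarray(v, float)
        if v.shape != (self.dim,):
            raise ValueError(f"expected vector of length {self.dim}, got {v.shape}")
        if np.any(v < 0.0) or np.any(v > 1.0):
            raise ValueError("vector outside [0, 1]^d")
        k = self._k
        labels = self.cue_set.presentable
        if self.parameterization == "stage_wise":
            stages = []
            pos = 0
            for n_tr in self.trials_per_stage:
                cue = _stick_to_simplex(v[pos:pos + k - 1])
                pos += k - 1
                out = v[pos:pos + k]
                pos += k
                stages.append(Stage(n_tr, dict(zip(labels, cue)),
                                    dict(zip(labels, out))))
            return StageWiseDesign(self.cue_set, tuple(stages))
        pos = 0
        cue_lv = []
        for _ in range(2):
            cue_lv.append(_stick_to_simplex(v[pos:pos + k - 1]))
            pos += k - 1
        out_lv = [v[pos:pos + k], v[pos + k:pos + 2 * k]]
        pos += 2 * k
        half_period = max(float(v[pos]), 1.0 / max(self.n_trials, 1))
        return PeriodicDesign(
            self.cue_set,
            self.n_trials,
            {lab: (cue_lv[0][j], cue_lv[1][j]) for j, lab in enumerate(labels)},
            {lab: (out_lv[0][j], out_lv[1][j]) for j, lab in enumerate(labels)},
            half_period,
        )

    def to_vector(self, design: StageWiseDesign | PeriodicDesign) -> np.ndarray:
        labels = self.cue_set.presentable
        out: list[float] = []
        if self.parameterization == "stage_wise":
            if not isinstance(design, StageWiseDesign):
                raise TypeError("space is stage-wise but design is not")
            for st in design.stages:
                p = np.array([st.cue_probs[lab] for lab in labels])
                out += list(_simplex_to_stick(p))
                out += [st.outcome_probs[lab] for lab in labels]
            return np.array(out)
        if not isinstance(design, PeriodicDesign):
            raise TypeError("space is periodic but design is not")
        for lev in (0, 1):
            p = np.array([design.cue_levels[lab][lev] for lab in labels])
            out += list(_simplex_to_stick(p))
        for lev in (0, 1):
            out += [design.outcome_levels[lab][lev] for lab in labels]
        out.append(design.half_period)
        return np.array(out)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def design_to_dict(design: StageWiseDesign | PeriodicDesign) -> dict:
    doc: dict = {
        "cues": list(design.cue_set.elements),
        "compounds": [list(c) for c in design.cue_set.compounds],
    }
    if isinstance(design, StageWiseDesign):
        doc["parameterization"] = "stage_wise"
        doc["stages"] = [
            {
                "n_trials": st.n_trials,
                "cue_probs": {k: float(v) for k, v in st.cue_probs.items()},
                "outcome_probs": {k: float(v) for k, v in st.outcome_probs.items()},
            }
            for st in design.stages
        ]
    else:
        doc["parameterization"] = "periodic"
        doc["n_trials"] = design.n_trials
        doc["periodic"] = {
            "half_period": float(design.half_period),
            "cue_levels": {k: [float(a), float(b)]
                           for k, (a, b) in design.cue_levels.items()},
            "outcome_levels": {k: [float(a), float(b)]
                               for k, (a, b) in design.outcome_levels.items()},
        }
    return doc


def design_from_dict(doc: dict) -> StageWiseDesign | PeriodicDesign:
    cue_set = CueSet(tuple(doc["cues"]),
                     tuple(tuple(c) for c in doc.get("compounds", [])))
    if doc["parameterization"] == "stage_wise":
        stages = tuple(
            Stage(s["n_trials"], dict(s["cue_probs"]), dict(s["outcome_probs"]))
            for s in doc["stages"]
        )
        return StageWiseDesign(cue_set, stages)
    per = doc["periodic"]
    return PeriodicDesign(
        cue_set,
        doc["n_trials"],
        {k: tuple(v) for k, v in per["cue_levels"].items()},
        {k: tuple(v) for k, v in per["outcome_levels"].items()},
        per["half_period"],
    )


def save_design(design, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def load_design(path):
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))
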