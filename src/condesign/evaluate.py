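"""Design-comparison statistics.

Designs are compared through effect sizes with confidence intervals rather
than p-values: the common language effect size (CLES) for utility
distributions, odds ratios (Woolf's log-scale CI with the Haldane-Anscombe
zero-cell correction) for selection accuracies, exact Clopper-Pearson
binomial intervals for per-design accuracies, and confusion matrices with
per-model recovery rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta, norm

__all__ = [
    "cles",
    "percentile_bootstrap_ci",
    "clopper_pearson",
    "odds_ratio_woolf",
    "confusion_matrix",
    "ComparisonReport",
    "compare_utility_vectors",
]


def cles(u_x: np.ndarray, u_y: np.ndarray) -> float:
    """Common language effect size: P(draw from x beats draw from y).

    Computed over all cross pairs; ties count one half. 0.5 indicates designs
    of equal quality.
    """
    u_x = np.asarray(u_x, float)
    u_y = np.asarray(u_y, float)
    if u_x.size == 0 or u_y.size == 0:
        raise ValueError("utility vectors must be non-empty")
    diff = u_x[:, None] - u_y[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def percentile_bootstrap_ci(
    u_x: np.ndarray,
    u_y: np.ndarray,
    statistic=cles,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap CI for an unpaired two-sample statistic.

    The two vectors are resampled with replacement independently.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    u_x = np.asarray(u_x, float)
    u_y = np.asarray(u_y, float)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        bx = u_x[rng.integers(0, u_x.size, u_x.size)]
        by = u_y[rng.integers(0, u_y.size, u_y.size)]
        stats[b] = statistic(bx, by)
    lo = (1.0 - level) / 2.0
    return float(np.quantile(stats, lo)), float(np.quantile(stats, 1.0 - lo))


def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta quantiles."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(beta.ppf(alpha / 2, successes,
                                                   n - successes + 1))
    hi = 1.0 if successes == n else float(beta.ppf(1 - alpha / 2, successes + 1,
                                                   n - successes))
    return lo, hi


def odds_ratio_woolf(
    correct_a: int,
    n_a: int,
    correct_b: int,
    n_b: int,
    level: float = 0.95,
    always_correct: bool = False,
) -> tuple[float, float, float]:
    """Odds ratio of design A being correct vs design B, with Woolf's CI.

    When any cell of the 2x2 table is zero (or ``always_correct``), 0.5 is
    added to all four cells (Haldane-Anscombe) before computing. OR = 1
    indicates designs of equal expected utility.
    """
    if n_a < 1 or n_b < 1:
        raise ValueError("both designs need at least one simulation")
    a, b = float(correct_a), float(n_a - correct_a)
    c, d = float(correct_b), float(n_b - correct_b)
    if always_correct or min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    return float(or_), float(np.exp(log_or - half)), float(np.exp(log_or + half))


def confusion_matrix(
    truth: list[str], selected: list[str], model_space: list[str]
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Counts of (ground truth model x selected model) plus recovery rates.

    Rows are ground truth, columns the selected model; recovery rate is the
    diagonal over the row sum.
    """
    if len(truth) != len(selected):
        raise ValueError("truth and selected must have equal length")
    unknown = (set(truth) | set(selected)) - set(model_space)
    if unknown:
        raise ValueError(f"unknown model labels {sorted(unknown)}")
    mat = pd.DataFrame(0, index=model_space, columns=model_space, dtype=int)
    for t, s in zip(truth, selected):
        mat.loc[t, s] += 1
    rates = {}
    for m in model_space:
        row = mat.loc[m].sum()
        rates[m] = float(mat.loc[m, m] / row) if row else float("nan")
    return mat, rates


@dataclass
class ComparisonReport:
    """Pairwise design comparison built from per-simulation results."""

    design_ids: list[str]
    cles_pairs: dict[str, dict]
    accuracy: dict[str, dict] | None = None
    odds_ratios: dict[str, dict] | None = None
    confusion: dict[str, dict] | None = None

    def to_dict(self) -> dict:
        return {
            "design_ids": self.design_ids,
            "cles": self.cles_pairs,
            "accuracy": self.accuracy,
            "odds_ratios": self.odds_ratios,
            "confusion": self.confusion,
        }


def compare_utility_vectors(
    utilities: dict[str, np.ndarray],
    selection: bool = False,
    records: dict[str, list] | None = None,
    model_space: list[str] | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> ComparisonReport:
    """Build a full comparison report from per-design utility vectors.

    For selection scenarios (0-1 utilities) also computes per-design
    accuracies with Clopper-Pearson CIs, pairwise odds ratios, and — when
    per-simulation records and a model space are given — confusion matrices.
    """
    ids = list(utilities)
    cles_pairs: dict[str, dict] = {}
    for i, a in enumerate(ids):
        for b_id in ids[i + 1:]:
            point = cles(utilities[a], utilities[b_id])
            lo, hi = percentile_bootstrap_ci(utilities[a], utilities[b_id],
                                             n_boot=n_boot, level=level, seed=seed)
            cles_pairs[f"{a} vs {b_id}"] = {"cles": point, "ci": [lo, hi]}
    report = ComparisonReport(ids, cles_pairs)
    if selection:
        report.accuracy = {}
        report.odds_ratios = {}
        for did in ids:
            u = np.asarray(utilities[did])
            k, n = int(u.sum()), u.size
            lo, hi = clopper_pearson(k, n, level)
            report.accuracy[did] = {"accuracy": k / n, "n": n, "ci": [lo, hi]}
        for i, a in enumerate(ids):
            for b_id in ids[i + 1:]:
                ua, ub = np.asarray(utilities[a]), np.asarray(utilities[b_id])
                or_, lo, hi = odds_ratio_woolf(int(ua.sum()), ua.size,
                                               int(ub.sum()), ub.size, level)
                report.odds_ratios[f"{a} vs {b_id}"] = {"or": or_, "ci": [lo, hi]}
        if records and model_space:
            report.confusion = {}
            for did in ids:
                recs = records[did]
                mat, rates = confusion_matrix(
                    [r["true_model"] for r in recs],
                    [r["selected_model"] for r in recs],
                    model_space,
                )
                report.confusion[did] = {
                    "matrix": {m: mat.loc[m].to_dict() for m in model_space},
                    "recovery_rates": rates,
                }
    return report
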