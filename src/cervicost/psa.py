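"""Monte Carlo probabilistic sensitivity analysis over both device arms.

Each trial draws one :class:`~cervicost.parameters.ParameterSet` shared by
the two devices (common random numbers / paired design), evaluates the
screening tree and economics for both arms, and records every metric plus
the broom-minus-spatula incrementals.  Summaries report the mean with a
95 % confidence interval of the mean (the default, matching the very
narrow published intervals) and, alternatively, the empirical 2.5th–97.5th
percentile interval of the trial distribution.

The whole engine is vectorized across trials — the tree's closed-form
expectations broadcast — so 10,000 trials run in well under a second while
remaining bit-identical to looping ``sample_parameters`` trial by trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import CostSet, cost_cohort, incremental
from .parameters import ParameterRegistry, sample_trial_matrix
from .tree import DEFAULT_MAX_ROUNDS, device_from_parameters, evaluate_cohort

__all__ = ["MeanCI", "PsaResult", "run_psa", "summarize_mean_ci", "DEFAULT_N_TRIALS"]

Z95 = 1.959964

#: trials per Monte Carlo run
DEFAULT_N_TRIALS = 10_000

DEVICES = ("spatula", "broom")

#: per-arm metric columns recorded for every trial
ARM_METRICS = (
    "programme_cost",
    "cost_per_woman",
    "cost_per_hsil",
    "abnormal_detected",
    "hsil_detected",
    "false_negatives",
    "lost_to_care",
    "expected_smears",
)

#: broom-minus-spatula incremental columns
DIFF_METRICS = (
    "d_programme_cost",
    "d_cost_per_woman",
    "d_cost_per_hsil",
    "d_abnormal_detected",
    "d_hsil_detected",
    "d_false_negatives",
    "d_lost_to_care",
)


@dataclass(frozen=True)
class MeanCI:
    """Mean with its 95 % CI and the empirical percentile interval."""

    mean: float
    ci_low: float
    ci_high: float
    p2_5: float
    p97_5: float
    n: int

    def interval(self, mode: str = "ci_of_mean") -> tuple[float, float]:
        if mode == "ci_of_mean":
            return self.ci_low, self.ci_high
        if mode == "percentile":
            return self.p2_5, self.p97_5
        raise ValueError(f"unknown interval mode {mode!r}")


def summarize_mean_ci(trial_values) -> MeanCI:
    """Mean, 95 % CI of the mean, and empirical 2.5/97.5 percentiles.

    The CI of the mean is ``mean ± 1.959964 x sd / sqrt(n)`` (sd with one
    delta degree of freedom).  Requires at least two values.
    """
    x = np.asarray(trial_values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("summarize_mean_ci needs at least 2 (non-NaN) values")
    m = float(x.mean())
    half = Z95 * float(x.std(ddof=1)) / np.sqrt(x.size)
    lo, hi = np.percentile(x, [2.5, 97.5])
    return MeanCI(m, m - half, m + half, float(lo), float(hi), int(x.size))


@dataclass
class PsaResult:
    """Per-trial draws and summaries of one probabilistic sensitivity run."""

    practice: str
    n_trials: int
    seed: int
    trials: pd.DataFrame
    n_excluded_ratio: int  # trials with zero HSIL detected in either arm

    def mean_ci(self, column: str) -> MeanCI:
        return summarize_mean_ci(self.trials[column].to_numpy())

    def mean(self, column: str) -> float:
        return self.mean_ci(column).mean

    def summary(self, interval: str = "ci_of_mean") -> pd.DataFrame:
        """One row per recorded metric: mean and 95 % interval bounds."""
        rows = []
        for col in self.trials.columns:
            s = self.mean_ci(col)
            lo, hi = s.interval(interval)
            rows.append(
                {"metric": col, "mean": s.mean, "ci_low": lo, "ci_high": hi, "n": s.n}
            )
        return pd.DataFrame(rows).set_index("metric")

    def to_csv(self, path) -> None:
        """Raw per-trial draws: one row per trial, one column per metric."""
        self.trials.to_csv(path, index_label="trial")


def run_psa(
    registry: ParameterRegistry,
    practice: str,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    *,
    max_rounds: int | None = DEFAULT_MAX_ROUNDS,
    include_false_positives: bool = False,
    interval: str = "central95",
    proportion_dist: str = "truncnorm",
) -> PsaResult:
    """Run the paired Monte Carlo PSA for one practice model.

    Deterministic for fixed ``(seed, n_trials)``.  Trials in which either
    arm detects zero HSIL are kept for count metrics but excluded (NaN)
    from the cost-per-HSIL ratios; their number is reported on the result.
    """
    if n_trials < 2:
        raise ValueError("run_psa needs n_trials >= 2")
    values = sample_trial_matrix(
        registry, seed, n_trials, interval=interval, proportion_dist=proportion_dist
    )
    costs = CostSet.from_parameters(values)
    econ = {}
    for dev in DEVICES:
        profile = device_from_parameters(values, dev)
        outcome = evaluate_cohort(
            values,
            profile,
            practice,
            max_rounds=max_rounds,
            include_false_positives=include_false_positives,
        )
        econ[dev] = cost_cohort(outcome, costs, profile)

    data: dict[str, np.ndarray] = {}
    for dev in DEVICES:
        r = econ[dev]
        data[f"{dev}_programme_cost"] = np.asarray(r.programme_cost, dtype=float)
        data[f"{dev}_cost_per_woman"] = np.asarray(r.cost_per_woman, dtype=float)
        data[f"{dev}_cost_per_hsil"] = np.asarray(r.cost_per_hsil_detected, dtype=float)
        data[f"{dev}_abnormal_detected"] = np.asarray(
            r.outcome.detected_abnormal_total, dtype=float
        )
        data[f"{dev}_hsil_detected"] = np.asarray(r.outcome.detected_hsil, dtype=float)
        data[f"{dev}_false_negatives"] = np.asarray(
            r.outcome.false_negatives_reported, dtype=float
        )
        data[f"{dev}_lost_to_care"] = np.asarray(r.outcome.lost_to_care, dtype=float)
        data[f"{dev}_expected_smears"] = np.asarray(
            r.outcome.expected_smears_per_woman, dtype=float
        )

    inc = incremental(econ["spatula"], econ["broom"])
    pair = {
        "d_programme_cost": "programme_cost",
        "d_cost_per_woman": "cost_per_woman",
        "d_cost_per_hsil": "cost_per_hsil_detected",
        "d_abnormal_detected": "abnormal_detected",
        "d_hsil_detected": "hsil_detected",
        "d_false_negatives": "false_negatives",
        "d_lost_to_care": "lost_to_care",
    }
    for col, metric in pair.items():
        data[col] = np.asarray(inc.difference[metric], dtype=float)

    degenerate = (data["spatula_hsil_detected"] <= 0) | (data["broom_hsil_detected"] <= 0)
    n_excluded = int(degenerate.sum())
    if n_excluded:
        for col in ("spatula_cost_per_hsil", "broom_cost_per_hsil", "d_cost_per_hsil"):
            data[col] = np.where(degenerate, np.nan, data[col])

    trials = pd.DataFrame(data)
    trials.index.name = "trial"
    return PsaResult(
        practice=practice,
        n_trials=n_trials,
        seed=seed,
        trials=trials,
        n_excluded_ratio=n_excluded,
    )
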