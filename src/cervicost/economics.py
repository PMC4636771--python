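"""Costing of cohort outcomes and device-vs-device incremental results.

Every smear taken (first or repeat) consumes exactly one outpatient visit,
one laboratory cytology test and one collection device; nothing else is
costed — no colposcopy, treatment, tracing or patient-side costs.  The
three headline metrics are the annual programme cost, the cost per woman
screened, and the cost per HSIL case detected.

The incremental per-HSIL metric is, by default, the *difference of the two
cost-per-HSIL ratios* (the published arithmetic); a conventional
incremental cost-effectiveness ratio (ICER: delta cost / delta HSIL) is
available separately and labelled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .parameters import ParameterSet
from .tree import CohortOutcome, DeviceProfile

__all__ = [
    "CostSet",
    "EconResult",
    "IncrementalResult",
    "cost_cohort",
    "incremental",
    "icer",
    "INCREMENTAL_METRICS",
]


@dataclass(frozen=True)
class CostSet:
    """Unit costs (2014 USD): outpatient visit and laboratory test.

    The collection-device cost lives on the :class:`DeviceProfile`.
    """

    visit: float
    lab: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.visit) < 0) or np.any(np.asarray(self.lab) < 0):
            raise ValueError("unit costs must be non-negative")

    @classmethod
    def from_parameters(cls, params: ParameterSet | Mapping) -> "CostSet":
        return cls(visit=params["cost_clinic_visit"], lab=params["cost_lab_test"])


@dataclass
class EconResult:
    """Programme cost and the derived cost metrics for one device arm."""

    programme_cost: float
    cost_per_woman: float
    cost_per_hsil_detected: float  # NaN when no HSIL detected
    outcome: CohortOutcome
    device: str
    practice: str


def cost_cohort(
    outcome: CohortOutcome, costs: CostSet, device: DeviceProfile
) -> EconResult:
    """Cost one evaluated cohort.

    ``programme_cost = n_women x E[smears/woman] x (visit + lab + device)``.
    A cohort with zero detected HSIL yields ``cost_per_hsil_detected = NaN``
    (an undefined marker, not an exception).
    """
    per_smear = costs.visit + costs.lab + device.unit_cost
    programme = outcome.n_women * outcome.expected_smears_per_woman * per_smear
    per_woman = programme / outcome.n_women
    hsil = outcome.detected_hsil
    with np.errstate(divide="ignore", invalid="ignore"):
        per_hsil = np.where(np.asarray(hsil) > 0, programme / np.where(
            np.asarray(hsil) > 0, hsil, 1.0), np.nan)
    if np.ndim(per_hsil) == 0:
        per_hsil = float(per_hsil)
    return EconResult(
        programme_cost=programme,
        cost_per_woman=per_woman,
        cost_per_hsil_detected=per_hsil,
        outcome=outcome,
        device=outcome.device or device.name,
        practice=outcome.practice,
    )


#: metric name -> (attribute path, is_cost) used for incremental comparisons
INCREMENTAL_METRICS = (
    "programme_cost",
    "cost_per_woman",
    "cost_per_hsil_detected",
    "abnormal_detected",
    "hsil_detected",
    "false_negatives",
    "lost_to_care",
)


def _metric(res: EconResult, name: str):
    if name == "programme_cost":
        return res.programme_cost
    if name == "cost_per_woman":
        return res.cost_per_woman
    if name == "cost_per_hsil_detected":
        return res.cost_per_hsil_detected
    if name == "abnormal_detected":
        return res.outcome.detected_abnormal_total
    if name == "hsil_detected":
        return res.outcome.detected_hsil
    if name == "false_negatives":
        return res.outcome.false_negatives_reported
    if name == "lost_to_care":
        return res.outcome.lost_to_care
    raise KeyError(name)


@dataclass
class IncrementalResult:
    """Differences (alternative minus base) and percent changes per metric.

    ``classification`` is ``"dominant"`` when the alternative is both
    cheaper (lower programme cost) and more effective (more HSIL detected),
    ``"trade-off"`` otherwise.
    """

    base_device: str
    alt_device: str
    practice: str
    base: dict
    alt: dict
    difference: dict
    percent_change: dict
    classification: str

    def __getitem__(self, metric: str):
        return self.difference[metric]


def incremental(base: EconResult, alt: EconResult) -> IncrementalResult:
    """Compare two device arms evaluated under the same practice model.

    Percent changes are relative to the base arm.  The per-HSIL entry is
    the difference of the two cost-per-HSIL ratios; see :func:`icer` for
    the delta-cost / delta-effect statistic.
    """
    if base.practice != alt.practice:
        raise ValueError(
            f"cannot compare practices {base.practice!r} and {alt.practice!r}"
        )
    base_vals = {m: _metric(base, m) for m in INCREMENTAL_METRICS}
    alt_vals = {m: _metric(alt, m) for m in INCREMENTAL_METRICS}
    diff = {m: alt_vals[m] - base_vals[m] for m in INCREMENTAL_METRICS}
    pct = {}
    for m in INCREMENTAL_METRICS:
        b = base_vals[m]
        with np.errstate(divide="ignore", invalid="ignore"):
            pct[m] = np.where(np.asarray(b) != 0, np.asarray(diff[m]) / np.asarray(b), np.nan)
        if np.ndim(pct[m]) == 0:
            pct[m] = float(pct[m])
    cheaper = np.all(np.asarray(diff["programme_cost"]) < 0)
    more_effective = np.all(np.asarray(diff["hsil_detected"]) > 0)
    classification = "dominant" if (cheaper and more_effective) else "trade-off"
    return IncrementalResult(
        base_device=base.device,
        alt_device=alt.device,
        practice=base.practice,
        base=base_vals,
        alt=alt_vals,
        difference=diff,
        percent_change=pct,
        classification=classification,
    )


def icer(base: EconResult, alt: EconResult):
    """Incremental cost-effectiveness ratio: delta cost per extra HSIL detected.

    Negative with a positive effect delta means the alternative dominates.
    NaN when the effect delta is zero.
    """
    if base.practice != alt.practice:
        raise ValueError("cannot compare results from different practice models")
    d_cost = alt.programme_cost - base.programme_cost
    d_eff = alt.outcome.detected_hsil - base.outcome.detected_hsil
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.asarray(d_eff) != 0, np.asarray(d_cost) / np.asarray(d_eff), np.nan)
    return float(out) if np.ndim(out) == 0 else out
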