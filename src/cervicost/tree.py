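"""Decision-tree engine for one screening round and its recall loop.

A cohort of HIV-infected women receives conventional cytology.  Each smear
has a device-dependent probability of containing endocervical cells and an
independent probability of being satisfactory for evaluation.  Abnormal
disease (ASC-US / LSIL / HSIL) is reported with a sensitivity that depends
on endocervical-cell presence (grade-split when absent); women without
disease are falsely reported abnormal at one minus specificity.  Detected
abnormalities are always reported, whether or not endocervical cells are
present.

Two practice variants differ only in what triggers a recall for a repeat
smear:

* ``guidelines`` (intended practice): a negative report lacking
  endocervical cells, or an unsatisfactory smear, triggers recall;
* ``typical`` practice: only an unsatisfactory smear triggers recall — a
  negative inadequate smear becomes a final (potentially false-negative)
  result.

A recalled woman returns with probability ``p_return`` and, once back,
actually receives the repeat smear with probability
``p_repeat_given_return``; failing either step she is lost to care without
a diagnosis.  Repeat smears draw adequacy independently of earlier rounds.
The loop runs to ``max_rounds`` smears per woman (women still recalled
after the last permitted smear are lost to care) or, with
``max_rounds=None``, to absorption.  The default is ``max_rounds=2`` — a
single repeat — which reproduces the published programme costs and
detection gains; see the methods note for the audit behind that choice.

All expectations are closed-form geometric sums, so every function accepts
scalars or numpy arrays (the Monte Carlo engine evaluates all trials at
once).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "GRADES",
    "TRUE_STATES",
    "DEFAULT_MAX_ROUNDS",
    "DeviceProfile",
    "TestPerformance",
    "FlowParams",
    "GradeMix",
    "CohortOutcome",
    "round_outcome",
    "evaluate_cohort",
    "expected_rounds",
    "cohort_size",
    "device_from_parameters",
    "tree_outline",
]

GRADES = ("hsil", "lsil", "ascus")
TRUE_STATES = ("negative",) + GRADES
PRACTICES = ("guidelines", "typical")

#: maximum smears per woman: one repeat after the initial smear
DEFAULT_MAX_ROUNDS = 2

#: absorption guard for the unbounded loop
HARD_ROUND_CAP = 10_000


@dataclass(frozen=True)
class DeviceProfile:
    """A collection device: its unit cost and adequacy performance."""

    name: str
    unit_cost: float
    p_endocervical: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.unit_cost) < 0):
            raise ValueError(f"{self.name}: negative unit cost")
        p = np.asarray(self.p_endocervical)
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError(f"{self.name}: p_endocervical outside [0, 1]")


def device_from_parameters(params: ParameterSet | Mapping, name: str) -> DeviceProfile:
    """Build the spatula or broom profile from a parameter set."""
    if name not in ("spatula", "broom"):
        raise ValueError(f"unknown device {name!r}")
    return DeviceProfile(
        name=name,
        unit_cost=params[f"cost_{name}"],
        p_endocervical=params[f"p_endocervical_{name}"],
    )


@dataclass(frozen=True)
class TestPerformance:
    """Cytology sensitivity/specificity by endocervical-cell presence.

    The with-endocervical sensitivity applies uniformly to all grades; only
    the no-endocervical case is grade-split (HSIL vs the rest).
    """

    sens_endo: float
    sens_no_endo: float
    sens_no_endo_hsil: float
    specificity: float

    @classmethod
    def from_parameters(cls, params: ParameterSet | Mapping) -> "TestPerformance":
        return cls(
            sens_endo=params["sensitivity_with_endocervical"],
            sens_no_endo=params["sensitivity_no_endocervical"],
            sens_no_endo_hsil=params["sensitivity_no_endocervical_hsil"],
            specificity=params["specificity"],
        )

    def sensitivity(self, grade: str, endocervical: bool) -> float:
        if grade not in GRADES:
            raise ValueError(f"unknown grade {grade!r}")
        if endocervical:
            return self.sens_endo
        return self.sens_no_endo_hsil if grade == "hsil" else self.sens_no_endo


@dataclass(frozen=True)
class FlowParams:
    """Adequacy and recall-loop probabilities."""

    p_satisfactory: float
    p_return: float
    p_repeat_given_return: float
    max_rounds: int | None = DEFAULT_MAX_ROUNDS

    def __post_init__(self) -> None:
        if self.max_rounds is not None and self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1 (or None for unbounded)")

    @property
    def p_repeat_effective(self) -> float:
        """P(a recalled woman actually receives the repeat smear)."""
        return self.p_return * self.p_repeat_given_return

    @classmethod
    def from_parameters(
        cls, params: ParameterSet | Mapping, *, max_rounds: int | None = DEFAULT_MAX_ROUNDS
    ) -> "FlowParams":
        return cls(
            p_satisfactory=params["p_satisfactory"],
            p_return=1.0 - params["p_lost_to_followup"],
            p_repeat_given_return=params["p_repeat_done"],
            max_rounds=max_rounds,
        )


@dataclass(frozen=True)
class GradeMix:
    """True-disease composition of the screened cohort (fractions of women)."""

    f_hsil: float
    f_lsil: float
    f_ascus: float

    @property
    def p_abnormal(self) -> float:
        return self.f_hsil + self.f_lsil + self.f_ascus

    @property
    def p_negative(self) -> float:
        return 1.0 - self.p_abnormal

    def fraction(self, state: str) -> float:
        if state == "negative":
            return self.p_negative
        if state in GRADES:
            return getattr(self, f"f_{state}")
        raise ValueError(f"unknown true state {state!r}")

    @classmethod
    def from_parameters(cls, params: ParameterSet | Mapping) -> "GradeMix":
        return cls(f_hsil=params["f_hsil"], f_lsil=params["f_lsil"], f_ascus=params["f_ascus"])


def cohort_size(params: ParameterSet | Mapping):
    """Annual HIV-infected cohort: screening volume x HIV-positive fraction."""
    return params["women_tested_annual"] * params["hiv_positive_fraction"]


# ---------------------------------------------------------------------------
# single-round branch probabilities


def _round_probabilities(true_state, device, perf, flow, practice):
    """Per-smear probabilities (reported_abnormal, final_negative, recall).

    An unsatisfactory smear cannot be read and always triggers recall.  On a
    satisfactory smear the laboratory reports abnormal with the applicable
    sensitivity (disease) or 1 - specificity (no disease) regardless of
    endocervical-cell presence; a negative report lacking endocervical
    cells is recalled under guidelines practice and final under typical
    practice.
    """
    if practice not in PRACTICES:
        raise ValueError(f"unknown practice {practice!r}")
    if true_state not in TRUE_STATES:
        raise ValueError(f"unknown true state {true_state!r}")
    p_e = device.p_endocervical
    p_sat = flow.p_satisfactory
    if true_state == "negative":
        p_pos_endo = p_pos_no_endo = 1.0 - perf.specificity
    else:
        p_pos_endo = perf.sens_endo
        p_pos_no_endo = (
            perf.sens_no_endo_hsil if true_state == "hsil" else perf.sens_no_endo
        )
    reported_abnormal = p_sat * (p_e * p_pos_endo + (1.0 - p_e) * p_pos_no_endo)
    neg_endo = p_sat * p_e * (1.0 - p_pos_endo)
    neg_no_endo = p_sat * (1.0 - p_e) * (1.0 - p_pos_no_endo)
    unsat = 1.0 - p_sat
    if practice == "guidelines":
        recall = unsat + neg_no_endo
        final_negative = neg_endo
    else:
        recall = unsat
        final_negative = neg_endo + neg_no_endo
    return reported_abnormal, final_negative, recall


def round_outcome(
    true_state: str,
    device: DeviceProfile,
    perf: TestPerformance,
    flow: FlowParams,
    practice: str,
) -> dict:
    """Single-smear outcome distribution for one true state.

    Returns a probability map over ``reported_abnormal`` (an abnormal
    report: true or false positive), ``final_negative`` (a negative result
    accepted as final this round) and ``recall`` (woman asked to return for
    a repeat smear).  The three probabilities sum to one.
    """
    a, f, r = _round_probabilities(true_state, device, perf, flow, practice)
    return {"reported_abnormal": a, "final_negative": f, "recall": r}


# ---------------------------------------------------------------------------
# recall-loop absorption


def _absorb(a, f, r, q, max_rounds):
    """Terminal-state probabilities of the recall loop.

    Per round: abnormal report ``a``, final negative ``f``, recall ``r``
    (a + f + r = 1); a recalled woman re-enters the loop with probability
    ``q`` and is lost otherwise.  Women still recalled after round
    ``max_rounds`` are lost to care.  Returns
    ``(p_reported, p_final_negative, p_lost, expected_smears)``.
    """
    rq = np.asarray(r) * q
    if max_rounds is None:
        if np.any(rq >= 1.0 - 1e-12):
            raise RuntimeError(
                f"recall loop does not converge within {HARD_ROUND_CAP} rounds "
                "(per-round recall-and-repeat probability is 1)"
            )
        s_total = 1.0 / (1.0 - rq)
        p_lost = r * (1.0 - q) * s_total
        p_rep = a * s_total
        p_fn = f * s_total
        return p_rep, p_fn, p_lost, s_total
    d = int(max_rounds)
    # geometric partial sums over rounds 1..d and 1..d-1
    with np.errstate(divide="ignore", invalid="ignore"):
        s_d = np.where(rq == 1.0, float(d), (1.0 - rq**d) / (1.0 - rq))
        s_dm1 = np.where(rq == 1.0, float(d - 1), (1.0 - rq ** (d - 1)) / (1.0 - rq))
    p_rep = a * s_d
    p_fn = f * s_d
    p_lost = r * (1.0 - q) * s_dm1 + rq ** (d - 1) * r
    return p_rep, p_fn, p_lost, s_d


@dataclass
class CohortOutcome:
    """Expected annual counts over the model's terminal states.

    All counts are real-valued expectations; rounding happens only at
    report rendering.  ``detected_abnormal_total`` counts true-positive
    detections by default; set ``include_false_positives=True`` on
    :func:`evaluate_cohort` to add false positives to the total (the
    alternative reading of the published detection rows).
    """

    n_women: float
    detected_abnormal_total: float
    detected_by_grade: dict
    false_positives: float
    true_negative_diagnosed: float
    false_negatives_reported: float
    lost_to_care: float
    expected_smears_per_woman: float
    expected_visits_per_woman: float
    device: str = ""
    practice: str = ""

    @property
    def detected_hsil(self) -> float:
        return self.detected_by_grade["hsil"]

    def as_dict(self) -> dict:
        out = {
            "n_women": self.n_women,
            "detected_abnormal_total": self.detected_abnormal_total,
            "false_positives": self.false_positives,
            "true_negative_diagnosed": self.true_negative_diagnosed,
            "false_negatives_reported": self.false_negatives_reported,
            "lost_to_care": self.lost_to_care,
            "expected_smears_per_woman": self.expected_smears_per_woman,
            "expected_visits_per_woman": self.expected_visits_per_woman,
        }
        for g in GRADES:
            out[f"detected_{g}"] = self.detected_by_grade[g]
        return out


def evaluate_cohort(
    params: ParameterSet | Mapping,
    device: DeviceProfile | str,
    practice: str,
    *,
    max_rounds: int | None = DEFAULT_MAX_ROUNDS,
    include_false_positives: bool = False,
) -> CohortOutcome:
    """Expected terminal-state counts for one device and practice model.

    ``device`` may be a :class:`DeviceProfile` or the name ``"spatula"`` /
    ``"broom"`` (profile built from ``params``).  Scalar parameters give a
    scalar outcome; array-valued parameters broadcast elementwise (one
    outcome per Monte Carlo trial).
    """
    if isinstance(device, str):
        device = device_from_parameters(params, device)
    perf = TestPerformance.from_parameters(params)
    flow = FlowParams.from_parameters(params, max_rounds=max_rounds)
    mix = GradeMix.from_parameters(params)
    n = cohort_size(params)
    q = flow.p_repeat_effective

    detected = {}
    fn_total = 0.0
    lost_total = 0.0
    e_smears = 0.0
    checks = []
    for state in TRUE_STATES:
        a, f, r = _round_probabilities(state, device, perf, flow, practice)
        p_rep, p_fin, p_lost, s = _absorb(a, f, r, q, flow.max_rounds)
        checks.append((state, p_rep + p_fin + p_lost))
        w = mix.fraction(state)
        if state == "negative":
            false_positives = n * w * p_rep
            true_negative = n * w * p_fin
        else:
            detected[state] = n * w * p_rep
            fn_total = fn_total + n * w * p_fin
        lost_total = lost_total + n * w * p_lost
        e_smears = e_smears + w * s

    for state, total in checks:
        if np.any(np.abs(np.asarray(total) - 1.0) > 1e-9):
            raise AssertionError(
                f"terminal probabilities for state {state!r} sum to {total}, not 1"
            )

    tp_total = sum(detected.values())
    total_detected = tp_total + false_positives if include_false_positives else tp_total
    return CohortOutcome(
        n_women=n,
        detected_abnormal_total=total_detected,
        detected_by_grade=detected,
        false_positives=false_positives,
        true_negative_diagnosed=true_negative,
        false_negatives_reported=fn_total,
        lost_to_care=lost_total,
        expected_smears_per_woman=e_smears,
        expected_visits_per_woman=e_smears,  # one clinic visit per smear taken
        device=device.name,
        practice=practice,
    )


def expected_rounds(
    params: ParameterSet | Mapping,
    device: DeviceProfile | str,
    practice: str,
    *,
    max_rounds: int | None = DEFAULT_MAX_ROUNDS,
):
    """Expected smears taken per woman entering the programme (>= 1)."""
    out = evaluate_cohort(params, device, practice, max_rounds=max_rounds)
    return out.expected_smears_per_woman


def tree_outline(
    params: ParameterSet | Mapping,
    device: DeviceProfile | str,
    practice: str,
    *,
    max_rounds: int | None = DEFAULT_MAX_ROUNDS,
) -> str:
    """Human-readable dump of the branch probabilities, for audit."""
    if isinstance(device, str):
        device = device_from_parameters(params, device)
    perf = TestPerformance.from_parameters(params)
    flow = FlowParams.from_parameters(params, max_rounds=max_rounds)
    mix = GradeMix.from_parameters(params)
    q = flow.p_repeat_effective
    depth = "unbounded" if flow.max_rounds is None else str(flow.max_rounds)
    lines = [
        f"screening tree — device={device.name}, practice={practice}, "
        f"max smears/woman={depth}",
        f"  P(endocervical cells) = {device.p_endocervical:.4f}   "
        f"P(satisfactory) = {flow.p_satisfactory:.4f}",
        f"  P(repeat | recalled) = {flow.p_return:.2f} x "
        f"{flow.p_repeat_given_return:.2f} = {q:.4f}",
    ]
    for state in TRUE_STATES:
        a, f, r = _round_probabilities(state, device, perf, flow, practice)
        p_rep, p_fin, p_lost, s = _absorb(a, f, r, q, flow.max_rounds)
        lines.append(
            f"  {state:<8} (cohort fraction {mix.fraction(state):.2f})"
        )
        lines.append(
            f"    per smear : abnormal report {a:.4f} | final negative {f:.4f} "
            f"| recall {r:.4f}"
        )
        lines.append(
            f"    terminal  : reported {p_rep:.4f} | final negative {p_fin:.4f} "
            f"| lost to care {p_lost:.4f} | E[smears] {s:.4f}"
        )
    return "\n".join(lines)
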