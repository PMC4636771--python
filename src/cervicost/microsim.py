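"""Individual-level synthetic cohort generator and brute-force oracle.

Women are simulated one at a time (vectorized) through exactly the branch
logic of :mod:`cervicost.tree` — true grade, per-smear endocervical-cell
presence, satisfactoriness, reported result, recall/return/repeat/loss —
and every smear is emitted as a laboratory-style slide record.  Tallying
the records reproduces the tree engine's expected counts up to binomial
noise, which is the package's core validation: the expectation algebra is
checked against an independent brute-force count, not against itself.

The record stream is also the package's synthetic stand-in for national
laboratory registry extracts (one row per slide, CSV-writable with a
documented header).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .tree import (
    DEFAULT_MAX_ROUNDS,
    GRADES,
    HARD_ROUND_CAP,
    CohortOutcome,
    DeviceProfile,
    FlowParams,
    GradeMix,
    TestPerformance,
    device_from_parameters,
)

__all__ = [
    "RECORD_COLUMNS",
    "SlideRecord",
    "simulate_cohort",
    "tally_records",
    "estimate_parameters_from_records",
]

#: documented header of the slide-record CSV export
RECORD_COLUMNS = (
    "woman_id",
    "round",
    "hiv_status",
    "true_grade",
    "endocervical_present",
    "satisfactory",
    "reported_result",
    "disposition",
)

_GRADE_NAMES = ("negative", "ascus", "lsil", "hsil")
_TERMINAL = ("diagnosed", "final_negative", "lost")


@dataclass(frozen=True)
class SlideRecord:
    """One synthetic laboratory record (one smear for one woman).

    ``disposition`` is ``recalled`` when a later smear follows, otherwise
    the woman's terminal state: ``diagnosed`` (abnormal report),
    ``final_negative`` (negative result accepted as final) or ``lost``
    (recalled but the repeat smear never happened).
    """

    woman_id: int
    round: int
    hiv_status: str
    true_grade: str
    endocervical_present: bool
    satisfactory: bool
    reported_result: str
    disposition: str


def simulate_cohort(
    params: ParameterSet,
    device: DeviceProfile | str,
    practice: str,
    n_women: int,
    seed: int,
    *,
    max_rounds: int | None = DEFAULT_MAX_ROUNDS,
) -> pd.DataFrame:
    """Simulate ``n_women`` through the screening tree; one row per smear.

    Identical seeds reproduce identical record streams.  Adequacy draws on
    repeat smears are independent of earlier rounds.
    """
    if n_women < 1:
        raise ValueError("n_women must be >= 1")
    if practice not in ("guidelines", "typical"):
        raise ValueError(f"unknown practice {practice!r}")
    if isinstance(device, str):
        device = device_from_parameters(params, device)
    perf = TestPerformance.from_parameters(params)
    flow = FlowParams.from_parameters(params, max_rounds=max_rounds)
    mix = GradeMix.from_parameters(params)

    rng = np.random.default_rng(int(seed))
    # true grade: 0 negative, 1 ascus, 2 lsil, 3 hsil
    probs = np.array([mix.p_negative, mix.f_ascus, mix.f_lsil, mix.f_hsil])
    grade = rng.choice(4, size=n_women, p=probs / probs.sum())

    sens_ne = np.array([np.nan, perf.sens_no_endo, perf.sens_no_endo, perf.sens_no_endo_hsil])
    cap = HARD_ROUND_CAP if flow.max_rounds is None else flow.max_rounds

    cols: dict[str, list[np.ndarray]] = {c: [] for c in RECORD_COLUMNS if c != "hiv_status"}
    ids = np.arange(n_women, dtype=np.int64)
    active_grade = grade
    round_no = 1
    while ids.size:
        if round_no > cap:
            raise RuntimeError(f"recall loop exceeded {cap} rounds")
        m = ids.size
        endo = rng.random(m) < device.p_endocervical
        sat = rng.random(m) < flow.p_satisfactory
        u = rng.random(m)
        p_pos = np.where(
            active_grade == 0,
            1.0 - perf.specificity,
            np.where(endo, perf.sens_endo, sens_ne[active_grade]),
        )
        reported = sat & (u < p_pos)
        if practice == "guidelines":
            recall = (~sat) | (sat & ~reported & ~endo)
        else:
            recall = ~sat
        final_neg = ~reported & ~recall

        if round_no == cap:
            cont = np.zeros(m, dtype=bool)
            lost = recall
        else:
            back = rng.random(m) < flow.p_return
            repeat = rng.random(m) < flow.p_repeat_given_return
            cont = recall & back & repeat
            lost = recall & ~cont

        disposition = np.full(m, "final_negative", dtype=object)
        disposition[reported] = "diagnosed"
        disposition[lost] = "lost"
        disposition[cont] = "recalled"

        cols["woman_id"].append(ids)
        cols["round"].append(np.full(m, round_no, dtype=np.int64))
        cols["true_grade"].append(np.asarray(_GRADE_NAMES, dtype=object)[active_grade])
        cols["endocervical_present"].append(endo)
        cols["satisfactory"].append(sat)
        cols["reported_result"].append(
            np.where(reported, "abnormal", "normal").astype(object)
        )
        cols["disposition"].append(disposition)

        ids = ids[cont]
        active_grade = active_grade[cont]
        round_no += 1

    frame = pd.DataFrame({c: np.concatenate(v) for c, v in cols.items()})
    frame.insert(2, "hiv_status", "positive")
    return frame[list(RECORD_COLUMNS)]


def _validate_rounds(records: pd.DataFrame) -> None:
    srt = records.sort_values(["woman_id", "round"])
    by_woman = srt.groupby("woman_id", sort=False)
    n_rec = by_woman.size().to_numpy()
    max_round = by_woman["round"].max().to_numpy()
    min_round = by_woman["round"].min().to_numpy()
    if np.any(n_rec != max_round) or np.any(min_round != 1):
        raise ValueError("inconsistent round sequences: rounds must run 1..k per woman")
    is_last = ~srt.duplicated("woman_id", keep="last")
    disp = srt["disposition"].to_numpy()
    if np.any(disp[is_last.to_numpy()] == "recalled"):
        raise ValueError("a woman's final record cannot have disposition 'recalled'")
    if np.any(disp[~is_last.to_numpy()] != "recalled"):
        raise ValueError("non-final records must have disposition 'recalled'")


def tally_records(
    records: pd.DataFrame, *, include_false_positives: bool = False, validate: bool = True
) -> CohortOutcome:
    """Count terminal dispositions into the tree engine's outcome shape.

    ``n_women`` is the number of distinct women; all counts are raw tallies
    (no scaling).  An empty frame yields an all-zero outcome.
    """
    if len(records) == 0:
        return CohortOutcome(
            n_women=0.0,
            detected_abnormal_total=0.0,
            detected_by_grade={g: 0.0 for g in GRADES},
            false_positives=0.0,
            true_negative_diagnosed=0.0,
            false_negatives_reported=0.0,
            lost_to_care=0.0,
            expected_smears_per_woman=0.0,
            expected_visits_per_woman=0.0,
        )
    if validate:
        _validate_rounds(records)
    last = records.sort_values(["woman_id", "round"]).drop_duplicates(
        "woman_id", keep="last"
    )
    n_women = float(last.shape[0])
    diagnosed = last["disposition"] == "diagnosed"
    negative = last["true_grade"] == "negative"
    detected = {
        g: float((diagnosed & (last["true_grade"] == g)).sum()) for g in GRADES
    }
    fp = float((diagnosed & negative).sum())
    tn = float(((last["disposition"] == "final_negative") & negative).sum())
    fn = float(((last["disposition"] == "final_negative") & ~negative).sum())
    lost = float((last["disposition"] == "lost").sum())
    tp_total = sum(detected.values())
    smears = len(records) / n_women
    return CohortOutcome(
        n_women=n_women,
        detected_abnormal_total=tp_total + fp if include_false_positives else tp_total,
        detected_by_grade=detected,
        false_positives=fp,
        true_negative_diagnosed=tn,
        false_negatives_reported=fn,
        lost_to_care=lost,
        expected_smears_per_woman=smears,
        expected_visits_per_woman=smears,
    )


def estimate_parameters_from_records(records: pd.DataFrame) -> dict[str, float]:
    """Empirical per-smear rates, for parameter-recovery checks.

    Inverts the generator's per-smear proportions (endocervical presence,
    satisfactoriness, abnormal-report rate) up to binomial sampling error.
    """
    if len(records) < 1000:
        raise ValueError("need at least 1,000 records for stable estimates")
    return {
        "p_endocervical": float(records["endocervical_present"].mean()),
        "p_satisfactory": float(records["satisfactory"].mean()),
        "p_abnormal_report": float((records["reported_result"] == "abnormal").mean()),
    }
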