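"""Branch probabilities, recall-loop absorption and cohort expectations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cervicost import (
    DeviceProfile,
    FlowParams,
    cohort_size,
    evaluate_cohort,
    expected_rounds,
    round_outcome,
    tree_outline,
)
from cervicost import TestPerformance as Performance

PERFECT = dict(sens_endo=1.0, sens_no_endo=1.0, sens_no_endo_hsil=1.0, specificity=1.0)


def make_params(**over):
    """A small self-consistent parameter dictionary for direct tree tests."""
    base = dict(
        women_tested_annual=1.0,
        hiv_positive_fraction=1.0,
        f_hsil=0.31,
        f_lsil=0.37,
        f_ascus=0.05,
        p_endocervical_spatula=0.53,
        p_endocervical_broom=0.83,
        sensitivity_with_endocervical=0.76,
        sensitivity_no_endocervical=0.40,
        sensitivity_no_endocervical_hsil=0.32,
        specificity=0.84,
        p_satisfactory=0.98,
        p_repeat_done=0.90,
        p_lost_to_followup=0.08,
        cost_spatula=0.02,
        cost_broom=0.22,
        cost_clinic_visit=8.36,
        cost_lab_test=4.89,
    )
    base.update(over)
    return base


class TestRoundOutcome:
    def test_perfect_test_always_detects(self):
        dev = DeviceProfile("spatula", 0.02, p_endocervical=1.0)
        perf = Performance(**PERFECT)
        flow = FlowParams(p_satisfactory=1.0, p_return=1.0, p_repeat_given_return=1.0)
        out = round_outcome("hsil", dev, perf, flow, "guidelines")
        assert out["reported_abnormal"] == pytest.approx(1.0)
        assert out["recall"] == pytest.approx(0.0)

    def test_guidelines_recall_of_inadequate_negative(self):
        # negative woman, satisfactory smear: recalled iff reported negative
        # (specificity) and endocervical cells absent
        dev = DeviceProfile("spatula", 0.02, p_endocervical=0.53)
        perf = Performance(0.76, 0.40, 0.32, specificity=0.84)
        flow = FlowParams(p_satisfactory=1.0, p_return=0.92, p_repeat_given_return=0.90)
        out = round_outcome("negative", dev, perf, flow, "guidelines")
        assert out["recall"] == pytest.approx(0.84 * 0.47)

    def test_typical_practice_repeats_only_unsatisfactory(self):
        dev = DeviceProfile("spatula", 0.02, p_endocervical=0.53)
        perf = Performance(0.76, 0.40, 0.32, specificity=0.84)
        flow = FlowParams(p_satisfactory=1.0, p_return=0.92, p_repeat_given_return=0.90)
        out = round_outcome("negative", dev, perf, flow, "typical")
        assert out["recall"] == 0.0

    def test_unknown_labels_rejected(self):
        dev = DeviceProfile("spatula", 0.02, 0.5)
        perf = Performance(**PERFECT)
        flow = FlowParams(1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            round_outcome("agc", dev, perf, flow, "guidelines")
        with pytest.raises(ValueError):
            round_outcome("hsil", dev, perf, flow, "aspirational")

    @given(
        p_e=st.floats(0.0, 1.0),
        p_sat=st.floats(0.0, 1.0),
        sens=st.floats(0.0, 1.0),
        spec_=st.floats(0.0, 1.0),
        state=st.sampled_from(["negative", "hsil", "lsil", "ascus"]),
        practice=st.sampled_from(["guidelines", "typical"]),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_outcome_probabilities_sum_to_one(self, p_e, p_sat, sens, spec_, state, practice):
        dev = DeviceProfile("spatula", 0.02, p_e)
        perf = Performance(sens, sens * 0.8, sens * 0.7, spec_)
        flow = FlowParams(p_sat, 0.92, 0.90)
        out = round_outcome(state, dev, perf, flow, practice)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)


class TestEvaluateCohort:
    def test_degenerate_perfect_screening(self):
        p = make_params(
            women_tested_annual=1000.0,
            sensitivity_with_endocervical=1.0,
            sensitivity_no_endocervical=1.0,
            sensitivity_no_endocervical_hsil=1.0,
            specificity=1.0,
            p_satisfactory=1.0,
            p_lost_to_followup=0.0,
            p_endocervical_spatula=1.0,
        )
        out = evaluate_cohort(p, "spatula", "guidelines")
        assert out.detected_abnormal_total == pytest.approx(1000 * 0.73)
        assert out.expected_smears_per_woman == pytest.approx(1.0)
        assert out.false_negatives_reported == pytest.approx(0.0)
        assert out.lost_to_care == pytest.approx(0.0)

    def test_no_return_means_every_recall_is_lost(self):
        p = make_params(p_lost_to_followup=1.0)
        out = evaluate_cohort(p, "spatula", "guidelines")
        # with q = 0 every recalled woman is lost on her first recall
        from cervicost.tree import _round_probabilities, DeviceProfile as DP
        from cervicost import FlowParams as FP, GradeMix

        dev = DP("spatula", 0.02, 0.53)
        perf = Performance(0.76, 0.40, 0.32, 0.84)
        flow = FP(0.98, 0.0, 0.90)
        mix = GradeMix(0.31, 0.37, 0.05)
        expected_lost = sum(
            mix.fraction(s) * _round_probabilities(s, dev, perf, flow, "guidelines")[2]
            for s in ("negative", "hsil", "lsil", "ascus")
        )
        assert out.lost_to_care == pytest.approx(out.n_women * expected_lost)
        assert out.expected_smears_per_woman == pytest.approx(1.0)

    def test_cohort_size_is_volume_times_hiv_fraction(self, means):
        assert cohort_size(means) == pytest.approx(723_829 * 0.51)

    def test_typical_practice_detected_row_with_false_positives(self, means):
        # the published typical-practice detection row back-calculates to
        # true plus false positives
        out = evaluate_cohort(means, "spatula", "typical", include_false_positives=True)
        assert out.detected_abnormal_total == pytest.approx(172_421, rel=0.10)

    @pytest.mark.parametrize("practice", ["guidelines", "typical"])
    @pytest.mark.parametrize("device", ["spatula", "broom"])
    @pytest.mark.parametrize("max_rounds", [1, 2, 3, None])
    def test_conservation(self, means, practice, device, max_rounds):
        out = evaluate_cohort(means, device, practice, max_rounds=max_rounds)
        total = (
            out.detected_abnormal_total
            + out.false_positives
            + out.true_negative_diagnosed
            + out.false_negatives_reported
            + out.lost_to_care
        )
        assert total == pytest.approx(out.n_women, rel=1e-6)

    @given(
        p_e=st.floats(0.01, 0.99),
        p_sat=st.floats(0.5, 1.0),
        sens_e=st.floats(0.3, 1.0),
        rel_ne=st.floats(0.1, 1.0),
        spec_=st.floats(0.5, 1.0),
        ltfu=st.floats(0.0, 0.5),
        practice=st.sampled_from(["guidelines", "typical"]),
        max_rounds=st.sampled_from([1, 2, 4, None]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_conservation_property(self, p_e, p_sat, sens_e, rel_ne, spec_, ltfu,
                                   practice, max_rounds):
        p = make_params(
            p_endocervical_spatula=p_e,
            p_satisfactory=p_sat,
            sensitivity_with_endocervical=sens_e,
            sensitivity_no_endocervical=sens_e * rel_ne,
            sensitivity_no_endocervical_hsil=sens_e * rel_ne * 0.8,
            specificity=spec_,
            p_lost_to_followup=ltfu,
        )
        out = evaluate_cohort(p, "spatula", practice, max_rounds=max_rounds)
        total = (
            out.detected_abnormal_total + out.false_positives
            + out.true_negative_diagnosed + out.false_negatives_reported
            + out.lost_to_care
        )
        assert total == pytest.approx(out.n_women, rel=1e-6)

    def test_monotone_in_adequacy_under_guidelines(self):
        detections, rounds = [], []
        for p_e in np.linspace(0.05, 0.95, 10):
            p = make_params(p_endocervical_spatula=float(p_e))
            out = evaluate_cohort(p, "spatula", "guidelines")
            detections.append(out.detected_abnormal_total)
            rounds.append(out.expected_smears_per_woman)
        assert np.all(np.diff(detections) >= -1e-12)
        assert np.all(np.diff(rounds) <= 1e-12)

    def test_guidelines_dominates_typical_in_detections_and_rounds(self, means):
        for device in ("spatula", "broom"):
            g = evaluate_cohort(means, device, "guidelines")
            t = evaluate_cohort(means, device, "typical")
            assert g.detected_abnormal_total >= t.detected_abnormal_total
            assert g.expected_smears_per_woman >= t.expected_smears_per_woman

    def test_devices_identical_when_adequacy_effect_removed(self):
        p = make_params(
            sensitivity_no_endocervical=0.76,
            sensitivity_no_endocervical_hsil=0.76,
            p_endocervical_broom=0.53,
        )
        a = evaluate_cohort(p, "spatula", "guidelines")
        b = evaluate_cohort(p, "broom", "guidelines")
        for k, v in a.as_dict().items():
            assert v == pytest.approx(b.as_dict()[k], rel=1e-12), k


class TestExpectedRounds:
    def test_no_recall_means_single_smear(self):
        p = make_params(p_satisfactory=1.0, specificity=1.0,
                        p_endocervical_spatula=1.0)
        assert expected_rounds(p, "spatula", "guidelines") == pytest.approx(1.0)

    def test_geometric_series_closed_form(self):
        # negative-only cohort, constant recall-and-repeat probability 0.25
        p = make_params(
            f_hsil=0.0, f_lsil=0.0, f_ascus=0.0,
            specificity=1.0, p_satisfactory=1.0,
            p_endocervical_spatula=0.5,
            p_lost_to_followup=0.5, p_repeat_done=1.0,
        )
        e = expected_rounds(p, "spatula", "guidelines", max_rounds=None)
        assert e == pytest.approx(4.0 / 3.0, rel=1e-12)

    def test_default_depth_matches_programme_scale(self, means):
        # at the registry means the spatula guidelines loop implies roughly a
        # quarter repeat smear per woman
        e = expected_rounds(means, "spatula", "guidelines")
        assert 1.2 < e < 1.35


def test_tree_outline_is_auditable(means):
    text = tree_outline(means, "broom", "guidelines")
    assert "broom" in text and "guidelines" in text
    assert "hsil" in text and "recall" in text
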