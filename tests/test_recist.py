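"""RECIST 1.1 and hyperprogression classifier tests."""

import numpy as np
import pandas as pd
import pytest

from rmctrial import synthetic as syn
from rmctrial.recist import (
    NotEvaluableError,
    assess_timeline,
    best_overall_response,
    classify_hyperprogression,
    classify_timepoint,
    cohort_summary,
    sum_longest_diameters,
)

from conftest import make_timeline

# (baseline, nadir, current, new_lesions, all_disappeared) -> category
TIMEPOINT_TRUTH_TABLE = [
    (50, 50, 35, False, False, "PR"),    # exactly -30%
    (50, 50, 36, False, False, "SD"),    # -28%, short of PR
    (50, 40, 48, False, False, "PD"),    # +20% and +8 mm from nadir
    (50, 50, 55, False, False, "SD"),    # +10%
    (50, 50, 60, False, False, "PD"),    # +20% and +10 mm
    (50, 50, 59, False, False, "SD"),    # +18%
    (20, 20, 24, False, False, "SD"),    # +20% but only +4 mm
    (20, 20, 25, False, False, "PD"),    # +25% and +5 mm
    (50, 50, 0, False, True, "CR"),      # disappearance
    (50, 50, 0, True, False, "PD"),      # new lesion trumps shrinkage
    (50, 50, 50, True, False, "PD"),     # new lesion alone
    (50, 30, 36, False, False, "PD"),    # +20% from nadir despite -28% from baseline
    (50, 30, 35, False, False, "PR"),    # +16.7% from nadir, -30% from baseline
    (100, 100, 70, False, False, "PR"),
    (100, 100, 69, False, False, "PR"),
    (100, 100, 140, False, False, "PD"),
    (100, 90, 107, False, False, "SD"),  # +18.9% from nadir
    (100, 90, 108, False, False, "PD"),  # +20% from nadir
    (10, 10, 13, False, False, "SD"),    # +30% but +3 mm < 5 mm
    (10, 10, 15, False, False, "PD"),    # +50%, +5 mm
    (40, 40, 28, False, False, "PR"),
    (40, 28, 33, False, False, "SD"),    # +17.9% from nadir, -17.5% baseline
]


class TestSumLongestDiameters:
    def test_sums_targets(self):
        df = make_timeline("P1", {0: 50}, n_targets=2)
        assert sum_longest_diameters(df) == 50

    def test_single_target(self):
        df = make_timeline("P1", {0: 15})
        assert sum_longest_diameters(df) == 15

    def test_no_targets_raises(self):
        df = make_timeline("P1", {0: 50})
        df["is_target"] = False
        with pytest.raises(NotEvaluableError):
            sum_longest_diameters(df)


class TestClassifyTimepoint:
    @pytest.mark.parametrize(
        "baseline, nadir, current, new, gone, expected", TIMEPOINT_TRUTH_TABLE
    )
    def test_truth_table(self, baseline, nadir, current, new, gone, expected):
        assert classify_timepoint(baseline, nadir, current, new, gone) == expected

    def test_invalid_baseline(self):
        with pytest.raises(NotEvaluableError):
            classify_timepoint(0, 0, 10)


class TestAssessTimeline:
    def test_missing_target_lesion_flags_ne(self):
        df = make_timeline("P1", {0: 50, 6: 50}, n_targets=2)
        df = df[~((df.week == 6) & (df.lesion_id == "P1-T2"))]
        cats = [a.category for a in assess_timeline(df)]
        assert cats == ["baseline", "NE"]

    def test_requires_baseline(self):
        df = make_timeline("P1", {6: 50})
        with pytest.raises(NotEvaluableError):
            assess_timeline(df)

    def test_nadir_tracks_minimum(self):
        df = make_timeline("P1", {0: 50, 6: 30, 12: 37})
        last = assess_timeline(df)[-1]
        # +23% and +7 mm from the week-6 nadir
        assert last.category == "PD"


class TestHyperprogression:
    def test_criterion_i(self):
        df = make_timeline("P1", {0: 50, 6: 75})
        call = classify_hyperprogression(df)
        assert call.is_hyperprogression and call.criterion_i
        assert call.absolute_increase_mm == pytest.approx(25)

    def test_criterion_ii_needs_two_organs(self):
        df = make_timeline("P1", {0: 50, 6: 62},
                           new_lesions={6: ["liver", "lung"]})
        call = classify_hyperprogression(df)
        assert call.is_hyperprogression and call.criterion_ii
        assert not call.criterion_i

    def test_one_new_organ_insufficient(self):
        df = make_timeline("P1", {0: 50, 6: 62}, new_lesions={6: ["liver"]})
        call = classify_hyperprogression(df)
        assert not call.is_hyperprogression

    def test_absolute_gate_blocks_small_tumors(self):
        """+75% growth without 10 mm absolute increase is not HP."""
        df = make_timeline("P1", {0: 8, 6: 14})
        call = classify_hyperprogression(df)
        assert call.window_pd
        assert not call.is_hyperprogression

    def test_late_pd_outside_window(self):
        df = make_timeline("P1", {0: 50, 6: 52, 12: 90})
        call = classify_hyperprogression(df)
        assert not call.is_hyperprogression

    def test_no_assessment_in_window_not_evaluable(self):
        df = make_timeline("P1", {0: 50, 12: 90})
        call = classify_hyperprogression(df)
        assert not call.evaluable

    def test_hyperprogression_implies_pd(self):
        df = make_timeline("P1", {0: 50, 6: 75})
        call = classify_hyperprogression(df)
        assessments = assess_timeline(df)
        assert call.is_hyperprogression
        assert any(a.category == "PD" for a in assessments[1:])

    def test_scaling_flips_absolute_gate_only(self):
        """Scaling diameters preserves percent criteria but can flip 10 mm."""
        big = make_timeline("P1", {0: 50, 6: 75})
        small = big.copy()
        small["longest_diameter_mm"] *= 0.1  # 5 -> 7.5 mm, +2.5 mm
        a_big = assess_timeline(big)[-1]
        a_small = assess_timeline(small)[-1]
        assert a_big.pct_change_from_baseline == pytest.approx(
            a_small.pct_change_from_baseline
        )
        assert classify_hyperprogression(big).is_hyperprogression
        assert not classify_hyperprogression(small).is_hyperprogression


class TestBestOverallResponse:
    def test_single_pr_is_unconfirmed(self):
        """A PR on one measurement followed by PD does not count for ORR."""
        df = make_timeline("P1", {0: 50, 6: 34, 12: 70})
        bor = best_overall_response(df)
        assert bor.bor == "PR" and not bor.confirmed

    def test_repeat_pr_is_confirmed(self):
        df = make_timeline("P1", {0: 50, 6: 34, 12: 33})
        bor = best_overall_response(df)
        assert bor.bor == "PR" and bor.confirmed

    def test_pd_at_first_assessment(self):
        df = make_timeline("P1", {0: 50, 6: 75})
        bor = best_overall_response(df)
        assert bor.bor == "PD"
        assert bor.max_pct_change == pytest.approx(50)

    def test_no_confirmation_mode(self):
        df = make_timeline("P1", {0: 50, 6: 34, 12: 70})
        bor = best_overall_response(df, require_confirmation=False)
        assert bor.bor == "PR" and bor.confirmed


class TestCohortSummary:
    def test_trial_like_cohort_has_zero_orr(self):
        """10 patients, one unconfirmed PR: ORR 0, like the halted trial."""
        timelines = [make_timeline(f"P{i}", {0: 50, 6: 70}) for i in range(9)]
        timelines.append(make_timeline("P9", {0: 50, 6: 34, 12: 80}))
        bors = [best_overall_response(t) for t in timelines]
        summary = cohort_summary(bors)
        assert summary["orr"] == 0.0

    def test_all_responders(self):
        timelines = [make_timeline(f"P{i}", {0: 50, 6: 30, 12: 30})
                     for i in range(4)]
        bors = [best_overall_response(t) for t in timelines]
        summary = cohort_summary(bors)
        assert summary["orr"] == 1.0
        assert summary["dcr"] == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_summary([])


class TestSyntheticCohortRecovery:
    def test_noiseless_labels_recovered_exactly(self):
        """Sensitivity = specificity = 1 against generator ground truth."""
        cfg = syn.LesionSimConfig(
            n_patients=40, fraction_responders=0.25,
            fraction_hyperprogressors=0.35, seed=5,
        )
        lesions, labels = syn.generate_lesion_cohort(cfg)
        truth = labels.set_index("patient_id")["phenotype"]
        for pid, group in lesions.groupby("patient_id"):
            call = classify_hyperprogression(group)
            assert call.is_hyperprogression == (truth[pid] == "hyperprogressor")
            bor = best_overall_response(group)
            if truth[pid] == "responder":
                assert bor.bor == "PR" and bor.confirmed
            elif truth[pid] == "stable":
                assert bor.bor == "SD"

    def test_five_of_ten_scenario(self):
        cfg = syn.LesionSimConfig(n_patients=10, fraction_hyperprogressors=0.5,
                                  seed=2)
        lesions, _ = syn.generate_lesion_cohort(cfg)
        calls = [classify_hyperprogression(g)
                 for _, g in lesions.groupby("patient_id")]
        assert sum(c.is_hyperprogression for c in calls) == 5
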