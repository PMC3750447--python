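"""Unit tests for the modification rule engine."""

import numpy as np
import pandas as pd
import pytest

from conftest import claims_frame
from rxpatterns import classify
from rxpatterns.classify import (
    Candidate,
    build_supply_timeline,
    classify_first_modification,
    detect_discontinuation,
    detect_dose_escalation,
    detect_intensification,
    detect_switch,
    estimate_daily_dose,
    summarize_modifications,
)
from rxpatterns.config import ClassifyParams

P = ClassifyParams()


class TestSupplyTimeline:
    def test_single_fill_runout(self):
        assert build_supply_timeline(claims_frame([(0, "exenatide", 30)])) == [(0, 30)]

    def test_early_refill_does_not_stack(self):
        # fills at 0 and 20, both 30-day: run-outs 30 and 50, never 60
        tl = build_supply_timeline(
            claims_frame([(0, "exenatide", 30), (20, "exenatide", 30)])
        )
        assert tl == [(0, 30), (20, 50)]

    def test_empty_and_invalid(self):
        assert build_supply_timeline(claims_frame([])) == []
        assert build_supply_timeline(claims_frame([(0, "exenatide", 0)])) == []


class TestDoseEstimation:
    def test_units_over_elapsed_days(self):
        doses = estimate_daily_dose(
            claims_frame([(0, "glargine", 30, 3000), (30, "glargine", 30, 3000)])
        )
        assert doses["est_daily_dose"].iloc[0] == pytest.approx(100.0)
        assert np.isnan(doses["est_daily_dose"].iloc[-1])  # no next dispense

    def test_long_elapsed_interval_dilutes_dose(self):
        doses = estimate_daily_dose(
            claims_frame([(0, "glargine", 30, 1000), (100, "glargine", 30, 1000)])
        )
        assert doses["est_daily_dose"].iloc[0] == pytest.approx(10.0)

    def test_single_fill_has_undefined_dose(self):
        doses = estimate_daily_dose(claims_frame([(0, "glargine", 30, 900)]))
        assert len(doses) == 1 and np.isnan(doses["est_daily_dose"].iloc[0])

    def test_same_day_fills_merged(self):
        doses = estimate_daily_dose(
            claims_frame(
                [(0, "glargine", 30, 1500), (0, "glargine", 30, 1500), (30, "glargine", 30, 100)]
            )
        )
        assert len(doses) == 2
        assert doses["est_daily_dose"].iloc[0] == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "second_dose,expected", [(25.0, 1), (19.0, None)], ids=["ratio2.5", "ratio1.9"]
    )
    def test_escalation_threshold(self, second_dose, expected):
        series = pd.DataFrame(
            {
                "fill_day": [0, 1, 2],
                "units": [10, second_dose, second_dose],
                "est_daily_dose": [10.0, second_dose, np.nan],
            }
        )
        cand = detect_dose_escalation(series, threshold=2.0)
        if expected is None:
            assert cand is None
        else:
            assert cand.event_day == expected and cand.detail == "dose_increase"

    def test_constant_refills_never_escalate(self):
        rows = [(30 * k, "glargine", 30, 900) for k in range(6)]
        cand = detect_dose_escalation(estimate_daily_dose(claims_frame(rows)))
        assert cand is None


class TestDiscontinuation:
    def test_single_fill_empty_gap(self):
        tl = [(0, 30)]
        cand = detect_discontinuation(tl, claims_frame([]), P)
        assert cand == Candidate("discontinuation", 30)

    def test_gap_shorter_than_90_days(self):
        # refill 80 days after run-out closes the gap
        tl = [(0, 30), (110, 140)]
        assert detect_discontinuation(tl, claims_frame([]), P) == Candidate(
            "discontinuation", 140
        )

    def test_nonindex_fill_blocks_gap(self):
        tl = [(0, 30)]
        other = claims_frame([(60, "sitagliptin", 30)])
        assert detect_discontinuation(tl, other, P) is None

    def test_unobservable_gap_at_horizon(self):
        # run-out day 500: the 90-day window extends past day 545
        assert detect_discontinuation([(470, 500)], claims_frame([]), P) is None


class TestSwitch:
    def test_confirmed_replacement(self):
        tl = [(0, 30), (30, 60), (60, 90)]
        other = claims_frame([(100, "sitagliptin", 30), (140, "sitagliptin", 30)])
        assert detect_switch(tl, other, P) == Candidate("switch", 100, "sitagliptin")

    def test_unconfirmed_candidate_is_not_a_switch(self):
        tl = [(0, 30), (30, 60), (60, 90)]
        other = claims_frame([(100, "sitagliptin", 30)])
        assert detect_switch(tl, other, P) is None

    def test_fill_during_active_supply_is_not_a_switch(self):
        # new class while index supply active and index refilled afterwards
        tl = [(0, 30), (30, 60), (60, 90), (95, 125)]
        other = claims_frame([(40, "sitagliptin", 30), (70, "sitagliptin", 30)])
        assert detect_switch(tl, other, P) is None


class TestIntensification:
    def test_overlapping_addon_with_refills(self):
        tl = [(0, 30), (30, 60), (60, 90)]
        other = claims_frame([(45, "biguanide", 30), (80, "biguanide", 30)])
        cand = detect_intensification(tl, other, set(), P)
        assert cand == Candidate("intensification", 45, "biguanide")

    def test_pre_index_medication_continuation_does_not_qualify(self):
        tl = [(0, 30), (30, 60), (60, 90)]
        other = claims_frame([(45, "biguanide", 30), (80, "biguanide", 30)])
        assert detect_intensification(tl, other, {"biguanide"}, P) is None

    def test_dose_candidate_passthrough(self):
        cand = detect_intensification(
            [(0, 30), (30, 60)], claims_frame([]), set(), P,
            dose_candidate=Candidate("intensification", 30, "dose_increase"),
        )
        assert cand.detail == "dose_increase"

    def test_addon_without_its_own_refill_does_not_qualify(self):
        tl = [(0, 30), (30, 60), (60, 90)]
        other = claims_frame([(45, "biguanide", 30)])
        assert detect_intensification(tl, other, set(), P) is None


class TestFirstModification:
    def _classify(self, rows, index_drug="exenatide", pre=()):
        return classify_first_modification(
            claims_frame(rows), 0, index_drug, set(pre), P, patient_id=1
        )

    def test_persistent_refills_are_censored(self):
        rows = [(30 * k, "exenatide", 30) for k in range(25)]
        ev = self._classify(rows)
        assert ev.mod_type == "censored" and ev.days_to_event == 545

    def test_single_fill_discontinues_at_runout(self):
        ev = self._classify([(0, "exenatide", 30)])
        assert ev.mod_type == "discontinuation" and ev.days_to_event == 30

    def test_first_event_wins(self):
        # add-on at day 45, chain stops later -> intensification reported
        rows = [(0, "exenatide", 30), (30, "exenatide", 30), (60, "exenatide", 30),
                (45, "biguanide", 30), (80, "biguanide", 30)]
        ev = self._classify(rows)
        assert ev.mod_type == "intensification" and ev.days_to_event == 45

    def test_glargine_dose_escalation_without_addon(self):
        rows = [
            (0, "glargine", 30, 900),
            (30, "glargine", 30, 2700),
            (60, "glargine", 30, 2700),
            (90, "glargine", 30, 2700),
        ]
        ev = self._classify(rows, index_drug="glargine")
        assert ev.mod_type == "intensification"
        assert ev.detail == "dose_increase" and ev.days_to_event == 30

    def test_same_day_tiebreak_prefers_intensification(self):
        # a 90-day fill at day 0 plus a 30-day fill at day 10: the day-40
        # run-out opens an empty gap (discontinuation candidate at 40) while
        # a confirmed overlapping add-on is also dated day 40 -> the tie
        # resolves to intensification (continued index use is demonstrated)
        rows = [(0, "exenatide", 90), (10, "exenatide", 30),
                (40, "biguanide", 30), (140, "biguanide", 30)]
        ev = self._classify(rows)
        assert ev.mod_type == "intensification" and ev.days_to_event == 40

    def test_fall_through_gap_flags_audit(self):
        # unconfirmed non-index fill in the gap: neither switch nor
        # discontinuation; censored with an audit flag
        rows = [(0, "exenatide", 30), (50, "sitagliptin", 30)]
        ev = self._classify(rows)
        assert ev.mod_type == "censored"
        assert ev.audit_flag == "gap_with_unconfirmed_nonindex"

    def test_index_day_addon_is_not_intensification(self):
        rows = [(0, "exenatide", 30), (30, "exenatide", 30), (60, "exenatide", 30),
                (0, "biguanide", 30), (25, "biguanide", 30)]
        ev = self._classify(rows)
        assert ev.mod_type != "intensification" or ev.days_to_event > 0


class TestSummaries:
    def test_cumulative_counts_by_cutoff(self):
        events = pd.DataFrame(
            {
                "patient_id": [1, 2, 3],
                "arm": ["exenatide"] * 3,
                "mod_type": ["discontinuation", "switch", "censored"],
                "event_day": [100, 200, 545],
                "days_to_event": [100, 200, 545],
                "detail": [None, "sitagliptin", None],
                "audit_flag": [None] * 3,
            }
        )
        s = summarize_modifications(events)
        any_row = s[(s["mod_type"] == "any")].iloc[0]
        assert (any_row["n_by_180"], any_row["n_by_365"], any_row["n_by_545"]) == (1, 2, 2)
        assert any_row["mean_days"] == pytest.approx(150.0)

    def test_all_censored_means_absent(self):
        events = pd.DataFrame(
            {
                "patient_id": [1, 2],
                "arm": ["glargine"] * 2,
                "mod_type": ["censored"] * 2,
                "event_day": [545] * 2,
                "days_to_event": [545] * 2,
                "detail": [None] * 2,
                "audit_flag": [None] * 2,
            }
        )
        s = summarize_modifications(events)
        assert (s.filter(like="pct_by_").to_numpy() == 0).all()
        assert s["mean_days"].isna().all()


class TestCohortInvariants:
    def test_partition_one_event_per_patient(self, small_cohort, small_events):
        coh, _ = small_cohort
        assert len(small_events) == len(coh)
        assert small_events["patient_id"].is_unique
        assert set(small_events["mod_type"]) <= {
            "discontinuation", "switch", "intensification", "censored"
        }

    def test_cumulative_monotonicity(self, small_events):
        s = summarize_modifications(small_events)
        assert (s["n_by_180"] <= s["n_by_365"]).all()
        assert (s["n_by_365"] <= s["n_by_545"]).all()

    def test_days_to_event_bounds(self, small_events):
        assert (small_events["days_to_event"] > 0).all()
        assert (small_events["days_to_event"] <= 545).all()
        censored = small_events[small_events["mod_type"] == "censored"]
        assert (censored["days_to_event"] == 545).all()
        assert censored["detail"].isna().all()

    def test_deterministic_classification(self, small_sim, small_cohort, small_events):
        _, data = small_sim
        coh, _ = small_cohort
        again = classify.classify_cohort(data.pharmacy, coh)
        pd.testing.assert_frame_equal(small_events, again)
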