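"""Tests for Kaplan-Meier, log-rank, and Cox estimation.

lifelines serves as an independent cross-check implementation; the
brute-force O-E oracle lives in tests/oracles.py.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

import oracles
from rxpatterns import survival
from rxpatterns.survival import (
    MonotoneLikelihoodError,
    NoEventsError,
    compare_arms,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
)


class TestKaplanMeier:
    def test_all_events_closed_form(self):
        km = km_estimate([1, 2, 3], [True, True, True])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_all_censored_flat(self):
        km = km_estimate([5, 6, 7], [False] * 3)
        assert len(km.times) == 0  # S stays at 1 with no event times

    def test_censoring_between_events(self):
        # event at 1 (S=2/3), censor at 2, event at 3 with 1 at risk (S=0)
        km = km_estimate([1, 2, 3], [True, False, True])
        assert km.survival == pytest.approx([2 / 3, 0.0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.integers(1, 50, 200).astype(float)
        km = km_estimate(t, np.ones(200, bool))
        for et, s in zip(km.times, km.survival):
            assert s == pytest.approx((t > et).mean())

    def test_matches_lifelines(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(100, 300).round() + 1
        e = rng.random(300) < 0.7
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        theirs = kmf.survival_function_at_times(km.times).to_numpy()
        assert km.survival == pytest.approx(theirs)

    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            km_estimate([0, 1], [True, True])


class TestLogrank:
    def test_identical_arms_give_zero(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [True] * 6
        chi2, p = logrank_test(t, e, [1, 1, 1, 0, 0, 0])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_four_event_example(self):
        # arm A events at 1, 2; arm B events at 3, 4; no censoring
        t = [1, 2, 3, 4]
        e = [True] * 4
        g = [1, 1, 0, 0]
        chi2, _ = logrank_test(t, e, g)
        assert chi2 == pytest.approx(oracles.logrank_by_hand(t, e, g))
        # the by-hand value: O1-E1 = (1-2/4)+(1-1/3)+0+0 = 7/6;
        # V = 1/4 + 2/9 (+0+0) = 17/36 -> chi2 = (7/6)^2/(17/36)
        assert chi2 == pytest.approx((7 / 6) ** 2 / (17 / 36))

    def test_matches_lifelines(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(100, 400).round() + 1
        e = rng.random(400) < 0.8
        g = (rng.random(400) < 0.5).astype(int)
        chi2, p = logrank_test(t, e, g)
        res = ll_logrank(t[g == 1], t[g == 0], e[g == 1], e[g == 0])
        assert chi2 == pytest.approx(res.test_statistic)
        assert p == pytest.approx(res.p_value)

    def test_no_events_is_an_error(self):
        with pytest.raises(NoEventsError):
            logrank_test([1, 2], [False, False], [0, 1])

    def test_exhaustive_small_datasets_match_oracle(self):
        # all datasets with 4 patients, times on {1,2,3}, any event/arm mix
        for times in itertools.product([1, 2, 3], repeat=4):
            for events in itertools.product([True, False], repeat=4):
                for groups in itertools.product([0, 1], repeat=4):
                    if len(set(groups)) < 2 or not any(events):
                        continue
                    try:
                        expected = oracles.logrank_by_hand(times, events, groups)
                    except ZeroDivisionError:
                        with pytest.raises(NoEventsError):
                            logrank_test(times, events, groups)
                        continue
                    chi2, _ = logrank_test(times, events, groups)
                    assert chi2 == pytest.approx(expected, abs=1e-12)


class TestCox:
    @staticmethod
    def _simulate(hr, n, seed, censor=545.0):
        rng = np.random.default_rng(seed)
        g = np.repeat([0, 1], n // 2)
        lam = 0.002 * hr**g
        t = rng.exponential(1 / lam)
        e = t <= censor
        return np.minimum(t, censor), e, g

    def test_identical_arms_null(self):
        t, e, g = self._simulate(1.0, 2000, 5)
        res = cox_fit(t, e, g)
        assert abs(res.log_hr) < 3 * res.se

    def test_true_hazard_ratio_recovered(self):
        t, e, g = self._simulate(2.0, 2000, 6)
        res = cox_fit(t, e, g)
        assert 1.8 < res.hr < 2.2

    def test_score_test_equals_logrank_on_tie_free_data(self):
        t, e, g = self._simulate(1.5, 300, 7)
        assert len(np.unique(t[e])) == e.sum()  # event times are tie-free
        chi2, _ = logrank_test(t, e, g)
        assert cox_score_test(t, e, g) == pytest.approx(chi2, abs=1e-8)

    def test_matches_lifelines_efron(self):
        t, e, g = self._simulate(1.7, 500, 8)
        t = np.ceil(t)  # day granularity introduces ties
        res = cox_fit(t, e, g, ties="efron")
        df = pd.DataFrame({"t": t, "e": e, "g": g})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert res.log_hr == pytest.approx(cph.params_["g"], abs=1e-6)
        assert res.se == pytest.approx(cph.standard_errors_["g"], abs=1e-6)

    def test_time_rescaling_invariance(self):
        t, e, g = self._simulate(1.4, 400, 9)
        a = cox_fit(t, e, g)
        b = cox_fit(t / 7.0, e, g)  # days -> weeks
        assert a.log_hr == pytest.approx(b.log_hr, abs=1e-6)

    def test_label_swap_inverts_hazard_ratio(self):
        t, e, g = self._simulate(1.4, 400, 10)
        a = cox_fit(t, e, g)
        b = cox_fit(t, e, 1 - g)
        assert a.hr == pytest.approx(1 / b.hr, abs=1e-6)

    def test_monotone_likelihood_detected(self):
        # every arm-1 event strictly before every arm-0 event
        t = np.array([1, 2, 3, 10, 11, 12], dtype=float)
        e = np.ones(6, bool)
        g = np.array([1, 1, 1, 0, 0, 0])
        with pytest.raises(MonotoneLikelihoodError):
            cox_fit(t, e, g)

    def test_no_events_rejected(self):
        with pytest.raises(NoEventsError):
            cox_fit([1, 2], [False, False], [0, 1])


class TestCompareArms:
    def test_null_generator_hazard_ratios_near_one(self):
        rng = np.random.default_rng(11)
        n = 3000
        arm = np.where(np.arange(n) % 2 == 0, "exenatide", "glargine")
        lat = rng.exponential(1 / 0.002, n)
        cause = rng.choice(["discontinuation", "switch", "intensification"], n)
        events = pd.DataFrame(
            {
                "patient_id": np.arange(n),
                "arm": arm,
                "mod_type": np.where(lat <= 545, cause, "censored"),
                "event_day": 0,
                "days_to_event": np.minimum(np.ceil(lat), 545).astype(int),
                "detail": None,
                "audit_flag": None,
            }
        )
        events.loc[events["mod_type"] == "censored", "days_to_event"] = 545
        res = compare_arms(events)
        for outcome, entry in res["outcomes"].items():
            ci = entry["cox"]
            assert ci["ci_low"] < 1.0 < ci["ci_high"], outcome

    def test_type_without_events_reports_unestimable(self, small_events):
        events = small_events[small_events["mod_type"] != "switch"].copy()
        res = compare_arms(events)
        assert "error" in res["outcomes"]["switch"]["cox"]
        assert "hr" in res["outcomes"]["any"]["cox"]

    def test_real_pipeline_events_bundle_shapes(self, small_events):
        res = compare_arms(small_events)
        assert set(res["outcomes"]) == {"any", "discontinuation", "switch", "intensification"}
        km = res["outcomes"]["any"]["km"]
        for arm, frame in km.items():
            s = frame["survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all()  # non-increasing
            assert ((s >= 0) & (s <= 1)).all()
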