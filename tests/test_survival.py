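"""Kaplan-Meier product-limit estimation and the Mantel-Cox test.

Independent oracles: an explicit risk-set enumeration for small KM
instances, and lifelines' log-rank statistic for the Mantel-Cox test.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines.statistics import logrank_test as lifelines_logrank

from plsd.survival import (
    crude_survival,
    km_estimate,
    km_event_from_inclusion,
    logrank_test,
    survival_at,
)

from conftest import make_record


def km_oracle(durations, events):
    """Brute-force product-limit: walk distinct event times, shrink risk sets.

    Events precede censorings at tied times (a subject censored at t is
    still at risk for an event at t).
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    out = {}
    s = 1.0
    for t in sorted(set(durations[events])):
        n = np.sum(durations >= t)
        d = np.sum(events & (durations == t))
        s *= 1.0 - d / n
        out[t] = s
    return out


small_instances = st.lists(
    st.tuples(
        st.floats(0.0, 10.0, allow_nan=False).map(lambda x: round(x, 1)),
        st.booleans(),
    ),
    min_size=1,
    max_size=6,
)


def assert_matches_oracle(subjects):
    durations = [d for d, _ in subjects]
    events = [e for _, e in subjects]
    curve = km_estimate(durations, events)
    for t, s in km_oracle(durations, events).items():
        got, _ = survival_at(curve, t)
        assert got == pytest.approx(s, abs=1e-12)


class TestKMEstimate:
    def test_hand_traced_product_limit(self):
        # (2+, 3, 4, 5+): S(3) = 3/4 * ... risk sets 3 and 2 after the censoring
        curve = km_estimate([2, 3, 4, 5], [False, True, True, False])
        assert survival_at(curve, 3)[0] == pytest.approx(2 / 3)
        assert survival_at(curve, 4)[0] == pytest.approx(1 / 3)

    def test_no_events_flat_at_one(self):
        curve = km_estimate([1, 2, 3], [False, False, False])
        assert np.all(curve.survival == 1.0)

    def test_single_event_drops_to_zero(self):
        curve = km_estimate([1.0], [True])
        assert survival_at(curve, 1.0)[0] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_curve_invariants(self):
        curve = km_estimate([1, 2, 2, 3, 5, 7], [True, True, False, True, False, True])
        assert survival_at(curve, 0)[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((0 <= curve.survival) & (curve.survival <= 1))
        assert np.all(np.diff(curve.n_at_risk) <= 0)

    @given(small_instances)
    @settings(max_examples=200, deadline=None)
    def test_matches_risk_set_oracle_on_small_instances(self, subjects):
        assert_matches_oracle(subjects)

    def test_greenwood_variance_hand_example(self):
        # events at 1 (n=4) and 2 (n=3): var = S^2 * (1/(4*3) + 1/(3*2))
        curve = km_estimate([1, 2, 3, 4], [True, True, False, False])
        s, _ = survival_at(curve, 2)
        i = np.searchsorted(curve.times, 2.0)
        assert curve.greenwood_var[i] == pytest.approx(s**2 * (1 / 12 + 1 / 6), abs=1e-12)


class TestSurvivalAt:
    def test_step_function_between_events(self):
        curve = km_estimate([2, 3, 4, 5], [False, True, True, False])
        assert survival_at(curve, 3.5)[0] == pytest.approx(2 / 3)

    def test_time_zero_is_one(self):
        curve = km_estimate([1.0], [True])
        assert survival_at(curve, 0)[0] == 1.0

    def test_extrapolation_warns_and_holds_last_value(self):
        curve = km_estimate([1, 2], [True, False])
        with pytest.warns(UserWarning, match="beyond last"):
            s, _ = survival_at(curve, 99.0)
        assert s == pytest.approx(0.5)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        d = [1, 2, 3, 4]
        e = [True, False, True, True]
        res = logrank_test(d, e, d, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_lifelines_on_hand_groups(self):
        da, ea = [1, 3, 5, 7, 9, 11], [1, 1, 0, 1, 0, 1]
        db, eb = [2, 4, 6, 8, 10], [1, 1, 1, 0, 1]
        ours = logrank_test(da, ea, db, eb)
        ref = lifelines_logrank(da, db, event_observed_A=ea, event_observed_B=eb)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_observed_totals_and_label_symmetry(self):
        da, ea = [1, 2, 5, 6], [1, 1, 0, 1]
        db, eb = [3, 4, 7], [1, 0, 1]
        res = logrank_test(da, ea, db, eb)
        assert res.observed[0] + res.observed[1] == sum(ea) + sum(eb)
        swapped = logrank_test(db, eb, da, ea)
        assert swapped.statistic == pytest.approx(res.statistic, abs=1e-12)
        assert swapped.observed == res.observed[::-1]

    def test_no_events_is_undefined(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2], [False, False], [3], [False])

    @given(
        ga=st.lists(st.tuples(st.integers(1, 8), st.booleans()), min_size=2, max_size=8),
        gb=st.lists(st.tuples(st.integers(1, 8), st.booleans()), min_size=2, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_agrees_with_lifelines_on_random_instances(self, ga, gb):
        da, ea = [d for d, _ in ga], [e for _, e in ga]
        db, eb = [d for d, _ in gb], [e for _, e in gb]
        if sum(ea) + sum(eb) == 0:
            return
        ours = logrank_test(da, ea, db, eb)
        ref = lifelines_logrank(
            np.array(da, float), np.array(db, float), event_observed_A=ea, event_observed_B=eb
        )
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9, abs=1e-12)


class TestCohortCurves:
    def test_event_proportion_zero_without_events(self, small_cohort):
        cohort = [r for r in small_cohort if not r.events]
        curve = km_event_from_inclusion(cohort, "crc")
        assert np.all(curve.survival == 1.0)

    def test_single_case_event_proportion_one_after_event(self):
        rec = make_record(age_inclusion=30.0, age_last_observation=40.0,
                          events=((34.0, "153"),))
        curve = km_event_from_inclusion([rec], "crc")
        assert survival_at(curve, 4.0)[0] == 0.0  # 1 - S = 1 at t >= 4

    def test_crude_survival_only_uses_cases(self, small_cohort):
        curve = crude_survival(small_cohort, "crc")
        # two CRC cases, no deaths: flat at 1
        assert curve.n_at_risk.max() == 2
        assert np.all(curve.survival == 1.0)

    def test_crude_survival_without_cases_rejected(self, small_cohort):
        no_cases = [r for r in small_cohort if not r.events]
        with pytest.raises(ValueError, match="undefined"):
            crude_survival(no_cases, "crc")
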