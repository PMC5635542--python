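"""Person-year tabulation and the cumulative-incidence recursion.

Independent oracles: a day-stepping allocator for band person-years and
the closed-form product 1 - prod(1-AIR)^years for the recursion.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plsd.incidence import (
    AgeBandTable,
    annual_incidence_rates,
    cumulative_incidence,
    hazard_transform,
    tabulate_person_years,
)

from conftest import make_record

NINE_BANDS = tuple((a, a + 5) for a in range(25, 70, 5))


def day_step_person_years(start, stop, bands, step=1 / 365.25):
    """Brute-force allocator: walk the window in day steps, binning each."""
    py = np.zeros(len(bands))
    t = start
    while t < stop - 1e-12:
        dt = min(step, stop - t)
        mid = t + dt / 2
        for i, (lo, hi) in enumerate(bands):
            if lo <= mid < hi:
                py[i] += dt
                break
        t += dt
    return py


def make_table(air, bands=NINE_BANDS, py=1000.0):
    """An AgeBandTable with prescribed annual rates and dummy exposure."""
    air = np.asarray(air, dtype=float)
    return AgeBandTable(
        bands=bands,
        person_years=np.full(len(bands), py),
        n_first_cancers=np.zeros(len(bands), dtype=int),
        air=air,
        se_air=np.zeros(len(bands)),
    )


class TestTabulatePersonYears:
    def test_single_patient_single_band(self):
        rec = make_record(age_inclusion=25.0, age_last_observation=30.0)
        t = tabulate_person_years([rec], "crc")
        assert t.person_years[0] == pytest.approx(5.0)
        assert t.person_years[1:].sum() == 0.0
        assert t.n_first_cancers.sum() == 0

    def test_fractional_split_matches_day_stepping_oracle(self):
        rec = make_record(age_inclusion=28.0, age_last_observation=41.5)
        t = tabulate_person_years([rec], "crc")
        assert t.person_years[:4].tolist() == pytest.approx([2.0, 5.0, 5.0, 1.5])
        # the oracle allocates in day steps, so band splits agree to ~1 day
        oracle = day_step_person_years(28.0, 41.5, t.bands)
        assert t.person_years == pytest.approx(oracle, abs=0.01)
        assert t.person_years.sum() == pytest.approx(oracle.sum(), abs=1e-9)

    @given(
        start=st.floats(20.0, 70.0),
        length=st.floats(0.5, 30.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_allocation_matches_oracle_for_random_windows(self, start, length):
        rec = make_record(age_inclusion=start, age_last_observation=start + length)
        t = tabulate_person_years([rec], "crc")
        if start + length <= 25.0:
            assert t.person_years.sum() == 0.0
            return
        oracle = day_step_person_years(max(25.0, start), min(start + length, 75.0), t.bands)
        assert t.person_years == pytest.approx(oracle, abs=0.01)
        assert t.person_years.sum() == pytest.approx(oracle.sum(), abs=1e-9)

    def test_event_ends_followup_and_lands_in_its_band(self):
        rec = make_record(age_inclusion=25.0, age_last_observation=45.0,
                          events=((33.0, "153"),))
        t = tabulate_person_years([rec], "crc")
        assert t.person_years[0] == pytest.approx(5.0)
        assert t.person_years[1] == pytest.approx(3.0)
        assert t.person_years[2:].sum() == 0.0
        assert t.n_first_cancers[1] == 1

    def test_band_edge_event_belongs_to_upper_band(self):
        rec = make_record(age_inclusion=25.0, age_last_observation=45.0,
                          events=((30.0, "153"),))
        t = tabulate_person_years([rec], "crc")
        assert t.n_first_cancers[1] == 1  # [30,35), half-open convention

    def test_any_policy_censors_at_first_other_class_cancer(self):
        rec = make_record(age_inclusion=25.0, age_last_observation=60.0,
                          events=((45.0, "182"), (50.0, "153")))
        t_any = tabulate_person_years([rec], "crc", censor_policy="any")
        assert t_any.person_years.sum() == pytest.approx(20.0)  # stops at 45
        assert t_any.n_first_cancers.sum() == 0
        t_cls = tabulate_person_years([rec], "crc", censor_policy="class")
        assert t_cls.person_years.sum() == pytest.approx(25.0)  # runs to 50
        assert t_cls.n_first_cancers.sum() == 1

    def test_observation_before_25_contributes_nothing(self):
        rec = make_record(age_inclusion=20.0, age_last_observation=24.0)
        t = tabulate_person_years([rec], "crc")
        assert t.person_years.sum() == 0.0

    def test_prevalent_case_triggers_defensive_error(self):
        rec = make_record(age_inclusion=40.0, age_last_observation=45.0,
                          events=((39.0, "153"),))
        with pytest.raises(ValueError, match="prevalent"):
            tabulate_person_years([rec], "crc")


class TestAnnualIncidenceRates:
    def test_rate_is_cancers_over_person_years(self):
        t = AgeBandTable(bands=((25, 30),), person_years=np.array([1982.0]),
                         n_first_cancers=np.array([19]))
        t = annual_incidence_rates(t)
        assert t.air[0] == pytest.approx(19 / 1982)
        assert t.se_air[0] == pytest.approx(np.sqrt(19) / 1982)

    def test_zero_cancers_give_zero_rate_and_se(self):
        t = AgeBandTable(bands=((25, 30),), person_years=np.array([500.0]),
                         n_first_cancers=np.array([0]))
        t = annual_incidence_rates(t)
        assert t.air[0] == 0.0 and t.se_air[0] == 0.0

    def test_zero_exposure_band_flagged_undefined(self):
        t = AgeBandTable(bands=((25, 30), (30, 35)), person_years=np.array([100.0, 0.0]),
                         n_first_cancers=np.array([1, 0]))
        t = annual_incidence_rates(t)
        assert np.isnan(t.air[1]) and t.undefined[1]


class TestHazardTransform:
    @pytest.mark.parametrize(
        "air,se,h,seh",
        [
            (0.0, 0.002, 0.0, 0.002),
            (0.01, 0.002, -np.log(0.99), 0.002 / 0.99),
            (0.5, 0.0, np.log(2), 0.0),
        ],
    )
    def test_printed_formulas(self, air, se, h, seh):
        got_h, got_seh = hazard_transform(air, se)
        assert got_h == pytest.approx(h, abs=1e-12)
        assert got_seh == pytest.approx(seh, abs=1e-12)

    def test_rate_of_one_rejected(self):
        with pytest.raises(ValueError):
            hazard_transform(1.0, 0.1)


class TestCumulativeIncidence:
    def test_all_zero_rates_give_flat_zero_curve(self):
        curve = cumulative_incidence(make_table(np.zeros(9)))
        assert np.all(curve.q == 0.0) and np.all(curve.se_q == 0.0)

    def test_absorbing_rate_of_one(self):
        air = np.zeros(9)
        air[0] = 1.0
        curve = cumulative_incidence(make_table(air))
        assert curve.q_at(25) == 1.0 and curve.q_at(70) == 1.0

    def test_first_year_equals_first_band_rate(self):
        air = np.full(9, 0.02)
        curve = cumulative_incidence(make_table(air))
        assert curve.q_at(25) == pytest.approx(0.02, abs=1e-15)

    def test_constant_rate_closed_form(self):
        curve = cumulative_incidence(make_table(np.full(9, 0.01)))
        assert curve.q_at(70) == pytest.approx(1 - 0.99**45, abs=1e-12)

    @given(
        air=st.lists(st.floats(0.0, 0.3), min_size=9, max_size=9),
    )
    @settings(max_examples=100, deadline=None)
    def test_recursion_equals_product_closed_form(self, air):
        curve = cumulative_incidence(make_table(air))
        expected = 1.0 - np.prod((1.0 - np.asarray(air)) ** 5)
        assert curve.q_at(70) == pytest.approx(expected, abs=1e-12)

    @given(air=st.lists(st.floats(0.0, 0.9), min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_curve_is_monotone_and_bounded(self, air):
        curve = cumulative_incidence(make_table(air))
        assert np.all(np.diff(curve.q) >= -1e-15)
        assert np.all((curve.ci_low <= curve.q + 1e-12) & (curve.q <= curve.ci_high + 1e-12))
        assert np.all((0.0 <= curve.ci_low) & (curve.ci_high <= 1.0))

    def test_degenerate_age_range_rejected(self):
        with pytest.raises(ValueError):
            cumulative_incidence(make_table(np.zeros(9)), age_start=70, age_stop=70)

    def test_zero_exposure_band_warns_and_counts_as_zero(self):
        t = AgeBandTable(
            bands=NINE_BANDS,
            person_years=np.array([1000.0] * 8 + [0.0]),
            n_first_cancers=np.array([10] * 8 + [0]),
        )
        t = annual_incidence_rates(t)
        with pytest.warns(UserWarning, match="zero person-years"):
            curve = cumulative_incidence(t)
        expected = 1.0 - (1.0 - 0.01) ** 40  # last band contributes nothing
        assert curve.q_at(70) == pytest.approx(expected, abs=1e-12)
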