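"""Cleaning, merge, imputation, exclusion-cascade and strata tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_series
from stepimpact.preprocessing import (
    AnalysisWindow,
    ExclusionTally,
    assign_strata,
    baseline_band,
    clean_and_merge,
    compute_baseline_mean,
    fiscal_year,
    impute_series,
    season_of,
    select_cohort,
    series_to_frame,
    frame_to_series,
)

REG = pd.Timestamp("2021-05-10")


def _records(rows):
    """rows: list of (offset, source, steps)."""
    return pd.DataFrame(
        {
            "user_id": "u0",
            "date": [REG + pd.Timedelta(days=o) for o, _, _ in rows],
            "source": [s for _, s, _ in rows],
            "steps": [v for _, _, v in rows],
        }
    )


class TestCleanAndMerge:
    @pytest.mark.parametrize(
        "rows, expected",
        [
            # larger stream wins on disagreement
            ([(0, "stream_a", 5000), (0, "stream_b", 6000)], 6000.0),
            # below-200 readings are implausible -> missing
            ([(0, "stream_a", 150)], np.nan),
            # an invalid stream must not win the max: filter precedes merge
            ([(0, "stream_a", 60_000), (0, "stream_b", 4000)], 4000.0),
            # manual pedometer entries are discarded
            ([(0, "manual", 9000)], np.nan),
            ([(0, "manual", 9000), (0, "stream_a", 3000)], 3000.0),
        ],
    )
    def test_merge_rules(self, rows, expected):
        series = clean_and_merge(_records(rows), REG)
        got = series.value_at(0)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_boundary_values_retained(self):
        series = clean_and_merge(
            _records([(0, "stream_a", 200), (1, "stream_a", 50_000)]), REG
        )
        assert series.value_at(0) == 200
        assert series.value_at(1) == 50_000

    def test_duplicate_rows_are_an_integrity_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            clean_and_merge(
                _records([(0, "stream_a", 5000), (0, "stream_a", 5200)]), REG
            )

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=-35, max_value=28),
                st.integers(min_value=0, max_value=60_000),
            ),
            min_size=1,
            max_size=40,
            unique_by=lambda t: t[0],
        )
    )
    def test_filter_merge_idempotent(self, day_vals):
        """Re-cleaning a cleaned series changes nothing."""
        rows = [(o, "stream_a", v) for o, v in day_vals]
        once = clean_and_merge(_records(rows), REG)
        observed = [
            (int(o), "stream_a", int(v))
            for o, v in zip(once.offsets, once.steps)
            if not np.isnan(v)
        ]
        if not observed:
            return
        twice = clean_and_merge(_records(observed), REG)
        np.testing.assert_array_equal(once.steps, twice.steps)


class TestImputation:
    def test_mean_of_previous_seven_days(self):
        vals = {o: v for o, v in zip(range(-8, -1), range(1000, 8000, 1000))}
        series = make_series(vals | {o: 5000 for o in range(-35, -8)})
        out = impute_series(series)
        assert out.value_at(-1) == 4000.0
        assert out.window_imputed(-1, -1)[0]

    def test_chained_propagation_of_constant_history(self):
        series = make_series({o: 3000 for o in range(-35, -28)})
        out = impute_series(series)
        filled = out.window_values(-28, -1)
        np.testing.assert_allclose(filled, 3000.0)
        assert out.window_imputed(-28, -1).all()

    def test_stays_missing_when_all_predecessors_missing(self):
        series = make_series({10: 4000})
        out = impute_series(series)
        assert np.isnan(out.value_at(-28))

    def test_partial_history_uses_available_days(self):
        series = make_series({-3: 2000, -2: 4000} | {o: 3000 for o in range(-35, -28)})
        out = impute_series(series)
        # day -1 mean over the non-missing of days -8..-2 (imputed ones included)
        prev = out.window_values(-8, -2)
        assert out.value_at(-1) == pytest.approx(np.nanmean(prev))

    def test_coverage_error(self):
        series = make_series({0: 5000}, post_end=28)
        short = AnalysisWindow(post_end=56)
        with pytest.raises(ValueError, match="cover"):
            impute_series(series, short)

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_observed_values_never_altered(self, data):
        offsets = data.draw(
            st.lists(st.integers(-35, 28), min_size=1, max_size=30, unique=True)
        )
        vals = {o: data.draw(st.integers(200, 50_000)) for o in offsets}
        series = make_series(vals)
        out = impute_series(series)
        for o, v in vals.items():
            assert out.value_at(o) == v
            assert not out.window_imputed(o, o)[0]


class TestBaselineMean:
    def test_constant_series(self):
        s = make_series({o: 5000 for o in range(-35, 29)})
        assert compute_baseline_mean(s) == 5000.0

    def test_balanced_mean(self):
        vals = {o: (4000 if o % 2 else 6000) for o in range(-28, 0)}
        s = make_series(vals | {o: 5000 for o in range(-35, -28)})
        assert compute_baseline_mean(s) == 5000.0

    def test_no_imputation_variant_skips_imputed_days(self):
        vals = {o: 5000 for o in range(-35, 0) if o != -10}
        s = impute_series(make_series(vals))
        assert s.window_imputed(-10, -10)[0]
        assert compute_baseline_mean(s, include_imputed=True) == 5000.0
        assert compute_baseline_mean(s, include_imputed=False) == 5000.0

    def test_undefined_mean_raises(self):
        s = make_series({})
        with pytest.raises(ValueError, match="no usable"):
            compute_baseline_mean(s)


class TestStrata:
    @pytest.mark.parametrize(
        "date, season, fy",
        [
            ("2020-04-15", "spring", 2020),
            ("2021-03-31", "spring", 2020),  # March is spring but still FY2020
            ("2020-12-01", "winter", 2020),
            ("2021-01-15", "winter", 2020),
            ("2023-09-30", "fall", 2023),
        ],
    )
    def test_season_and_fiscal_year(self, date, season, fy):
        ts = pd.Timestamp(date)
        assert season_of(ts) == season
        assert fiscal_year(ts) == fy

    @pytest.mark.parametrize(
        "value, band",
        [
            (0, "<2000"), (1999.9, "<2000"), (2000.0, "2000-3999"),
            (3999.4, "2000-3999"), (4000.0, "4000-5999"), (5999.9, "4000-5999"),
            (6000, "6000-7999"), (8000, "8000-9999"), (10_000, "10000-11999"),
            (11_999.9, "10000-11999"), (12_000, ">=12000"), (30_000, ">=12000"),
        ],
    )
    def test_baseline_band_boundaries(self, value, band):
        assert baseline_band(value) == band

    def test_assign_strata_row(self):
        profile = pd.Series(
            {
                "sex": "female",
                "birth_date": pd.Timestamp("1958-06-01"),
                "registration_date": pd.Timestamp("2020-04-15"),
            }
        )
        label = assign_strata(profile, 4200.0)
        assert label.age_band == "60-69"
        assert label.season == "spring"
        assert label.fiscal_year == 2020
        assert label.baseline_band == "4000-5999"


def _profile(uid, sex="female", birth="1980-01-01", pref="Osaka", reg="2021-05-10"):
    return {
        "user_id": uid,
        "sex": sex,
        "birth_date": pd.Timestamp(birth) if birth else pd.NaT,
        "prefecture": pref,
        "registration_date": pd.Timestamp(reg),
    }


class TestSelectCohort:
    def test_age_nineteen_excluded_at_rule_three(self):
        profiles = pd.DataFrame([_profile("u0", birth="2002-01-01")])
        series = {"u0": make_series({o: 5000 for o in range(-35, 29)})}
        cohort, kept, tally = select_cohort(profiles, series)
        assert tally.age_out_of_range == 1
        assert tally.remaining == 0

    def test_rule_order_first_failure_counts(self):
        # missing sex AND wrong prefecture: counted at the first rule only
        profiles = pd.DataFrame([_profile("u0", sex=None, pref="Other")])
        series = {"u0": make_series({o: 5000 for o in range(-35, 29)})}
        _, _, tally = select_cohort(profiles, series)
        assert tally.missing_sex_or_birth == 1
        assert tally.outside_prefecture == 0

    def test_complete_and_imputed_membership(self):
        profiles = pd.DataFrame([_profile("u0"), _profile("u1")])
        full = {o: 5000 for o in range(-35, 29)}
        gap = dict(full)
        del gap[10]
        series = {"u0": make_series(full, "u0"), "u1": make_series(gap, "u1")}
        cohort, kept, tally = select_cohort(profiles, series)
        assert tally.remaining == 2
        by_uid = cohort.set_index("user_id")["complete_data"]
        assert bool(by_uid["u0"]) is True
        assert bool(by_uid["u1"]) is False

    def test_unlinked_and_unimputable_users_excluded(self):
        profiles = pd.DataFrame([_profile("u0"), _profile("u1")])
        series = {
            "u0": make_series({}),  # never linked
            "u1": make_series({5: 5000}),  # post-only stub: pre stays missing
        }
        _, _, tally = select_cohort(profiles, series)
        assert tally.not_linkable == 1
        assert tally.missing_after_imputation == 1
        assert tally.remaining == 0

    def test_tally_conservation_on_contaminated_cohort(self):
        from stepimpact.synthetic import DemographyParams, generate_profiles

        demo = DemographyParams(
            missing_sex_rate=0.1, missing_birth_rate=0.05,
            foreign_residence_rate=0.05, age_out_of_range_rate=0.05,
        )
        profiles = generate_profiles(200, demo, seed=13)
        series = {
            uid: make_series({o: 5000 for o in range(-35, 29)}, uid)
            for uid in profiles["user_id"]
        }
        _, _, tally = select_cohort(profiles, series)
        tally.check()
        assert tally.total == 200
        assert tally.excluded > 0

    def test_contamination_free_cohort_keeps_everyone(self):
        from stepimpact.synthetic import generate_profiles

        profiles = generate_profiles(50, seed=14)
        series = {
            uid: make_series({o: 5000 for o in range(-35, 29)}, uid)
            for uid in profiles["user_id"]
        }
        _, _, tally = select_cohort(profiles, series)
        assert tally.remaining == 50
        assert tally.excluded == 0


def test_series_frame_round_trip():
    series = {"u7": make_series({o: 4321 for o in range(-35, 29)}, "u7")}
    back = frame_to_series(series_to_frame(series))
    np.testing.assert_array_equal(back["u7"].steps, series["u7"].steps)
    np.testing.assert_array_equal(back["u7"].offsets, series["u7"].offsets)
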