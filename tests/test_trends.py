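"""Weekly trend series, overall averages, and correlation statistics."""

import math
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from vaxsent.corpus import UsageError
from vaxsent.trends import (
    cross_platform_average,
    get_series,
    overall_proportions,
    pearson_r,
    round_half_up,
    trend_strength,
    week_start,
    weekly_proportions,
)


def frame(rows):
    df = pd.DataFrame(rows, columns=["id", "timestamp", "country", "platform", "label"])
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


ONE_WEEK = frame(
    [
        ("a", "2020-05-04", "GB", "twitter", 1),
        ("b", "2020-05-05", "GB", "twitter", 1),
        ("c", "2020-05-06", "GB", "twitter", -1),
        ("d", "2020-05-07", "GB", "twitter", 0),
    ]
)


class TestWeeklyProportions:
    def test_single_week_hand_tally(self):
        out = weekly_proportions(ONE_WEEK)
        by_class = out.set_index("class")["proportion"]
        assert by_class["positive"] == pytest.approx(0.5)
        assert by_class["negative"] == pytest.approx(0.25)
        assert by_class["neutral"] == pytest.approx(0.25)
        assert (out["n"] == 4).all()

    def test_all_positive_series_constant_one(self):
        df = ONE_WEEK.assign(label=1)
        out = weekly_proportions(df)
        pos = out[out["class"] == "positive"]
        assert (pos["proportion"] == 1.0).all()

    def test_proportions_sum_to_one_per_week(self):
        rng = np.random.default_rng(4)
        df = frame(
            [
                (f"p{i}",
                 pd.Timestamp("2020-03-01") + pd.Timedelta(days=int(rng.integers(60))),
                 "GB", "twitter", int(rng.integers(-1, 2)))
                for i in range(300)
            ]
        )
        out = weekly_proportions(df)
        sums = out.groupby("week_start")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_weeks_are_iso_monday_start(self):
        assert week_start("2020-05-06") == date(2020, 5, 4)  # Wed -> Mon
        assert week_start("2020-05-04") == date(2020, 5, 4)

    def test_zero_post_weeks_emitted_as_missing(self):
        df = frame(
            [("a", "2020-05-04", "GB", "twitter", 1),
             ("b", "2020-05-25", "GB", "twitter", 1)]  # two-week gap
        )
        out = weekly_proportions(df)
        weeks = sorted(out["week_start"].unique())
        assert len(weeks) == 4
        gap = out[(out["week_start"] == date(2020, 5, 11))]
        assert (gap["n"] == 0).all() and gap["proportion"].isna().all()

    def test_unlabeled_posts_excluded_and_counted(self):
        df = ONE_WEEK.copy()
        df.loc[0, "label"] = np.nan
        out = weekly_proportions(df)
        assert out.attrs["n_unlabeled"] == 1
        assert (out["n"] == 3).all()


class TestOverallProportions:
    def test_hand_tally_percentages(self):
        out = overall_proportions(ONE_WEEK)
        by_class = out.set_index("class")["percent"]
        assert by_class["positive"] == 50.00
        assert by_class["negative"] == 25.00
        assert by_class["neutral"] == 25.00

    def test_percentages_sum_to_hundred_within_rounding(self):
        rng = np.random.default_rng(8)
        df = frame(
            [(f"p{i}", "2020-06-01", "GB",
              "twitter" if i % 2 else "facebook", int(rng.integers(-1, 2)))
             for i in range(301)]
        )
        out = overall_proportions(df)
        for _, grp in out.groupby("platform"):
            assert grp["percent"].sum() == pytest.approx(100.0, abs=0.02)

    def test_empty_corpus_gives_empty_frame(self):
        out = overall_proportions(frame([]))
        assert out.empty


class TestCrossPlatformAverage:
    def test_published_worked_example(self):
        """The unweighted platform mean reproduces the printed overall UK
        negative share: mean(27.95, 17.04) -> 22.50 after half-up rounding."""
        got = cross_platform_average(
            {"twitter": {"negative": 27.95}, "facebook": {"negative": 17.04}}
        )
        assert got["negative"] == 22.50

    def test_idempotent_on_equal_inputs(self):
        got = cross_platform_average(
            {"twitter": {"positive": 33.33}, "facebook": {"positive": 33.33}}
        )
        assert got["positive"] == 33.33

    def test_midpoint(self):
        got = cross_platform_average(
            {"twitter": {"neutral": 0.0}, "facebook": {"neutral": 100.0}}
        )
        assert got["neutral"] == 50.00

    def test_symmetric_in_platforms(self):
        a = {"twitter": {"negative": 27.95}, "facebook": {"negative": 17.04}}
        b = {"facebook": {"negative": 17.04}, "twitter": {"negative": 27.95}}
        assert cross_platform_average(a) == cross_platform_average(b)

    def test_missing_platform_rejected(self):
        with pytest.raises(UsageError):
            cross_platform_average({"twitter": {"negative": 10.0}})

    def test_half_up_rounding_at_the_boundary(self):
        assert round_half_up(22.495) == 22.50
        assert round_half_up(2.675) == 2.68  # repr-based, immune to float repr of 2.675


class TestPearson:
    def test_self_correlation_is_one(self):
        x = [1.0, 2.0, 5.0, 3.0]
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_definitional_computation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert pearson_r(x, y) == pytest.approx(expected)

    def test_constant_series_not_available_with_warning(self):
        with pytest.warns(UserWarning):
            out = pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(out)

    def test_missing_values_dropped_pairwise(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, np.nan, 3.0, 4.0, 5.0]
        assert pearson_r(x, y) == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(UsageError):
            pearson_r([1.0, 2.0], [2.0, 1.0])

    @given(
        a=st.floats(0.01, 5), b=st.floats(-5, 5),
        c=st.floats(0.01, 5), d=st.floats(-5, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_positive_affine_transforms(self, a, b, c, d):
        x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        base = pearson_r(x, y)
        assert pearson_r(a * x + b, c * y + d) == pytest.approx(base, abs=1e-6)


class TestTrendStrength:
    def series(self, props):
        return pd.DataFrame(
            {
                "week_start": [
                    date(2020, 3, 2) + timedelta(days=7 * i) for i in range(len(props))
                ],
                "proportion": props,
                "n": [100] * len(props),
            }
        )

    def test_linear_increase_is_perfect_trend(self):
        assert trend_strength(self.series([0.1, 0.2, 0.3, 0.4])) == pytest.approx(1.0)

    def test_constant_series_not_available(self):
        with pytest.warns(UserWarning):
            assert math.isnan(trend_strength(self.series([0.3, 0.3, 0.3])))

    def test_planted_linear_ramp_with_binomial_noise_recovered(self):
        """At 1,000 posts/week a ramping share gives trend r >= 0.9."""
        rng = np.random.default_rng(21)
        planted = np.linspace(0.2, 0.6, 38)
        observed = rng.binomial(1000, planted) / 1000
        assert trend_strength(self.series(list(observed))) >= 0.9


def test_get_series_orders_by_week():
    df = frame(
        [("a", "2020-05-12", "GB", "twitter", 1),
         ("b", "2020-05-04", "GB", "twitter", 0)]
    )
    out = get_series(weekly_proportions(df), "GB", "twitter", "positive")
    assert list(out["week_start"]) == sorted(out["week_start"])
    assert len(out) == 2
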