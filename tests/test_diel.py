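import numpy as np
import pandas as pd
import pytest

from tunatag.diel import (classify_altered_week, classify_diel,
                          daily_similarity, day_night_partition,
                          diel_return_day, hourly_profiles, permutation_null,
                          rank_days, similarity_analysis,
                          compare_across_phases)
from tunatag.solar import lunar_phase, lunar_phase_angle, sun_times


class TestDayNightPartition:
    def test_fixed_boundaries_split_day_in_half(self):
        times = pd.date_range("2020-09-01", periods=24, freq="h", tz="UTC")
        is_day = day_night_partition(times)
        assert is_day.sum() == 12
        assert is_day[6] and not is_day[18]  # half-open [sunrise, sunset)

    def test_timestamp_at_sunset_is_night(self):
        rise = pd.Timestamp("2020-09-01T06:30", tz="UTC")
        sets = pd.Timestamp("2020-09-01T19:45", tz="UTC")
        date = pd.Timestamp("2020-09-01", tz="UTC")
        times = pd.DatetimeIndex([rise, sets - pd.Timedelta(seconds=1), sets])
        is_day = day_night_partition(times, {date: (rise, sets)})
        np.testing.assert_array_equal(is_day, [True, True, False])

    def test_polar_day_defaults_to_all_day_with_warning(self):
        date = pd.Timestamp("2020-06-21", tz="UTC")
        times = pd.date_range(date, periods=4, freq="6h", tz="UTC")
        with pytest.warns(UserWarning, match="no sunset"):
            is_day = day_night_partition(times, {date: (None, None)})
        assert is_day[:4].all()

    def test_solar_routine_plugs_in(self):
        times = pd.date_range("2020-09-01T00:00", periods=24, freq="h",
                              tz="UTC")
        is_day = day_night_partition(times, lat=50.0, lon=-5.0)
        # early-September Celtic Sea: roughly 05:30-18:45 UTC daylight
        assert 12 <= is_day.sum() <= 14
        assert not is_day[3] and is_day[12]


class TestSolarAndLunar:
    def test_sunrise_sunset_against_almanac(self):
        rise, sets = sun_times("2020-06-21", 50.0, -5.0)
        assert abs((rise - pd.Timestamp("2020-06-21T04:11", tz="UTC"))
                   .total_seconds()) < 300
        assert abs((sets - pd.Timestamp("2020-06-21T20:33", tz="UTC"))
                   .total_seconds()) < 300

    def test_known_new_moon(self):
        assert lunar_phase("2020-09-17") == "new"

    def test_half_cycle_is_opposite_phase(self):
        d = pd.Timestamp("2020-09-17", tz="UTC")
        assert lunar_phase(d + pd.Timedelta(days=29.530589 / 2)) == "full"

    def test_periodic_with_synodic_month(self):
        d = pd.Timestamp("2020-09-17", tz="UTC")
        a0 = lunar_phase_angle(d)
        a1 = lunar_phase_angle(d + pd.Timedelta(days=29.530588853))
        assert abs(a1 - a0) < 0.01 or abs(abs(a1 - a0) - 360) < 0.01


class TestClassifyDiel:
    def test_identical_distributions_neither(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.2, 0.05, 30)
        cls, _, p = classify_diel(x, x.copy())
        assert cls == "neither"

    def test_published_effect_size_detected(self):
        # day 0.30 +/- 0.14 vs night 0.18 +/- 0.10, n = 30/30
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            day = rng.normal(0.30, 0.14, 30)
            night = rng.normal(0.18, 0.10, 30)
            cls, _, _ = classify_diel(day, night)
            hits += cls == "diurnal"
        assert hits >= 19

    def test_swapping_groups_mirrors_classification(self):
        rng = np.random.default_rng(5)
        day = rng.normal(0.30, 0.14, 30)
        night = rng.normal(0.18, 0.10, 30)
        c1, _, _ = classify_diel(day, night)
        c2, _, _ = classify_diel(night, day)
        assert (c1, c2) == ("diurnal", "nocturnal")

    def test_skewed_data_routes_to_wilcoxon(self):
        rng = np.random.default_rng(6)
        day = rng.lognormal(-1.0, 1.2, 60)
        night = rng.lognormal(-1.6, 1.2, 60)
        _, test, _ = classify_diel(day, night)
        assert test == "wilcoxon"


class TestDielReturn:
    def test_all_diurnal_returns_day_one(self):
        assert diel_return_day([True] * 10) == 1

    def test_sparse_flags_enumerated(self):
        flags = np.zeros(12, bool)
        flags[[2, 4, 8]] = True  # days 3, 5, 9
        assert diel_return_day(flags) == 3

    def test_two_diurnal_days_never_qualify(self):
        flags = np.zeros(30, bool)
        flags[[4, 20]] = True
        assert diel_return_day(flags) is None


class TestHourlyProfiles:
    def test_constant_metric_constant_profile(self):
        fs = 0.2
        v = np.full(int(2 * 86400 * fs), 0.3)
        prof = hourly_profiles(v, fs, "2020-09-01T00:00:00Z", 2)
        assert prof.shape == (2, 24)
        np.testing.assert_allclose(prof, 0.3)

    def test_half_day_of_data_masks_half_the_bins(self):
        fs = 0.2
        v = np.full(int(12 * 3600 * fs), 1.0)
        prof = hourly_profiles(v, fs, "2020-09-01T00:00:00Z", 1)
        assert np.isfinite(prof[0]).sum() == 12

    def test_equals_bruteforce_groupby(self):
        rng = np.random.default_rng(7)
        fs = 0.5
        v = rng.uniform(0, 1, int(86400 * fs))
        prof = hourly_profiles(v, fs, "2020-09-01T06:30:00Z", 1)
        t = np.arange(len(v)) / fs
        hour = ((6 * 3600 + 30 * 60 + t) // 3600).astype(int) % 24
        expected = pd.Series(v).groupby(hour).mean()
        np.testing.assert_allclose(prof[0], expected.to_numpy(), rtol=1e-12)


class TestDailySimilarity:
    def test_identical_nonconstant_profiles_all_one(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 24))
        prof = np.tile(base, (30, 1))
        values = daily_similarity(prof)
        np.testing.assert_allclose(values, 1.0)

    def test_single_inverted_day_scores_minus_one(self):
        base = np.sin(np.linspace(0, 2 * np.pi, 24))
        prof = np.tile(base, (30, 1))
        prof[10] = -base
        values = daily_similarity(prof)
        assert values[10] == pytest.approx(-1.0)
        mask = np.arange(30) != 10
        np.testing.assert_allclose(values[mask], 1.0)

    def test_bounded_for_random_profiles(self):
        rng = np.random.default_rng(8)
        values = daily_similarity(rng.standard_normal((30, 24)))
        assert np.all(values >= -1.0) and np.all(values <= 1.0)

    def test_constant_profile_day_excluded_with_warning(self):
        rng = np.random.default_rng(9)
        prof = rng.standard_normal((5, 24))
        prof[2] = 0.25
        with pytest.warns(UserWarning, match="excluded"):
            values = daily_similarity(prof)
        assert np.isnan(values[2])


class TestRanks:
    def test_increasing_values_rank_in_order(self):
        values = np.linspace(-0.5, 0.9, 30)
        np.testing.assert_array_equal(rank_days(values), np.arange(1, 31))

    def test_ties_broken_by_earlier_day(self):
        values = np.array([0.5, 0.2, 0.9, 0.2])
        ranks = rank_days(values)
        assert ranks[1] == 1 and ranks[3] == 2  # day 2 beats day 4 at the tie

    def test_rank_vector_is_a_permutation(self):
        rng = np.random.default_rng(10)
        ranks = rank_days(rng.standard_normal(30))
        assert sorted(ranks) == list(range(1, 31))


class TestPermutationNull:
    def test_flags_exactly_two_lowest_for_any_seed(self):
        rng = np.random.default_rng(11)
        for seed in range(5):
            ranks = rng.permutation(np.arange(1, 31))
            _, flagged = permutation_null(ranks, n_perm=5000, seed=seed)
            assert set(np.flatnonzero(flagged) + 1) == {
                int(np.flatnonzero(ranks == 1)[0]) + 1,
                int(np.flatnonzero(ranks == 2)[0]) + 1}

    def test_exact_null_quantile_is_two(self):
        # inverted-CDF 5th percentile of uniform{1..30}: P(<=1)=3.3% < 5%
        # <= P(<=2)=6.7%, so the threshold is 2
        cdf = np.arange(1, 31) / 30
        assert int(np.argmax(cdf >= 0.05)) + 1 == 2

    def test_same_seed_same_flags(self):
        ranks = np.random.default_rng(12).permutation(np.arange(1, 31))
        t1, f1 = permutation_null(ranks, n_perm=3000, seed=42)
        t2, f2 = permutation_null(ranks, n_perm=3000, seed=42)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(t1, t2)

    def test_low_n_perm_warns(self):
        ranks = np.arange(1, 31)
        with pytest.warns(UserWarning, match="unstable"):
            permutation_null(ranks, n_perm=200, seed=0)


class TestAlteredWeek:
    def _ranks(self, mean_rank):
        r = np.full(30, np.nan)
        r[:7] = mean_rank
        return r

    def _flags(self, days):
        f = np.zeros(30, bool)
        f[[d - 1 for d in days]] = True
        return f

    @pytest.mark.parametrize("days,mean_rank,expected", [
        ({2, 21}, 13, True),    # early flagged day, low mean rank
        ({20, 21}, 17, False),  # no flagged day in the first week
        ({1, 7}, 9, True),
        ({8, 9}, 5, False),     # low rank alone is not enough
        ({3}, 16, False),       # flagged day alone is not enough
    ])
    def test_decision_rule(self, days, mean_rank, expected):
        got = classify_altered_week(self._flags(days), self._ranks(mean_rank))
        assert got is expected

    def test_inclusive_vs_strict_cutoff_at_fifteen(self):
        flags, ranks = self._flags({2}), self._ranks(15)
        assert classify_altered_week(flags, ranks, inclusive=True)
        assert not classify_altered_week(flags, ranks, inclusive=False)


class TestSimilarityPipeline:
    def test_full_analysis_flags_planted_outliers(self):
        rng = np.random.default_rng(13)
        base = np.sin(np.linspace(0, 2 * np.pi, 24))
        prof = base + 0.05 * rng.standard_normal((30, 24))
        prof[1] = -base + 0.05 * rng.standard_normal(24)   # day 2 inverted
        prof[20] = rng.standard_normal(24)                 # day 21 scrambled
        res = similarity_analysis(prof, n_perm=3000, seed=0)
        assert res.flagged_days == [2, 21]
        # the verdict is exactly the decision rule applied to its own outputs
        assert res.altered_week == classify_altered_week(res.flagged, res.ranks)


class TestLunarComparison:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(14)
        dates = pd.date_range("2020-09-01", periods=60, freq="D")
        H, p = compare_across_phases(rng.normal(0.2, 0.05, 60), dates)
        assert p > 0.01

    def test_rank_statistic_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(15)
        dates = pd.date_range("2020-09-01", periods=60, freq="D")
        m = rng.lognormal(0, 0.5, 60)
        H1, _ = compare_across_phases(m, dates)
        H2, _ = compare_across_phases(np.log(m), dates)
        assert H1 == pytest.approx(H2, rel=1e-9)
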