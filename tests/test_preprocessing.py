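"""Pooling, normalization, windowing and weekly summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import afwear as aw
from afwear.cohort import RawSensorStream
from afwear.preprocessing import correlation_band


def stream_from_minutes(hr_per_min, steps_per_min, start="2024-01-01T00:00:00",
                        pid="P001"):
    """One HR sample and one step record per minute (NaN = omit the record)."""
    start = np.datetime64(start, "s")
    hr_t, hr_v, st_t, st_v = [], [], [], []
    for i, (h, s) in enumerate(zip(hr_per_min, steps_per_min)):
        t = start + np.timedelta64(60 * i, "s")
        if not np.isnan(h):
            hr_t.append(t)
            hr_v.append(h)
        if not np.isnan(s):
            st_t.append(t)
            st_v.append(s)
    return RawSensorStream(pid, np.array(hr_t, dtype="datetime64[s]"),
                           np.array(hr_v, float),
                           np.array(st_t, dtype="datetime64[s]"),
                           np.array(st_v, float))


class TestPooling:
    def test_hr_averaged_within_minute(self):
        t0 = np.datetime64("2024-01-01T00:00:00", "s")
        s = RawSensorStream(
            "P1",
            hr_times=t0 + np.array([0, 10, 20], "timedelta64[s]"),
            hr_values=np.array([70.0, 72.0, 74.0]),
            step_times=np.array([t0]),
            step_values=np.array([0.0]))
        series = aw.pool_to_minutes(s)
        assert series.hr_bpm[0] == pytest.approx(72.0)

    def test_steps_summed_within_minute(self):
        t0 = np.datetime64("2024-01-01T00:00:00", "s")
        s = RawSensorStream(
            "P1", hr_times=np.array([t0]), hr_values=np.array([70.0]),
            step_times=t0 + np.array([0, 15, 30], "timedelta64[s]"),
            step_values=np.array([5.0, 0.0, 7.0]))
        series = aw.pool_to_minutes(s)
        assert series.steps[0] == 12

    def test_empty_minute_is_masked(self):
        s = stream_from_minutes([70, np.nan, 74], [3, np.nan, 5])
        series = aw.pool_to_minutes(s)
        assert np.isnan(series.hr_bpm[1])
        assert np.isnan(series.steps[1])
        assert list(series.mask) == [0, 1, 0]

    def test_empty_stream_rejected(self):
        s = RawSensorStream("P1", np.array([], "datetime64[s]"), np.array([]),
                            np.array([], "datetime64[s]"), np.array([]))
        with pytest.raises(ValueError):
            aw.pool_to_minutes(s)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(min_value=30, max_value=180), min_size=2, max_size=60))
    def test_one_sample_per_minute_roundtrip(self, hrs):
        """Pooling a stream with exactly one sample per minute reproduces it."""
        s = stream_from_minutes(hrs, [0] * len(hrs))
        series = aw.pool_to_minutes(s)
        np.testing.assert_allclose(series.hr_bpm, hrs)
        assert series.mask.sum() == 0


class TestNormalization:
    def test_zscore_and_unit_range(self, pooled_series):
        for series in pooled_series[:3]:
            norm = aw.normalize_patient(series)
            ok = series_ok = ~np.isnan(series.hr_bpm)
            assert abs(norm.hr_bpm[ok].mean()) < 1e-9
            assert abs(norm.hr_bpm[ok].std() - 1.0) < 1e-9
            assert norm.steps.min() >= 0.0 and norm.steps.max() <= 1.0

    def test_missing_minutes_filled_with_zero(self):
        s = stream_from_minutes([70, np.nan, 74], [3, np.nan, 6])
        norm = aw.normalize_patient(aw.pool_to_minutes(s))
        assert norm.hr_bpm[1] == 0.0 and norm.steps[1] == 0.0
        assert norm.mask[1] == 1

    def test_steps_scaling_by_patient_max(self):
        s = stream_from_minutes([70, 72, 74], [0, 50, 100])
        norm = aw.normalize_patient(aw.pool_to_minutes(s))
        np.testing.assert_allclose(norm.steps, [0.0, 0.5, 1.0])

    def test_sedentary_patient_guarded(self):
        s = stream_from_minutes([70, 72, 74], [0, 0, 0])
        norm = aw.normalize_patient(aw.pool_to_minutes(s))
        assert np.all(norm.steps == 0.0)

    def test_constant_hr_rejected(self):
        s = stream_from_minutes([70, 70, 70], [0, 1, 2])
        with pytest.raises(ValueError, match="zero variance|constant"):
            aw.normalize_patient(aw.pool_to_minutes(s))


class TestWindows:
    def _norm_series(self, n_minutes, seed=0):
        rng = np.random.default_rng(seed)
        hrs = rng.normal(72, 5, n_minutes)
        return aw.normalize_patient(aw.pool_to_minutes(
            stream_from_minutes(hrs, rng.integers(0, 20, n_minutes))))

    @pytest.mark.parametrize("T,expected", [(480, 5), (240, 1), (239, 0)])
    def test_window_count(self, T, expected):
        wins = aw.extract_windows(self._norm_series(T), window_min=240, stride_min=60)
        assert len(wins) == expected

    def test_window_shape_and_availability(self):
        wins = aw.extract_windows(self._norm_series(480))
        assert all(w.values.shape == (240, 3) for w in wins)
        assert all(w.available for w in wins)   # no missingness here

    def test_fully_missing_window_unavailable(self):
        hrs = [70.0, 75.0] + [np.nan] * 300 + [72.0, 71.0]
        steps = [1.0, 2.0] + [np.nan] * 300 + [1.0, 1.0]
        norm = aw.normalize_patient(aw.pool_to_minutes(stream_from_minutes(hrs, steps)))
        wins = aw.extract_windows(norm, window_min=240, stride_min=60)
        assert wins and not wins[1].available

    def test_translation_consistency(self):
        """Dropping one stride from the front shifts windows by one index."""
        series = self._norm_series(600)
        wins = aw.extract_windows(series, stride_min=60)
        import dataclasses
        shifted = dataclasses.replace(
            series, hr_bpm=series.hr_bpm[60:], steps=series.steps[60:],
            mask=series.mask[60:], start=series.start + np.timedelta64(3600, "s"))
        wins2 = aw.extract_windows(shifted, stride_min=60)
        np.testing.assert_allclose(wins2[0].values, wins[1].values)

    def test_requires_normalized_series(self, pooled_series):
        with pytest.raises(ValueError):
            aw.extract_windows(pooled_series[0])


class TestWeeklySummaries:
    @pytest.mark.parametrize("steps,expected", [
        (14_999, "low"), (15_000, "minimum_recommended"),
        (29_999, "minimum_recommended"), (30_000, "recommended")])
    def test_cdc_activity_thresholds(self, steps, expected):
        from afwear.preprocessing import categorize_activity
        assert categorize_activity(steps) == expected

    def test_constant_week_mean(self):
        n = aw.cohort.MINUTES_PER_WEEK
        series = aw.pool_to_minutes(stream_from_minutes([70.0] * n, [1.0] * n))
        [w] = aw.weekly_summaries(series)
        assert w.mean_hr_bpm == pytest.approx(70.0)
        assert w.total_steps == n
        assert w.nonmissing_minutes == n

    def test_max_weeks_truncation(self, pooled_series):
        assert all(len(aw.weekly_summaries(s, max_weeks=1)) <= 1
                   for s in pooled_series)

    def test_sparse_week_excluded(self):
        n = aw.cohort.MINUTES_PER_WEEK
        hrs = [70.0, 72.0] + [np.nan] * (n - 2)           # ~0% nonmissing week
        hrs += [71.0] * n                                  # full second week
        steps = [1.0] * len(hrs)
        out = aw.weekly_summaries(aw.pool_to_minutes(stream_from_minutes(hrs, steps)))
        assert [w.week_index for w in out] == [2]

    def test_step_conservation(self, pooled_series):
        """Weekly totals equal the sum of that week's minute steps."""
        series = pooled_series[0]
        for w in aw.weekly_summaries(series):
            lo = (w.week_index - 1) * aw.cohort.MINUTES_PER_WEEK
            hi = lo + aw.cohort.MINUTES_PER_WEEK
            assert w.total_steps == int(np.nansum(series.steps[lo:hi]))


class TestDaytimeCorrelation:
    def _stream(self, hr, steps):
        # 08:00 start => all records in daytime
        return stream_from_minutes(hr, steps, start="2024-01-01T08:00:00")

    def test_perfect_monotone(self):
        rho, p, band = aw.daytime_correlation(
            self._stream([60, 65, 70, 75, 80], [1, 2, 3, 4, 5]), interval_s=60)
        assert rho == pytest.approx(1.0)
        assert band == "strong"

    def test_matches_rank_formula(self):
        """Pairs (1,2),(2,1),(3,4),(4,3),(5,5): rho = 1 - 6*4/120 = 0.8."""
        rho, _, _ = aw.daytime_correlation(
            self._stream([61, 62, 63, 64, 65], [2, 1, 4, 3, 5]), interval_s=60)
        assert rho == pytest.approx(1 - 6 * 4 / (5 * 24))

    @pytest.mark.parametrize("rho,expected", [
        (0.15, "very weak"), (0.4, "weak to moderate"), (0.8, "strong")])
    def test_bands(self, rho, expected):
        assert correlation_band(rho) == expected

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            aw.daytime_correlation(self._stream([70, 71], [1, 2]), interval_s=60)

    def test_nighttime_records_excluded(self):
        # start at 23:30: first 30 minutes excluded, leaving too few pairs
        s = stream_from_minutes([70, 71, 72], [1, 2, 3],
                                start="2024-01-01T23:30:00")
        with pytest.raises(ValueError):
            aw.daytime_correlation(s, interval_s=60)
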