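"""Dominance and exceedance indicator metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import T0, hourly_series, make_event, minute_series
from vesselsound.errors import InvalidArgumentError, UndefinedMetricError
from vesselsound.metrics import (
    dominance_percent_hours,
    hour_of_day_profile,
    hourly_exceedance,
    minute_exceedance,
)


def hour_grid(n, start=T0):
    return pd.date_range(start, periods=n, freq="h")


class TestDominance:
    def test_12_of_24_sampled_hours_gives_50_percent(self):
        events = [make_event(h * 60 + 10, h * 60 + 20) for h in range(12)]
        out = dominance_percent_hours(events, hour_grid(24))
        assert out.percent_hours_dominant == pytest.approx(50.0)
        assert out.n_vessel_hours == 12 and out.n_sampled_hours == 24

    def test_no_events_gives_zero(self):
        out = dominance_percent_hours([], hour_grid(24))
        assert out.percent_hours_dominant == 0.0

    def test_matches_brute_force_hour_labelling_oracle(self, rng):
        events = []
        for _ in range(30):
            s = rng.uniform(0, 60 * 48)
            events.append(make_event(s, s + rng.uniform(1, 200)))
        hours = hour_grid(48)
        out = dominance_percent_hours(events, hours)
        marked = 0
        for h in hours:
            h1 = h + pd.Timedelta(hours=1)
            if any(e.start < h1 and e.end > h for e in events):
                marked += 1
        assert out.percent_hours_dominant == pytest.approx(100.0 * marked / 48)

    def test_partial_overlap_counts_the_hour(self):
        out = dominance_percent_hours([make_event(59, 61)], hour_grid(24))
        assert out.n_vessel_hours == 2  # any-overlap rule touches two hours

    def test_non_vessel_events_ignored(self):
        out = dominance_percent_hours(
            [make_event(10, 20, label="non-vessel")], hour_grid(24)
        )
        assert out.percent_hours_dominant == 0.0

    def test_zero_sampled_hours_undefined(self):
        with pytest.raises(UndefinedMetricError):
            dominance_percent_hours([], pd.DatetimeIndex([], tz="UTC"))

    def test_monotone_in_added_events_and_bounded(self, rng):
        hours = hour_grid(24)
        events = []
        prev = 0.0
        for _ in range(15):
            s = rng.uniform(0, 60 * 24)
            events.append(make_event(s, s + rng.uniform(1, 120)))
            cur = dominance_percent_hours(events, hours).percent_hours_dominant
            assert prev <= cur <= 100.0
            prev = cur


class TestHourlyExceedance:
    def test_plus_6_db_fixture(self):
        levels = hourly_series([100.0] * 12 + [94.0] * 12)
        events = [make_event(h * 60 + 5, h * 60 + 30) for h in range(12)]
        rec = hourly_exceedance(levels, events)
        assert rec.value_db == pytest.approx(6.0)

    def test_negative_exceedance_when_nonvessel_hours_louder(self):
        levels = hourly_series([90.0] * 12 + [95.0] * 12)
        events = [make_event(h * 60 + 5, h * 60 + 30) for h in range(12)]
        assert hourly_exceedance(levels, events).value_db == pytest.approx(-5.0)

    def test_matches_sort_based_median_difference_oracle(self, rng):
        n = 200
        levels = hourly_series(rng.normal(95, 4, size=n))
        vessel_hours = sorted(rng.choice(n, size=60, replace=False))
        events = [make_event(h * 60 + 1, h * 60 + 10) for h in vessel_hours]
        rec = hourly_exceedance(levels, events)
        v = np.sort(levels.levels_db[list(vessel_hours)])
        nv = np.sort(np.delete(levels.levels_db, list(vessel_hours)))

        def mid(x):
            return 0.5 * (x[(len(x) - 1) // 2] + x[len(x) // 2])

        assert rec.value_db == pytest.approx(mid(v) - mid(nv))

    def test_all_hours_one_class_is_undefined(self):
        levels = hourly_series([95.0] * 24)
        with pytest.raises(UndefinedMetricError):
            hourly_exceedance(levels, [])

    def test_translation_invariance(self, rng):
        levels_db = rng.normal(95, 3, size=48)
        events = [make_event(h * 60, h * 60 + 45) for h in range(0, 48, 3)]
        a = hourly_exceedance(hourly_series(levels_db), events).value_db
        b = hourly_exceedance(hourly_series(levels_db + 7.3), events).value_db
        assert a == pytest.approx(b, abs=1e-9)

    def test_requires_hourly_resolution(self):
        with pytest.raises(InvalidArgumentError):
            hourly_exceedance(minute_series([90.0] * 60), [])


class TestMinuteExceedance:
    def test_median_2_max_4_fixture(self):
        # event minutes {100, 102, 104}; nearest vessel-free window -> 100 dB
        levels = np.full(60, 100.0)
        levels[30:33] = [100.0, 102.0, 104.0]
        ev = make_event(30, 33)
        rec = minute_exceedance(ev, minute_series(levels), [ev])
        assert rec.median_diff_db == pytest.approx(2.0)
        assert rec.max_diff_db == pytest.approx(4.0)

    def test_baseline_matches_exhaustive_window_scan(self, rng):
        levels = rng.normal(95, 2, size=240)
        ev1, ev2 = make_event(100, 110), make_event(180, 190)
        events = [ev1, ev2]
        series = minute_series(levels)
        rec = minute_exceedance(ev1, series, events)

        # oracle: brute-force over every vessel-free 10-minute window
        vessel_minutes = set(range(100, 110)) | set(range(180, 190))
        best = None
        for w0 in range(240 - 10 + 1):
            window = range(w0, w0 + 10)
            if any(m in vessel_minutes for m in window):
                continue
            gap = (100 - (w0 + 10)) if w0 + 10 <= 100 else (w0 - 110)
            gap = max(gap, 0) * 60.0
            if best is None or gap < best[0]:
                best = (gap, w0)
        _, w0 = best
        baseline = 10 * np.log10(np.mean(10 ** (levels[w0 : w0 + 10] / 10)))
        assert rec.median_diff_db == pytest.approx(
            np.median(levels[100:110]) - baseline
        )
        assert rec.baseline_start == T0 + pd.Timedelta(minutes=w0)

    def test_earlier_window_wins_gap_ties(self):
        levels = np.full(31, 95.0)
        levels[10] = 90.0  # distinguish the earlier candidate window
        ev = make_event(15, 16)
        rec = minute_exceedance(ev, minute_series(levels), [ev])
        # windows [14,15) and [16,17) are both adjacent (gap 0); earlier wins
        assert rec.baseline_start == T0 + pd.Timedelta(minutes=14)

    def test_event_spanning_whole_record_is_undefined(self):
        ev = make_event(0, 60)
        with pytest.raises(UndefinedMetricError):
            minute_exceedance(ev, minute_series(np.full(60, 95.0)), [ev])

    def test_baseline_window_avoids_all_vessel_events(self, rng):
        levels = rng.normal(95, 2, size=300)
        events = [make_event(60 * k, 60 * k + 30) for k in range(5)]
        series = minute_series(levels)
        for ev in events:
            rec = minute_exceedance(ev, series, events)
            for other in events:
                assert not (
                    rec.baseline_start < other.end and rec.baseline_end > other.start
                )

    def test_translation_invariance(self, rng):
        levels = rng.normal(95, 2, size=120)
        ev = make_event(50, 60)
        a = minute_exceedance(ev, minute_series(levels), [ev])
        b = minute_exceedance(ev, minute_series(levels + 11.0), [ev])
        assert a.median_diff_db == pytest.approx(b.median_diff_db, abs=1e-9)
        assert a.max_diff_db == pytest.approx(b.max_diff_db, abs=1e-9)


class TestHourOfDayProfile:
    def test_daily_30_minute_event_gives_mean_30_se_0(self):
        events = []
        for day in range(30):
            s = day * 1440 + 10 * 60
            events.append(make_event(s, s + 30))
        prof = hour_of_day_profile(events, "2019-04")
        assert prof.mean_minutes[10] == pytest.approx(30.0)
        assert prof.se_minutes[10] == pytest.approx(0.0)
        assert prof.mean_minutes[[h for h in range(24) if h != 10]].sum() == 0.0

    def test_no_events_gives_all_zeros(self):
        prof = hour_of_day_profile([], "2019-04")
        assert prof.mean_minutes.sum() == 0.0 and prof.se_minutes.sum() == 0.0

    def test_matches_minute_tally_oracle(self, rng):
        events = []
        for _ in range(40):
            s = rng.uniform(0, 30 * 1440 - 200)
            events.append(make_event(s, s + rng.uniform(5, 180)))
        prof = hour_of_day_profile(events, "2019-04")

        tally = np.zeros((30, 24))
        for day in range(30):
            for hour in range(24):
                for minute in range(60):
                    m0 = T0 + pd.Timedelta(minutes=day * 1440 + hour * 60 + minute)
                    m1 = m0 + pd.Timedelta(minutes=1)
                    if any(e.start < m1 and e.end > m0 for e in events):
                        tally[day, hour] += 1
                        continue
        np.testing.assert_allclose(prof.mean_minutes, tally.mean(axis=0))
        np.testing.assert_allclose(
            prof.se_minutes, tally.std(axis=0, ddof=1) / np.sqrt(30), atol=1e-12
        )

    def test_low_coverage_days_excluded(self):
        # 2 days of minute levels; day 2 has only 300 valid minutes (<50%)
        levels = np.full(2 * 1440, 95.0)
        levels[1440 + 300 :] = np.nan
        series = minute_series(levels)
        events = [make_event(10 * 60, 10 * 60 + 30)]  # day 1 only
        prof = hour_of_day_profile(events, "2019-04", minute_levels=series)
        assert prof.n_days == 1
        assert prof.mean_minutes[10] == pytest.approx(30.0)
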