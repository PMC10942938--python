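"""LTSA construction, adaptive thresholding, and the three-criterion detector.

Structural tests run on a reduced frequency span (PSD to 300 Hz with
detector bands low 40–100, medium 100–200, high 200–300 Hz) so fixtures stay
small; the band logic is identical at any span.
"""

import numpy as np
import pandas as pd
import pytest

from vesselsound.bands import PsdSeries, from_db, to_db
from vesselsound.detector import (
    DetectorConfig,
    adaptive_threshold,
    block_process,
    build_ltsa,
    detect_events,
    relabel_event,
)
from vesselsound.errors import ConfigError

T0 = pd.Timestamp("2019-04-01T00:00:00Z")

SMALL = dict(
    low_band=(40.0, 100.0),
    medium_band=(100.0, 200.0),
    high_band=(200.0, 300.0),
    window_s=1800.0,
    block_s=3600.0,
    buffer_s=600.0,
)


def small_config(**kw):
    cfg = dict(SMALL)
    cfg.update(kw)
    return DetectorConfig(**cfg)


def make_psd(values, start=T0, fmax=300):
    return PsdSeries(start, np.arange(1, fmax + 1, dtype=float), values)


def noise_psd(rng, n_seconds, level_db=70.0, sigma_db=2.0, fmax=300):
    base = from_db(level_db)
    g = rng.standard_normal((n_seconds, fmax))
    return make_psd(base * np.exp(sigma_db * np.log(10) / 10 * g), fmax=fmax)


def add_box_signal(psd, t0, t1, f0, f1, add_db):
    """Raise a time × frequency box by add_db (in place)."""
    fmask = (psd.freqs >= f0) & (psd.freqs < f1)
    psd.values[t0:t1, fmask] *= from_db(add_db)
    return psd


class TestBuildLtsa:
    def test_constant_psd_gives_constant_db(self):
        psd = make_psd(np.full((50, 300), 100.0))
        ltsa = build_ltsa(psd)
        assert ltsa.values_db.shape == (10, 6)
        np.testing.assert_allclose(ltsa.values_db, to_db(100.0))

    def test_matches_nested_loop_block_mean_oracle(self, rng):
        psd = make_psd(rng.exponential(1.0, size=(23, 300)))
        ltsa = build_ltsa(psd)
        assert ltsa.values_db.shape == (4, 6)  # trailing partial blocks dropped
        for i in range(4):
            for j in range(6):
                block = psd.values[i * 5 : (i + 1) * 5, j * 48 : (j + 1) * 48]
                assert ltsa.values_db[i, j] == pytest.approx(to_db(block.mean()))

    def test_input_shorter_than_one_block_gives_empty(self):
        ltsa = build_ltsa(make_psd(np.ones((4, 300))))
        assert ltsa.n_bins == 0

    def test_cell_frequencies_are_block_centres(self):
        ltsa = build_ltsa(make_psd(np.ones((5, 300))))
        np.testing.assert_allclose(ltsa.freqs, [24.5, 72.5, 120.5, 168.5, 216.5, 264.5])


class TestAdaptiveThreshold:
    def test_constant_series_gives_value_plus_offset(self):
        cfg = small_config()
        series = np.full(720, 83.0)
        np.testing.assert_allclose(
            adaptive_threshold(series, cfg), 83.0 + cfg.threshold_offset_db
        )

    def test_percentile_stat_matches_independent_oracle(self, rng):
        cfg = small_config()
        series = rng.normal(75.0, 1.0, size=900)
        thr = adaptive_threshold(series, cfg)
        wlen = int(cfg.window_s / 5)
        for w0 in range(0, 900, wlen):
            chunk = series[w0 : w0 + wlen]
            oracle = np.percentile(chunk, cfg.threshold_percentile)
            np.testing.assert_allclose(thr[w0 : w0 + wlen], oracle + cfg.threshold_offset_db)

    def test_mode_stat_matches_brute_force_histogram_oracle(self, rng):
        cfg = small_config(threshold_stat="mode", window_s=900.0)
        series = rng.normal(75.0, 0.8, size=600)
        thr = adaptive_threshold(series, cfg)
        wlen = 180
        for w0 in range(0, 600, wlen):
            chunk = series[w0 : w0 + wlen]
            # brute-force absolute-grid histogram mode
            k = np.floor(chunk / cfg.hist_bin_db).astype(int)
            counts = {}
            for kk in k:
                counts[kk] = counts.get(kk, 0) + 1
            best = min(sorted(counts), key=lambda kk: (-counts[kk], kk))
            centre = (best + 0.5) * cfg.hist_bin_db
            near = chunk[np.abs(chunk - centre) <= 1.5 * cfg.hist_bin_db]
            oracle = np.median(near) + cfg.threshold_offset_db
            np.testing.assert_allclose(thr[w0 : w0 + wlen], oracle)

    def test_level_step_between_windows_steps_threshold(self):
        cfg = small_config()
        wlen = int(cfg.window_s / 5)
        series = np.concatenate([np.full(wlen, 70.0), np.full(wlen, 76.0)])
        thr = adaptive_threshold(series, cfg)
        assert thr[0] == pytest.approx(70.0 + cfg.threshold_offset_db)
        assert thr[-1] == pytest.approx(76.0 + cfg.threshold_offset_db)

    def test_window_longer_than_series_degenerates_to_global(self):
        cfg = small_config(window_s=36000.0)
        series = np.full(100, 65.0)
        np.testing.assert_allclose(
            adaptive_threshold(series, cfg), 65.0 + cfg.threshold_offset_db
        )


class TestDetectEvents:
    def test_broadband_transit_detected_with_tight_endpoints(self, rng):
        cfg = small_config()
        psd = noise_psd(rng, 3600)
        # vessel-like: strongest low, weaker medium, weakest high band
        add_box_signal(psd, 1200, 1320, 40, 100, 15.0)
        add_box_signal(psd, 1210, 1310, 100, 200, 10.0)
        add_box_signal(psd, 1240, 1280, 200, 300, 8.0)
        events = detect_events(build_ltsa(psd), cfg)
        vessel = [e for e in events if e.label == "vessel"]
        assert len(vessel) == 1
        (ev,) = vessel
        assert abs((ev.start - (T0 + pd.Timedelta(seconds=1200))).total_seconds()) <= 5
        assert abs((ev.end - (T0 + pd.Timedelta(seconds=1320))).total_seconds()) <= 5

    def test_click_train_surrogate_labelled_non_vessel(self, rng):
        cfg = small_config()
        psd = noise_psd(rng, 3600)
        # echolocation-like: longest exceedance in the high band, medium-band
        # exceedance too brief to qualify under the duration criterion
        add_box_signal(psd, 1200, 1320, 200, 300, 15.0)
        add_box_signal(psd, 1270, 1290, 100, 200, 12.0)
        add_box_signal(psd, 1240, 1320, 40, 100, 12.0)
        events = detect_events(build_ltsa(psd), cfg)
        assert len(events) >= 1
        assert all(e.label == "non-vessel" for e in events)

    def test_stationary_noise_gives_no_events(self, rng):
        cfg = small_config()
        events = detect_events(build_ltsa(noise_psd(rng, 3600)), cfg)
        assert events == []

    def test_weather_like_broadband_step_not_vessel(self, rng):
        cfg = small_config()
        psd = noise_psd(rng, 3600)
        # sustained broadband rise with equal band durations
        add_box_signal(psd, 900, 1800, 40, 300, 8.0)
        events = detect_events(build_ltsa(psd), cfg)
        assert all(e.label == "non-vessel" for e in events)

    def test_band_outside_ltsa_range_raises_config_error(self, rng):
        cfg = small_config(high_band=(1000.0, 5000.0))
        with pytest.raises(ConfigError):
            detect_events(build_ltsa(noise_psd(rng, 600)), cfg)

    def test_raising_offset_never_increases_vessel_events(self, rng):
        psd = noise_psd(rng, 3600)
        add_box_signal(psd, 1200, 1320, 40, 100, 15.0)
        add_box_signal(psd, 1210, 1310, 100, 200, 10.0)
        counts = []
        for offset in (3.0, 4.8, 8.0, 12.0, 20.0):
            cfg = small_config(threshold_offset_db=offset)
            events = detect_events(build_ltsa(psd), cfg)
            counts.append(sum(e.label == "vessel" for e in events))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_event_intervals_disjoint_and_inside_record(self, rng):
        psd = noise_psd(rng, 3600)
        add_box_signal(psd, 600, 700, 40, 200, 14.0)
        add_box_signal(psd, 2000, 2150, 40, 200, 14.0)
        events = detect_events(build_ltsa(psd), small_config())
        end = T0 + pd.Timedelta(seconds=3600)
        for e in events:
            assert T0 <= e.start < e.end <= end
        for a, b in zip(events, events[1:]):
            assert a.end <= b.start


class TestBlockProcess:
    def _psd_with_events(self, rng, n_seconds=10800, event_times=((1500, 1620),)):
        psd = noise_psd(rng, n_seconds)
        for t0, t1 in event_times:
            add_box_signal(psd, t0, t1, 40, 100, 15.0)
            add_box_signal(psd, t0 + 5, t1 - 5, 100, 200, 10.0)
        return psd

    def test_event_inside_one_block_matches_single_pass(self, rng):
        psd = self._psd_with_events(rng)
        cfg = small_config()
        assert block_process(psd, cfg) == detect_events(build_ltsa(psd), cfg)

    def test_event_spanning_block_boundary_is_one_event(self, rng):
        psd = self._psd_with_events(rng, event_times=((3540, 3700),))
        cfg = small_config()  # block boundary at 3600 s
        blocked = block_process(psd, cfg)
        single = detect_events(build_ltsa(psd), cfg)
        assert blocked == single
        assert sum(e.label == "vessel" for e in blocked) == 1

    def test_buffer_duplicates_removed(self, rng):
        psd = self._psd_with_events(
            rng, event_times=((3300, 3420), (3660, 3780), (7100, 7250))
        )
        cfg = small_config()
        assert block_process(psd, cfg) == detect_events(build_ltsa(psd), cfg)

    def test_block_must_exceed_twice_buffer(self):
        with pytest.raises(ConfigError):
            small_config(block_s=1000.0, buffer_s=600.0)


class TestRelabelEvent:
    def test_relabel_changes_label_and_sets_verified(self):
        ev = _event()
        out = relabel_event(ev, "non-vessel")
        assert out.label == "non-vessel" and out.verified
        assert out.provenance == ("vessel",)

    def test_idempotent_relabel_keeps_content(self):
        ev = _event()
        out = relabel_event(ev, "vessel")
        assert out.label == "vessel" and out.verified
        assert (out.start, out.end, out.low_db) == (ev.start, ev.end, ev.low_db)

    def test_provenance_chain_after_two_relabels(self):
        ev = relabel_event(relabel_event(_event(), "non-vessel"), "vessel")
        assert ev.provenance == ("vessel", "non-vessel")

    def test_unknown_label_rejected(self):
        with pytest.raises(Exception):
            relabel_event(_event(), "maybe")


def _event():
    from vesselsound.detector import VesselDetectionEvent

    return VesselDetectionEvent(
        start=T0, end=T0 + pd.Timedelta(minutes=10), label="vessel",
        low_db=90.0, mid_db=80.0, high_db=70.0,
    )
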