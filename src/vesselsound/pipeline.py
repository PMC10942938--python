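"""End-to-end workflow: bands → detect → metrics → AIS → categorize.

``run_pipeline`` executes the full indicator computation for one station and
month from a PSD record plus optional AIS reports, writes tidy CSV tables,
and emits a manifest (config hash, seed, version, row counts) so a rerun
with the same inputs is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ais import daily_buffer_summary, in_buffer_intervals, match_events_to_ais
from .bands import PsdSeries, band_series, make_decidecade_bands, summarize_band
from .compare import categorize
from .detector import block_process
from .errors import VesselSoundError
from .io import RunConfig, StationMetadata, write_events, write_summaries
from .metrics import (
    dominance_percent_hours,
    hourly_exceedance,
    minute_exceedance,
    month_bounds,
)

__all__ = ["run_pipeline", "month_eligible", "config_hash"]


def config_hash(config: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form of the configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def month_eligible(hourly_times: pd.DatetimeIndex, levels_db, month) -> bool:
    """True iff more than 95% of the month's days have valid hourly levels."""
    m0, m1 = month_bounds(month)
    sel = (hourly_times >= m0) & (hourly_times < m1) & np.isfinite(levels_db)
    days_covered = hourly_times[sel].floor("D").nunique()
    days_in_month = (m1 - m0).days
    return days_covered > 0.95 * days_in_month


def _stage(name: str):
    """Wrap stage errors with the failing stage's name for context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, KeyboardInterrupt):
                raise VesselSoundError(f"pipeline stage '{name}' failed: {exc}") from exc

    return _Ctx()


def run_pipeline(
    config: RunConfig,
    psd: PsdSeries,
    station: StationMetadata,
    month: str,
    ais: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Compute all vessel-noise indicators for one station-month.

    Returns a dict with the band-level series, events, metric tables, the
    quadrant label, and the manifest; if ``outdir`` is given the tables are
    also written as CSV alongside ``manifest.json``.
    """
    out: dict = {}
    band125 = make_decidecade_bands([125.0])[0]

    with _stage("bands"):
        per_second = band_series(psd, band125)
        minute = summarize_band(psd.times, per_second, "minute", band=band125)
        hourly = summarize_band(psd.times, per_second, "hour", band=band125)
        out["minute_levels"] = minute
        out["hourly_levels"] = hourly

    with _stage("detect"):
        events = block_process(psd, config.detector_config())
        out["events"] = events

    with _stage("metrics"):
        sampled_hours = hourly.times[np.isfinite(hourly.levels_db)]
        dom = dominance_percent_hours(events, sampled_hours, month=month)
        exc = hourly_exceedance(
            hourly, events, month=month, statistic=config.exceedance_statistic
        )
        minute_rows = []
        for ev in events:
            if ev.label != "vessel":
                continue
            try:
                rec = minute_exceedance(ev, minute, events)
            except VesselSoundError:
                continue
            minute_rows.append(
                {
                    "start_utc_iso8601": ev.start.isoformat(),
                    "end_utc_iso8601": ev.end.isoformat(),
                    "median_diff_db": rec.median_diff_db,
                    "max_diff_db": rec.max_diff_db,
                }
            )
        out["dominance"] = dom
        out["hourly_exceedance"] = exc
        out["minute_exceedance"] = pd.DataFrame(
            minute_rows,
            columns=["start_utc_iso8601", "end_utc_iso8601", "median_diff_db", "max_diff_db"],
        )

    with _stage("ais"):
        if ais is not None and len(ais):
            intervals = []
            for _, g in ais.groupby("vessel_id"):
                intervals.extend(in_buffer_intervals(g, station.station, config.buffer_radius_km))
            days = pd.DatetimeIndex(ais["timestamp"]).floor("D").unique().sort_values()
            daily = [
                daily_buffer_summary(ais, station.station, d, config.buffer_radius_km)
                for d in days
            ]
            flags = match_events_to_ais(events, intervals)
        else:
            daily, flags = [], [False] * len(events)
        out["ais_daily"] = pd.DataFrame(daily)
        out["ais_nearby"] = flags

    with _stage("categorize"):
        out["quadrant"] = categorize(
            dom.percent_hours_dominant,
            exc.value_db,
            (config.dominance_threshold, config.exceedance_threshold_db),
        )

    eligible = month_eligible(hourly.times, hourly.levels_db, month)
    manifest = {
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "station": station.station_id,
        "month": month,
        "month_eligible_for_comparison": bool(eligible),
        "row_counts": {
            "minute_levels": len(minute),
            "hourly_levels": len(hourly),
            "events": len(events),
            "minute_exceedance": len(out["minute_exceedance"]),
            "ais_daily": len(out["ais_daily"]),
        },
    }
    out["manifest"] = manifest

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_band_levels

        write_band_levels(minute, outdir / "minute_levels.csv")
        write_band_levels(hourly, outdir / "hourly_levels.csv")
        write_events(events, outdir / "events.csv")
        out["minute_exceedance"].to_csv(outdir / "minute_exceedance.csv", index=False)
        if len(out["ais_daily"]):
            write_summaries(out["ais_daily"], outdir / "ais_daily.csv")
        metrics_row = pd.DataFrame(
            [
                {
                    "station": station.station_id,
                    "month": month,
                    "percent_hours_dominant": dom.percent_hours_dominant,
                    "hourly_exceedance_db": exc.value_db,
                    "quadrant": out["quadrant"].label,
                    "month_eligible": bool(eligible),
                }
            ]
        )
        metrics_row.to_csv(outdir / "metrics.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
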