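"""Readers and writers for the pipeline's tabular and gridded products.

All timestamps are ISO-8601 UTC; levels are dB re 1 µPa² (band levels) or
dB re 1 µPa²/Hz (PSD), as stated in the column headers.  Write→read round
trips are exact for strings/integers and to 1e-9 for floating levels.
Malformed rows in tabular inputs are skipped and logged with line numbers;
schema-level mismatches raise hard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .bands import BandLevelSeries, PsdSeries, make_decidecade_bands
from .detector import DetectorConfig, VesselDetectionEvent
from .errors import DataQualityError
from .ais import Station

logger = logging.getLogger("vesselsound")

__all__ = [
    "StationMetadata",
    "RunConfig",
    "read_band_levels",
    "write_band_levels",
    "read_band_levels_netcdf",
    "write_band_levels_netcdf",
    "read_events",
    "write_events",
    "read_ais",
    "write_summaries",
    "read_psd_netcdf",
    "write_psd_netcdf",
]

#: marine-cadastre-style AIS column dialect
DEFAULT_AIS_COLUMNS = {
    "vessel_id": "MMSI",
    "timestamp": "BaseDateTime",
    "latitude": "LAT",
    "longitude": "LON",
    "sog_knots": "SOG",
    "length": "Length",
}

EVENT_COLUMNS = [
    "start_utc_iso8601",
    "end_utc_iso8601",
    "label",
    "low_db",
    "mid_db",
    "high_db",
    "verified",
]


@dataclass
class StationMetadata:
    """A listening station: position, deployments, and calibration."""

    station_id: str
    latitude: float
    longitude: float
    deployment_intervals: list[tuple[str, str]] = field(default_factory=list)
    shipping_lane_within_10km: bool = False
    calibration_offset_db: float = 0.0

    def __post_init__(self) -> None:
        ivs = sorted(pd.Timestamp(a) for a, _ in self.deployment_intervals)
        ends = sorted(pd.Timestamp(b) for _, b in self.deployment_intervals)
        for e, s in zip(ends[:-1], ivs[1:]):
            if s < e:
                raise DataQualityError("deployment intervals overlap")

    @property
    def station(self) -> Station:
        return Station(self.station_id, self.latitude, self.longitude)


@dataclass
class RunConfig:
    """Serializable end-to-end pipeline configuration."""

    band_nominal_hz: list[float] = field(default_factory=lambda: [125.0])
    detector: dict = field(default_factory=dict)
    exceedance_statistic: str = "median"
    dominance_threshold: float = 20.0
    exceedance_threshold_db: float = 0.0
    ais_columns: dict = field(default_factory=lambda: dict(DEFAULT_AIS_COLUMNS))
    buffer_radius_km: float = 10.0
    seed: int = 0

    def detector_config(self) -> DetectorConfig:
        cfg = dict(self.detector)
        for key in ("low_band", "medium_band", "high_band"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return DetectorConfig(**cfg)

    def to_dict(self) -> dict:
        return {
            "band_nominal_hz": list(self.band_nominal_hz),
            "detector": dict(self.detector),
            "exceedance_statistic": self.exceedance_statistic,
            "dominance_threshold": self.dominance_threshold,
            "exceedance_threshold_db": self.exceedance_threshold_db,
            "ais_columns": dict(self.ais_columns),
            "buffer_radius_km": self.buffer_radius_km,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


# ---------------------------------------------------------------- band levels

def write_band_levels(series: BandLevelSeries, path: str | Path) -> None:
    df = series.to_frame()
    df["time_utc_iso8601"] = pd.DatetimeIndex(df["time_utc_iso8601"]).strftime(
        "%Y-%m-%dT%H:%M:%S%z"
    )
    df.to_csv(path, index=False, float_format="%.9f")


def _series_from_frame(df: pd.DataFrame) -> BandLevelSeries:
    times = pd.DatetimeIndex(pd.to_datetime(df["time_utc_iso8601"], utc=True))
    if len(times) > 1:
        step = np.median(np.diff(times.asi8)) / 1e9
        resolution = "hour" if step >= 3600 else "minute"
    else:
        resolution = "minute"
    nominal = df["band_nominal_hz"].iloc[0] if len(df) else np.nan
    band = make_decidecade_bands([float(nominal)])[0] if np.isfinite(nominal) else None
    return BandLevelSeries(
        resolution=resolution,
        times=times,
        levels_db=df["level_db_re_1upa2"].to_numpy(dtype=float),
        coverage_seconds=df["coverage_seconds"].to_numpy(dtype=float),
        band=band,
    )


def read_band_levels(path: str | Path) -> BandLevelSeries:
    df = pd.read_csv(path)
    missing = set(
        ["time_utc_iso8601", "band_nominal_hz", "level_db_re_1upa2", "coverage_seconds"]
    ) - set(df.columns)
    if missing:
        raise DataQualityError(f"band-level file missing columns {sorted(missing)}")
    return _series_from_frame(df)


def write_band_levels_netcdf(series: BandLevelSeries, path: str | Path) -> None:
    """Band levels as NetCDF (classic format), semantics identical to the CSV."""
    nominal = series.band.nominal_center if series.band is not None else np.nan
    ds = xr.Dataset(
        {
            "level_db_re_1upa2": ("time", series.levels_db),
            "coverage_seconds": ("time", series.coverage_seconds),
        },
        coords={"time": series.times.tz_convert("UTC").tz_localize(None)},
        attrs={
            "resolution": series.resolution,
            "band_nominal_hz": float(nominal),
            "time_zone": "UTC",
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_band_levels_netcdf(path: str | Path) -> BandLevelSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        nominal = float(ds.attrs["band_nominal_hz"])
        band = make_decidecade_bands([nominal])[0] if np.isfinite(nominal) else None
        return BandLevelSeries(
            resolution=str(ds.attrs["resolution"]),
            times=pd.DatetimeIndex(ds["time"].values).tz_localize("UTC"),
            levels_db=ds["level_db_re_1upa2"].values.astype(float),
            coverage_seconds=ds["coverage_seconds"].values.astype(float),
            band=band,
        )


# --------------------------------------------------------------------- events

def write_events(events: Sequence[VesselDetectionEvent], path: str | Path) -> None:
    rows = [
        {
            "start_utc_iso8601": e.start.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "end_utc_iso8601": e.end.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "label": e.label,
            "low_db": e.low_db,
            "mid_db": e.mid_db,
            "high_db": e.high_db,
            "verified": e.verified,
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False, float_format="%.9f")


def read_events(path: str | Path) -> list[VesselDetectionEvent]:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise DataQualityError(f"event file missing columns {sorted(missing)}")
    events: list[VesselDetectionEvent] = []
    n_skipped = 0
    for i, row in df.iterrows():
        try:
            events.append(
                VesselDetectionEvent(
                    start=pd.Timestamp(row["start_utc_iso8601"]).tz_convert("UTC"),
                    end=pd.Timestamp(row["end_utc_iso8601"]).tz_convert("UTC"),
                    label=str(row["label"]),
                    low_db=float(row["low_db"]),
                    mid_db=float(row["mid_db"]),
                    high_db=float(row["high_db"]),
                    verified=bool(row["verified"]),
                )
            )
        except (ValueError, TypeError) as exc:
            n_skipped += 1
            logger.warning("skipping malformed event row at line %d: %s", i + 2, exc)
    if n_skipped:
        logger.warning("skipped %d malformed event rows in %s", n_skipped, path)
    return events


# ------------------------------------------------------------------------ AIS

def read_ais(path: str | Path, column_map: dict | None = None) -> pd.DataFrame:
    """Read AIS position reports with a configurable column mapping.

    Default dialect is the marine-cadastre one (MMSI, BaseDateTime, LAT,
    LON, SOG, Length).  Rows with unparseable timestamps or out-of-range
    coordinates are skipped with a logged count.
    """
    cmap = dict(DEFAULT_AIS_COLUMNS)
    cmap.update(column_map or {})
    df = pd.read_csv(path)
    required = {cmap["vessel_id"], cmap["timestamp"], cmap["latitude"], cmap["longitude"]}
    missing = required - set(df.columns)
    if missing:
        raise DataQualityError(f"AIS file missing columns {sorted(missing)}")
    out = pd.DataFrame(
        {
            "vessel_id": df[cmap["vessel_id"]].astype(str),
            "timestamp": pd.to_datetime(df[cmap["timestamp"]], utc=True, errors="coerce"),
            "latitude": pd.to_numeric(df[cmap["latitude"]], errors="coerce"),
            "longitude": pd.to_numeric(df[cmap["longitude"]], errors="coerce"),
        }
    )
    for opt in ("sog_knots", "length"):
        col = cmap.get(opt)
        out[opt] = pd.to_numeric(df[col], errors="coerce") if col in df.columns else np.nan
    bad = (
        out["timestamp"].isna()
        | out["latitude"].abs().gt(90)
        | out["longitude"].abs().gt(180)
        | out["latitude"].isna()
        | out["longitude"].isna()
    )
    if bad.any():
        for line in (np.flatnonzero(bad.to_numpy()) + 2)[:20]:
            logger.warning("skipping malformed AIS row at line %d", line)
        logger.warning("skipped %d malformed AIS rows in %s", int(bad.sum()), path)
    out = out[~bad].sort_values(["vessel_id", "timestamp"]).reset_index(drop=True)
    return out


def write_summaries(rows: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.9f")


# ------------------------------------------------------------------------ PSD

def write_psd_netcdf(psd: PsdSeries, path: str | Path) -> None:
    """1 Hz/1 s PSD as NetCDF (classic format), linear µPa²/Hz values."""
    ds = xr.Dataset(
        {"psd_upa2_per_hz": (("time", "frequency"), psd.values)},
        coords={
            "time": psd.times.tz_convert("UTC").tz_localize(None),
            "frequency": psd.freqs,
        },
        attrs={"calibration_applied": int(psd.calibration_applied), "time_zone": "UTC"},
    )
    ds.to_netcdf(path, engine="scipy")


def read_psd_netcdf(path: str | Path) -> PsdSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        times = pd.DatetimeIndex(ds["time"].values)
        return PsdSeries(
            start_time=times[0].tz_localize("UTC"),
            freqs=ds["frequency"].values.astype(float),
            values=ds["psd_upa2_per_hz"].values.astype(float),
            calibration_applied=bool(ds.attrs.get("calibration_applied", 0)),
        )
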