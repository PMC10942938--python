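"""Decidecade (one-third octave) band levels from 1 Hz / 1 s power spectral density.

The processing chain is: calibrated audio -> 1 Hz/1 s mean-square pressure
spectral density (µPa²/Hz) -> band integration over decidecade bands ->
minute/hourly summaries as the median of the linear mean-square values,
converted to decibels (dB re 1 µPa²).

Conventions
-----------
* All spectral quantities are carried in the *linear* mean-square domain
  (µPa²/Hz or µPa²) and converted to dB only at summary boundaries.
* A 1 Hz PSD bin belongs to a band iff its centre frequency f satisfies
  ``lower_edge <= f < upper_edge`` (half-open, so adjacent decidecade bands
  never share a bin).
* Summary bins are aligned to UTC wall-clock minutes/hours.  An hourly bin
  needs at least 1800 s of data; a minute bin needs at least 30 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import get_window

from .errors import CoverageError, DataQualityError, InvalidArgumentError

__all__ = [
    "PsdSeries",
    "BandSpec",
    "BandLevelSeries",
    "make_decidecade_bands",
    "integrate_band",
    "band_series",
    "summarize_band",
    "wav_to_psd",
    "to_db",
    "from_db",
]

#: Minimum seconds of data for an hourly summary bin to be reported.
HOUR_MIN_COVERAGE_S = 1800
#: Minimum seconds of data for a minute summary bin (mirrors the >=50% hourly rule).
MINUTE_MIN_COVERAGE_S = 30
#: Linear PSD floor substituted for exactly-zero power so dB values stay finite.
SILENCE_FLOOR = 1e-10


def to_db(linear: np.ndarray | float) -> np.ndarray | float:
    """Convert linear mean-square quantities to dB (re 1 µPa² or 1 µPa²/Hz)."""
    return 10.0 * np.log10(linear)


def from_db(db: np.ndarray | float) -> np.ndarray | float:
    """Convert dB back to linear mean-square quantities."""
    return np.power(10.0, np.asarray(db) / 10.0)


@dataclass
class PsdSeries:
    """Calibrated power spectral density at 1 Hz / 1 s resolution.

    Parameters
    ----------
    start_time
        UTC timestamp of the first 1-s analysis window.
    freqs
        Bin centre frequencies in Hz, uniformly spaced at exactly 1 Hz.
    values
        Array of shape ``(n_seconds, n_freqs)`` of linear mean-square
        pressure spectral density, µPa²/Hz.
    calibration_applied
        Whether a hydrophone calibration offset has been applied.
    """

    start_time: pd.Timestamp
    freqs: np.ndarray
    values: np.ndarray
    calibration_applied: bool = False

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.tz_localize("UTC")
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.freqs.size:
            raise InvalidArgumentError(
                f"values shape {self.values.shape} inconsistent with {self.freqs.size} bins"
            )
        if self.freqs.size > 1 and not np.allclose(np.diff(self.freqs), 1.0):
            raise InvalidArgumentError("PSD frequency step must be exactly 1 Hz")
        if np.any(self.values < 0):
            raise InvalidArgumentError("PSD values must be non-negative")

    @property
    def n_seconds(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> pd.DatetimeIndex:
        """UTC timestamps (window starts), 1 s apart."""
        return self.start_time + pd.to_timedelta(np.arange(self.n_seconds), unit="s")


@dataclass(frozen=True)
class BandSpec:
    """One decidecade band: nominal label, exact base-10 centre, and edges."""

    nominal_center: float
    exact_center: float
    lower_edge: float
    upper_edge: float

    def __post_init__(self) -> None:
        if not (self.lower_edge < self.exact_center < self.upper_edge):
            raise InvalidArgumentError("band edges must bracket the exact centre")


@dataclass
class BandLevelSeries:
    """Minute or hourly band sound pressure levels with coverage bookkeeping.

    ``levels_db`` is NaN wherever the coverage rule was not met, so missing
    bins are explicit rather than silently dropped.
    """

    resolution: Literal["minute", "hour"]
    times: pd.DatetimeIndex
    levels_db: np.ndarray
    coverage_seconds: np.ndarray
    band: BandSpec | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.resolution not in ("minute", "hour"):
            raise InvalidArgumentError(f"unknown resolution {self.resolution!r}")
        self.levels_db = np.asarray(self.levels_db, dtype=float)
        self.coverage_seconds = np.asarray(self.coverage_seconds, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        nominal = self.band.nominal_center if self.band is not None else np.nan
        return pd.DataFrame(
            {
                "time_utc_iso8601": self.times,
                "band_nominal_hz": nominal,
                "level_db_re_1upa2": self.levels_db,
                "coverage_seconds": self.coverage_seconds,
            }
        )


def _decidecade_index(center_hz: float) -> int:
    # base-10 decidecade band number: exact centres are 10^(n/10) Hz
    return int(np.round(10.0 * np.log10(center_hz)))


def make_decidecade_bands(
    nominal_centers: Sequence[float], *, exclude_below_125: bool = False
) -> list[BandSpec]:
    """Build decidecade :class:`BandSpec` objects for nominal centre frequencies.

    Each nominal centre (e.g. 125, 1000 Hz) is mapped to the nearest base-10
    decidecade band, whose exact centre is ``10^(n/10)`` Hz and whose edges are
    ``exact_center * 10^(∓1/20)``.  The nominal 125 Hz band has edges that
    round to 112 and 141 Hz.

    Parameters
    ----------
    nominal_centers
        Nominal band centres in Hz.
    exclude_below_125
        If true, drop bands whose nominal centre is below 125 Hz (low-frequency
        bands are excluded from the vessel-noise analysis).
    """
    bands: list[BandSpec] = []
    for nominal in nominal_centers:
        if nominal <= 0:
            raise InvalidArgumentError(f"non-positive band centre {nominal}")
        if exclude_below_125 and nominal < 125:
            continue
        exact = 10.0 ** (_decidecade_index(nominal) / 10.0)
        bands.append(
            BandSpec(
                nominal_center=float(nominal),
                exact_center=exact,
                lower_edge=exact * 10.0 ** (-1.0 / 20.0),
                upper_edge=exact * 10.0 ** (1.0 / 20.0),
            )
        )
    return bands


def _band_mask(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    return (freqs >= band.lower_edge) & (freqs < band.upper_edge)


def integrate_band(
    freqs: np.ndarray, psd_values: np.ndarray, band: BandSpec
) -> np.ndarray | float:
    """Integrate 1 Hz PSD bins over one decidecade band.

    With 1 Hz bins the integral reduces to a sum of the included bins.
    ``psd_values`` may be a single 1-s slice (1-D) or a time × frequency
    array (2-D); the band sum is taken over the last axis.

    Raises
    ------
    CoverageError
        If the band extends beyond the PSD frequency range.
    """
    freqs = np.asarray(freqs, dtype=float)
    if band.lower_edge < freqs[0] - 0.5 or band.upper_edge > freqs[-1] + 0.5:
        raise CoverageError(
            f"band [{band.lower_edge:.1f}, {band.upper_edge:.1f}) Hz outside "
            f"PSD range [{freqs[0]:.0f}, {freqs[-1]:.0f}] Hz"
        )
    mask = _band_mask(freqs, band)
    values = np.asarray(psd_values, dtype=float)
    return values[..., mask].sum(axis=-1)


def band_series(psd: PsdSeries, band: BandSpec) -> np.ndarray:
    """Per-second linear band mean-square pressure (µPa²) for one band."""
    return integrate_band(psd.freqs, psd.values, band)


def summarize_band(
    times: pd.DatetimeIndex,
    linear_values: np.ndarray,
    resolution: Literal["minute", "hour"],
    band: BandSpec | None = None,
) -> BandLevelSeries:
    """Summarize per-second linear band values into minute or hourly levels.

    Per summary bin the level is ``10*log10(median of linear values)``; bins
    that fail the coverage rule (>= 1800 s per hour, >= 30 s per minute) are
    reported as NaN with their actual coverage.  Bins are aligned to UTC
    wall-clock boundaries, so partial first/last bins fall under the same rule.
    """
    if resolution == "hour":
        freq, min_cov = "h", HOUR_MIN_COVERAGE_S
    elif resolution == "minute":
        freq, min_cov = "min", MINUTE_MIN_COVERAGE_S
    else:
        raise InvalidArgumentError(f"unknown resolution {resolution!r}")

    linear_values = np.asarray(linear_values, dtype=float)
    if len(times) == 0:
        return BandLevelSeries(
            resolution=resolution,
            times=pd.DatetimeIndex([], tz="UTC"),
            levels_db=np.array([]),
            coverage_seconds=np.array([]),
            band=band,
        )
    s = pd.Series(linear_values, index=pd.DatetimeIndex(times))
    grouped = s.groupby(s.index.floor(freq))
    med = grouped.median()
    cov = grouped.count().astype(float)
    levels = np.where(cov >= min_cov, to_db(np.maximum(med.to_numpy(), SILENCE_FLOOR)), np.nan)
    return BandLevelSeries(
        resolution=resolution,
        times=pd.DatetimeIndex(med.index),
        levels_db=levels,
        coverage_seconds=cov.to_numpy(),
        band=band,
    )


def wav_to_psd(
    samples: np.ndarray,
    sample_rate: int,
    calibration_offset_db: float = 0.0,
    start_time: pd.Timestamp | str = "1970-01-01T00:00:00Z",
    fmax: float = 24000.0,
    silence_floor: float = SILENCE_FLOOR,
) -> PsdSeries:
    """Compute a 1 Hz / 1 s PSD series from calibrated audio samples.

    Each non-overlapping 1-s segment is Hann-windowed and transformed; the
    one-sided periodogram is normalized by the window power so that the sum of
    PSD bins equals the segment's (window-weighted) mean-square pressure —
    Parseval-consistent to within the window's spectral leakage (about 1% for
    broadband or many-cycle tonal content).

    Parameters
    ----------
    samples
        Audio samples on the µPa pressure scale *before* calibration offset.
    sample_rate
        48000 or 96000 Hz.
    calibration_offset_db
        Added to the PSD in dB (i.e. the linear PSD is scaled by
        ``10^(offset/10)``); the output is marked calibrated.
    start_time
        UTC timestamp of the first sample.
    fmax
        Highest retained frequency bin, Hz (bins run 1..fmax).
    silence_floor
        Linear floor (µPa²/Hz) substituted for exactly-zero bins so that
        silent input yields a finite, floor-valued PSD rather than -inf dB.
    """
    if sample_rate not in (48000, 96000):
        raise InvalidArgumentError(f"sample rate {sample_rate} not in (48000, 96000)")
    samples = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(samples)):
        raise DataQualityError("audio contains non-finite samples")

    n_sec = samples.size // sample_rate
    fmax = min(float(fmax), sample_rate / 2.0)
    n_keep = int(fmax)  # bins 1..fmax Hz at 1 Hz spacing
    window = get_window("hann", sample_rate)
    # density scaling: |X_k|^2 / (fs * sum(w^2)); one-sided doubling below Nyquist
    norm = sample_rate * np.sum(window**2)

    frames = samples[: n_sec * sample_rate].reshape(n_sec, sample_rate)
    spec = np.fft.rfft(frames * window, axis=1)
    psd = (np.abs(spec) ** 2) / norm
    psd[:, 1:-1] *= 2.0
    psd = psd[:, 1 : n_keep + 1]  # drop DC, keep 1..fmax Hz

    psd *= from_db(calibration_offset_db)
    psd[psd == 0.0] = silence_floor
    return PsdSeries(
        start_time=pd.Timestamp(start_time),
        freqs=np.arange(1, n_keep + 1, dtype=float),
        values=psd,
        calibration_applied=calibration_offset_db != 0.0,
    )
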