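import numpy as np
import pandas as pd
import pytest

from vesselsound.bands import BandLevelSeries
from vesselsound.detector import VesselDetectionEvent

T0 = pd.Timestamp("2019-04-01T00:00:00Z")


@pytest.fixture
def rng():
    return np.random.default_rng(20190401)


def make_event(start_min, end_min, label="vessel", base=T0, **kw):
    kw.setdefault("low_db", 90.0)
    kw.setdefault("mid_db", 80.0)
    kw.setdefault("high_db", 70.0)
    return VesselDetectionEvent(
        start=base + pd.Timedelta(minutes=start_min),
        end=base + pd.Timedelta(minutes=end_min),
        label=label,
        **kw,
    )


def minute_series(levels_db, start=T0, coverage=60.0):
    levels_db = np.asarray(levels_db, dtype=float)
    return BandLevelSeries(
        resolution="minute",
        times=pd.date_range(start, periods=levels_db.size, freq="min"),
        levels_db=levels_db,
        coverage_seconds=np.full(levels_db.size, coverage),
    )


def hourly_series(levels_db, start=T0, coverage=3600.0):
    levels_db = np.asarray(levels_db, dtype=float)
    return BandLevelSeries(
        resolution="hour",
        times=pd.date_range(start, periods=levels_db.size, freq="h"),
        levels_db=levels_db,
        coverage_seconds=np.full(levels_db.size, coverage),
    )
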