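import numpy as np
import pandas as pd
import pytest

from geopheno.io import Segment, Trace
from geopheno.simulate import M_PER_DEG_LAT

MIN = 60_000  # ms


def make_points(lats, lons, times_ms, confidence=np.nan) -> pd.DataFrame:
    conf = np.broadcast_to(np.asarray(confidence, dtype=float), (len(lats),))
    return pd.DataFrame(
        {
            "timestamp": np.asarray(times_ms, dtype="int64"),
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
            "confidence_m": conf,
        }
    )


def make_segment(lats, lons, times_ms, segment_id=0) -> Segment:
    return Segment(segment_id=segment_id, points=make_points(lats, lons, times_ms))


def make_trace(lats, lons, times_ms, subject_id="s1", timezone="UTC", confidence=np.nan):
    return Trace(
        subject_id=subject_id,
        points=make_points(lats, lons, times_ms, confidence),
        timezone=timezone,
    )


def offset_deg(dx_m, dy_m, base_lat=52.0):
    """Meters east/north -> (dlat, dlon) at the base latitude."""
    return dy_m / M_PER_DEG_LAT, dx_m / (M_PER_DEG_LAT * np.cos(np.radians(base_lat)))


@pytest.fixture
def two_dwell_segment():
    """Two 90-min dwells 2 km apart joined by a 15-min travel run (5-min fixes).

    Hand-trace of the anchor sweep: dwell A occupies fixes 0..18
    (t = 0..90 min), the three travel fixes sit 500/1000/1500 m east, dwell B
    occupies fixes 22..40 (t = 110..200 min).  Expected: stay point 1 with
    arrival 0 / departure 90 min, stay point 2 with arrival 110 / departure
    200 min, one trajectory of the 3 travel fixes spanning 90 -> 110 min.
    """
    base_lat, base_lon = 52.0, 5.0
    lats, lons, ts = [], [], []
    for k in range(19):  # dwell A: 0..90 min
        lats.append(base_lat)
        lons.append(base_lon)
        ts.append(k * 5 * MIN)
    for k, dx in enumerate([500.0, 1000.0, 1500.0]):  # travel at 95/100/105 min
        dlat, dlon = offset_deg(dx, 0.0, base_lat)
        lats.append(base_lat + dlat)
        lons.append(base_lon + dlon)
        ts.append((95 + 5 * k) * MIN)
    dlat_b, dlon_b = offset_deg(2000.0, 0.0, base_lat)
    for k in range(19):  # dwell B: 110..200 min
        lats.append(base_lat + dlat_b)
        lons.append(base_lon + dlon_b)
        ts.append((110 + 5 * k) * MIN)
    return make_segment(lats, lons, ts)


@pytest.fixture(scope="session")
def sim_subject():
    from geopheno import SimConfig, simulate_subject

    return simulate_subject(11, SimConfig())


@pytest.fixture(scope="session")
def sim_result(sim_subject):
    from geopheno import process_subject

    trace, truth = sim_subject
    return process_subject(trace), truth
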