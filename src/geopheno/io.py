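"""Reading, validating, filtering and segmenting raw location traces.

A trace is a time-ordered stream of smartphone location fixes.  Each fix is a
WGS84 coordinate with an epoch-millisecond UTC timestamp and an optional
positional confidence: the radius (meters) within which the true position lies
with 68% probability.  Timestamps are kept in UTC throughout; one IANA
timezone per subject drives all local-day and night-window logic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import ConfigError

#: Canonical column names of the in-memory point table.
POINT_COLUMNS = ["timestamp", "lat", "lon", "confidence_m"]

#: Default mapping from canonical fields to input CSV column names.
DEFAULT_SCHEMA = {
    "subject_id": "subject_id",
    "timestamp": "timestamp",
    "lat": "lat",
    "lon": "lon",
    "confidence_m": "accuracy",
}


class SchemaError(ValueError):
    """An input file is missing a required column."""


class EmptyTraceError(ValueError):
    """An input file contains no usable fixes."""


@dataclass
class LoadReport:
    """Row-level accounting for one loaded trace."""

    n_rows: int = 0
    n_invalid_coords: int = 0
    n_unparseable_time: int = 0
    n_duplicate_timestamps: int = 0
    n_points: int = 0


@dataclass
class Trace:
    """A subject's time-ordered fixes.

    ``points`` is a DataFrame with columns ``timestamp`` (epoch ms UTC,
    int64), ``lat``/``lon`` (decimal degrees) and ``confidence_m`` (meters,
    NaN when missing), strictly increasing in ``timestamp``.
    """

    subject_id: str
    points: pd.DataFrame
    timezone: str = "UTC"
    load_report: LoadReport | None = None

    def __len__(self) -> int:
        return len(self.points)

    def with_points(self, points: pd.DataFrame) -> "Trace":
        return replace(self, points=points.reset_index(drop=True))


@dataclass
class Segment:
    """A contiguous run of fixes with no internal gap above ``max_gap``."""

    segment_id: int
    points: pd.DataFrame

    @property
    def start_ms(self) -> int:
        return int(self.points["timestamp"].iloc[0])

    @property
    def end_ms(self) -> int:
        return int(self.points["timestamp"].iloc[-1])

    def __len__(self) -> int:
        return len(self.points)


def _parse_timestamps(col: pd.Series) -> pd.Series:
    """Epoch ms (numeric) or ISO-8601 strings -> epoch ms; NaN when unparseable."""
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        return numeric.astype("float64")
    parsed = pd.to_datetime(col, errors="coerce", utc=True, format="ISO8601")
    ms = parsed.astype("int64", copy=False).astype("float64") / 1e6
    ms[parsed.isna()] = np.nan
    return ms


def read_trace(
    path,
    schema: dict | None = None,
    timezone: str = "UTC",
    subject_id: str | None = None,
) -> Trace:
    """Read a delimited-text trace into a validated :class:`Trace`.

    Rows with out-of-range coordinates or unparseable timestamps are dropped
    and counted in the trace's :class:`LoadReport`.  Duplicate timestamps keep
    the first occurrence.  Raises :class:`SchemaError` if a required column is
    absent and :class:`EmptyTraceError` if no usable fix remains.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path)
    report = LoadReport(n_rows=len(df))
    for key in ("timestamp", "lat", "lon"):
        if colmap[key] not in df.columns:
            raise SchemaError(
                f"required column {colmap[key]!r} (for {key}) not found in {path}"
            )
    out = pd.DataFrame(index=df.index)
    out["timestamp"] = _parse_timestamps(df[colmap["timestamp"]])
    out["lat"] = pd.to_numeric(df[colmap["lat"]], errors="coerce")
    out["lon"] = pd.to_numeric(df[colmap["lon"]], errors="coerce")
    conf_col = colmap.get("confidence_m")
    if conf_col and conf_col in df.columns:
        out["confidence_m"] = pd.to_numeric(df[conf_col], errors="coerce")
        out.loc[out["confidence_m"] < 0, "confidence_m"] = np.nan
    else:
        out["confidence_m"] = np.nan

    bad_time = out["timestamp"].isna()
    report.n_unparseable_time = int(bad_time.sum())
    bad_coord = (
        out["lat"].isna()
        | out["lon"].isna()
        | (out["lat"].abs() > 90)
        | (out["lon"].abs() > 180)
    ) & ~bad_time
    report.n_invalid_coords = int(bad_coord.sum())
    out = out[~bad_time & ~bad_coord]

    out = out.sort_values("timestamp", kind="mergesort")
    dup = out["timestamp"].duplicated(keep="first")
    report.n_duplicate_timestamps = int(dup.sum())
    out = out[~dup].reset_index(drop=True)
    if out.empty:
        raise EmptyTraceError(f"no usable fixes in {path}")
    out["timestamp"] = out["timestamp"].astype("int64")
    report.n_points = len(out)

    if subject_id is None:
        sid_col = colmap.get("subject_id")
        if sid_col and sid_col in df.columns and len(df):
            subject_id = str(df[sid_col].iloc[0])
        else:
            subject_id = "unknown"
    return Trace(subject_id=subject_id, points=out, timezone=timezone, load_report=report)


def write_trace(trace: Trace, path, schema: dict | None = None) -> None:
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.DataFrame(
        {
            colmap["subject_id"]: trace.subject_id,
            colmap["timestamp"]: trace.points["timestamp"],
            colmap["lat"]: trace.points["lat"],
            colmap["lon"]: trace.points["lon"],
            colmap["confidence_m"]: trace.points["confidence_m"],
        }
    )
    df.to_csv(path, index=False)


def filter_by_confidence(
    trace: Trace, max_confidence_m: float, missing: str = "keep"
) -> Trace:
    """Keep fixes whose 68%-containment radius is at most ``max_confidence_m``.

    ``missing`` decides the fate of fixes with no reported confidence
    (``"keep"``, the default, or ``"drop"``).  An empty result is legal.
    """
    if max_confidence_m <= 0:
        raise ValueError("max_confidence_m must be > 0")
    if missing not in ("keep", "drop"):
        raise ValueError("missing must be 'keep' or 'drop'")
    conf = trace.points["confidence_m"]
    ok = conf <= max_confidence_m
    if missing == "keep":
        ok = ok | conf.isna()
    return trace.with_points(trace.points[ok])


def segment_on_gaps(trace: Trace, max_gap_min: float) -> list[Segment]:
    """Split a trace into contiguous segments at holes longer than ``max_gap_min``.

    The segments partition the trace: concatenated in order they reproduce it
    exactly.
    """
    if max_gap_min <= 0:
        raise ValueError("max_gap_min must be > 0")
    pts = trace.points
    if pts.empty:
        return []
    max_gap_ms = max_gap_min * 60_000.0
    ts = pts["timestamp"].to_numpy()
    breaks = np.flatnonzero(np.diff(ts) > max_gap_ms) + 1
    bounds = np.concatenate([[0], breaks, [len(pts)]])
    return [
        Segment(segment_id=i, points=pts.iloc[a:b].reset_index(drop=True))
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]))
    ]


def assign_local_days(trace: Trace) -> pd.Series:
    """Local civil date (midnight-to-midnight in the trace timezone) per fix."""
    return local_dates(trace.points["timestamp"], trace.timezone)


def local_dates(timestamps_ms: pd.Series | np.ndarray, timezone: str) -> pd.Series:
    """Vectorized epoch-ms -> local calendar date conversion."""
    try:
        dt = pd.to_datetime(
            np.asarray(timestamps_ms, dtype="int64"), unit="ms", utc=True
        ).tz_convert(timezone)
    except Exception as exc:  # pytz/zoneinfo raise several types here
        raise ConfigError(f"invalid timezone {timezone!r}") from exc
    idx = timestamps_ms.index if isinstance(timestamps_ms, pd.Series) else None
    return pd.Series(dt.date, index=idx)


def points_to_geojson(trace: Trace, path=None, states=None) -> dict:
    """Trace fixes as a GeoJSON FeatureCollection of Points (for map inspection)."""
    feats = []
    state_arr = None if states is None else np.asarray(states)
    for i, row in enumerate(trace.points.itertuples(index=False)):
        props = {"subject_id": trace.subject_id, "timestamp_ms": int(row.timestamp)}
        if state_arr is not None:
            props["state"] = str(state_arr[i])
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row.lon, row.lat]},
                "properties": props,
            }
        )
    fc = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc


def staypoints_to_geojson(staypoints: pd.DataFrame, path=None) -> dict:
    """Stay-point centroids as a GeoJSON FeatureCollection of Points."""
    feats = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [row.centroid_lon, row.centroid_lat],
            },
            "properties": {
                "arrival_ms": int(row.arrival_ms),
                "departure_ms": int(row.departure_ms),
                "duration_min": float(row.duration_min),
            },
        }
        for row in staypoints.itertuples(index=False)
    ]
    fc = {"type": "FeatureCollection", "features": feats}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(fc, fh)
    return fc
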