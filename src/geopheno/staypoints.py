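"""Stay-point detection: stationary vs non-stationary states.

A stay point is a contiguous run of fixes that remains within a distance
threshold ``theta_d`` of its anchor (the run's first fix) for at least a time
threshold ``theta_t`` — a visit to a place.  The interval between two
consecutive stay points is a trajectory (a non-stationary state, e.g.
traveling from work to home).  The sweep is the classic anchor-based
formulation: from anchor ``i`` the window grows while every fix stays within
``theta_d`` of fix ``i``; at the first exceedance (or the segment end) the
window becomes a stay point if its time span is at least ``theta_t``
(inclusive), otherwise the anchor advances by one fix.

Defaults ``theta_t`` = 60 min and ``theta_d`` = 350 m: a stay point is a group
of coordinates remaining stationary for 60 min within an area of 350 m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Segment

#: Mean Earth radius (IUGG), meters.
EARTH_RADIUS_M = 6_371_008.8

STATIONARY = "stationary"
NON_STATIONARY = "non-stationary"


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in meters on a sphere of mean Earth radius.

    Accepts scalars or broadcastable arrays of decimal degrees; symmetric and
    zero exactly when the coordinates coincide.
    """
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_M * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))


@dataclass(frozen=True)
class DetectionParams:
    """Stay-point thresholds: dwell duration (minutes) and radius (meters)."""

    theta_t_min: float = 60.0
    theta_d_m: float = 350.0

    def __post_init__(self) -> None:
        if self.theta_t_min <= 0 or self.theta_d_m <= 0:
            raise ValueError("theta_t_min and theta_d_m must be > 0")

    @property
    def theta_t_ms(self) -> float:
        return self.theta_t_min * 60_000.0


@dataclass(frozen=True)
class StayPoint:
    """A detected stationary episode within one segment.

    ``start_idx``/``end_idx`` are inclusive positions of the member fixes in
    the segment; the centroid is the unweighted mean of member coordinates.
    """

    segment_id: int
    start_idx: int
    end_idx: int
    centroid_lat: float
    centroid_lon: float
    arrival_ms: int
    departure_ms: int

    @property
    def n_fixes(self) -> int:
        return self.end_idx - self.start_idx + 1

    @property
    def duration_min(self) -> float:
        return (self.departure_ms - self.arrival_ms) / 60_000.0


@dataclass(frozen=True)
class Trajectory:
    """A non-stationary episode between two stay points (or a segment edge).

    ``start_ms`` is the departure of the preceding stay point (or the segment
    start); ``end_ms`` the arrival of the following one (or the segment end).
    Member fixes are the ``start_idx..end_idx`` run strictly between the
    neighbouring stay points' members.
    """

    segment_id: int
    start_idx: int
    end_idx: int
    start_ms: int
    end_ms: int

    @property
    def n_fixes(self) -> int:
        return self.end_idx - self.start_idx + 1


def detect_staypoints(
    segment: Segment, params: DetectionParams | None = None
) -> tuple[list[StayPoint], list[Trajectory]]:
    """Run the anchor-sweep stay-point detector on one segment.

    Returns the time-ordered, time-disjoint stay points and the trajectories
    (maximal fix runs between consecutive stay points and segment edges that
    contain at least one fix).  The duration test is inclusive, and a trailing
    window truncated by the segment end still counts if it spans ``theta_t``,
    so dwell episodes cut short by data gaps are not lost.
    """
    params = params or DetectionParams()
    pts = segment.points
    n = len(pts)
    lat = pts["lat"].to_numpy(dtype=float)
    lon = pts["lon"].to_numpy(dtype=float)
    ts = pts["timestamp"].to_numpy(dtype="int64")

    staypoints: list[StayPoint] = []
    i = 0
    while i < n:
        d = haversine_m(lat[i], lon[i], lat[i + 1 :], lon[i + 1 :])
        beyond = np.flatnonzero(d > params.theta_d_m)
        j = (i + 1 + beyond[0]) if beyond.size else n  # first fix outside theta_d
        last = j - 1
        if ts[last] - ts[i] >= params.theta_t_ms:
            staypoints.append(
                StayPoint(
                    segment_id=segment.segment_id,
                    start_idx=i,
                    end_idx=last,
                    centroid_lat=float(lat[i : j].mean()),
                    centroid_lon=float(lon[i : j].mean()),
                    arrival_ms=int(ts[i]),
                    departure_ms=int(ts[last]),
                )
            )
            i = j
        else:
            i += 1

    trajectories: list[Trajectory] = []
    prev_end_idx = -1
    prev_dep = int(ts[0]) if n else 0
    for sp in staypoints + [None]:  # sentinel for the trailing run
        lo = prev_end_idx + 1
        hi = (sp.start_idx - 1) if sp is not None else n - 1
        if hi >= lo:
            trajectories.append(
                Trajectory(
                    segment_id=segment.segment_id,
                    start_idx=lo,
                    end_idx=hi,
                    start_ms=prev_dep,
                    end_ms=int(sp.arrival_ms) if sp is not None else int(ts[hi]),
                )
            )
        if sp is not None:
            prev_end_idx = sp.end_idx
            prev_dep = sp.departure_ms
    return staypoints, trajectories


def label_states(
    segment: Segment, staypoints: list[StayPoint]
) -> np.ndarray:
    """Per-fix state label: ``stationary`` inside a stay point, else
    ``non-stationary``.  Raises if a stay point refers outside the segment."""
    n = len(segment.points)
    labels = np.full(n, NON_STATIONARY, dtype=object)
    for sp in staypoints:
        if sp.segment_id != segment.segment_id or sp.end_idx >= n or sp.start_idx < 0:
            raise ValueError("stay point does not belong to this segment")
        labels[sp.start_idx : sp.end_idx + 1] = STATIONARY
    return labels


def staypoints_to_frame(
    staypoints: list[StayPoint], subject_id: str | None = None
) -> pd.DataFrame:
    """Tabular view of stay points (one row each), ready for CSV export."""
    rows = [
        {
            "segment_id": sp.segment_id,
            "sp_index": k,
            "centroid_lat": sp.centroid_lat,
            "centroid_lon": sp.centroid_lon,
            "arrival_ms": sp.arrival_ms,
            "departure_ms": sp.departure_ms,
            "n_fixes": sp.n_fixes,
            "duration_min": sp.duration_min,
        }
        for k, sp in enumerate(staypoints)
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "segment_id",
            "sp_index",
            "centroid_lat",
            "centroid_lon",
            "arrival_ms",
            "departure_ms",
            "n_fixes",
            "duration_min",
        ],
    )
    if subject_id is not None:
        df.insert(0, "subject_id", subject_id)
    return df


def trajectories_to_frame(
    trajectories: list[Trajectory], subject_id: str | None = None
) -> pd.DataFrame:
    rows = [
        {
            "segment_id": tr.segment_id,
            "start_ms": tr.start_ms,
            "end_ms": tr.end_ms,
            "n_fixes": tr.n_fixes,
        }
        for tr in trajectories
    ]
    df = pd.DataFrame(rows, columns=["segment_id", "start_ms", "end_ms", "n_fixes"])
    if subject_id is not None:
        df.insert(0, "subject_id", subject_id)
    return df


def detect_trace(
    segments: list[Segment], params: DetectionParams | None = None, subject_id=None
) -> tuple[pd.DataFrame, pd.DataFrame, list[np.ndarray]]:
    """Detect stay points on every segment of a trace.

    Returns the concatenated stay-point and trajectory tables plus the per-
    segment state-label arrays, in segment order.
    """
    sp_frames, tr_frames, labels = [], [], []
    for seg in segments:
        sps, trs = detect_staypoints(seg, params)
        sp_frames.append(staypoints_to_frame(sps, subject_id))
        tr_frames.append(trajectories_to_frame(trs, subject_id))
        labels.append(label_states(seg, sps))
    sp_df = pd.concat(sp_frames, ignore_index=True) if sp_frames else staypoints_to_frame([], subject_id)
    tr_df = pd.concat(tr_frames, ignore_index=True) if tr_frames else trajectories_to_frame([], subject_id)
    return sp_df, tr_df, labels
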