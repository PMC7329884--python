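"""Behavioral phenotypes derived from context-enriched location data.

From the stay points and place clusters of one subject this module derives
the six mobility phenotypes — number of places visited, unique places
visited, number of trajectories, home stay, normalized location entropy and
diurnal movement — plus the home-location inference they depend on, per local
calendar day and per observation window.

Home is the place cluster accumulating the most dwell time inside a nightly
window (default 00:00–06:00 local clock), the dominant-nighttime-dwell
heuristic.  Normalized entropy is the Shannon entropy of per-place dwell
proportions divided by ``ln N``; diurnal movement is the log spectral energy
of the location time series in a period band around 24 h, so regular daily
routines score high.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

#: Energy floor guarding the log in diurnal movement (a constant location has
#: zero band energy; its score is ln of this floor, about -27.6).
DIURNAL_ENERGY_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# local-time helpers
# ---------------------------------------------------------------------------

def _local_ms(date: _dt.date, hours: float, tz: str) -> int:
    """Epoch ms of local clock time ``hours`` after midnight on ``date``."""
    naive = pd.Timestamp(date) + pd.Timedelta(hours=hours)
    ts = naive.tz_localize(tz, nonexistent="shift_forward", ambiguous=True)
    return int(ts.value // 1_000_000)


def _local_date(ms: int, tz: str) -> _dt.date:
    return pd.Timestamp(ms, unit="ms", tz="UTC").tz_convert(tz).date()


def _overlap_ms(a0: float, a1: float, b0: float, b1: float) -> float:
    return max(0.0, min(a1, b1) - max(a0, b0))


def _dates_between(d0: _dt.date, d1: _dt.date):
    d = d0
    while d <= d1:
        yield d
        d += _dt.timedelta(days=1)


# ---------------------------------------------------------------------------
# home inference and home stay
# ---------------------------------------------------------------------------

@dataclass
class HomeInference:
    """Result of the dominant-nighttime-dwell home heuristic."""

    home_cluster_id: int | None
    night_dwell_min: dict = field(default_factory=dict)

    @property
    def determined(self) -> bool:
        return self.home_cluster_id is not None


def infer_home(
    staypoints: pd.DataFrame,
    assignments: np.ndarray,
    timezone: str = "UTC",
    night_window: tuple[float, float] = (0.0, 6.0),
) -> HomeInference:
    """Infer the home cluster as the one with the most nighttime dwell.

    Nighttime dwell of a cluster is the summed overlap of its stay points
    with the nightly ``night_window`` (local clock) over the whole
    observation period.  Ties go to the cluster with the larger total dwell,
    then to the earlier first visit.  With no nighttime dwell at all, home is
    undetermined and home-stay phenotypes are emitted as missing.
    """
    assignments = np.asarray(assignments)
    night: dict[int, float] = {}
    total: dict[int, float] = {}
    first: dict[int, float] = {}
    lo, hi = night_window
    for (_, sp), cid in zip(staypoints.iterrows(), assignments):
        if cid < 0:
            continue
        arr, dep = float(sp["arrival_ms"]), float(sp["departure_ms"])
        total[cid] = total.get(cid, 0.0) + (dep - arr)
        first[cid] = min(first.get(cid, arr), arr)
        d0 = _local_date(int(arr), timezone)
        d1 = _local_date(int(dep), timezone)
        acc = 0.0
        for d in _dates_between(d0, d1):
            w0 = _local_ms(d, lo, timezone)
            w1 = _local_ms(d, hi, timezone)
            acc += _overlap_ms(arr, dep, w0, w1)
        if acc > 0:
            night[cid] = night.get(cid, 0.0) + acc
    if not night:
        return HomeInference(home_cluster_id=None)
    home = max(night, key=lambda c: (night[c], total[c], -first[c]))
    return HomeInference(
        home_cluster_id=int(home),
        night_dwell_min={c: v / 60_000.0 for c, v in night.items()},
    )


def _split_dwell_by_day(
    staypoints: pd.DataFrame, timezone: str
) -> pd.DataFrame:
    """One row per (stay point, local date) with the dwell ms falling on it."""
    rows = []
    for idx, sp in staypoints.iterrows():
        arr, dep = float(sp["arrival_ms"]), float(sp["departure_ms"])
        for d in _dates_between(_local_date(int(arr), timezone), _local_date(int(dep), timezone)):
            day0 = _local_ms(d, 0.0, timezone)
            day1 = _local_ms(d + _dt.timedelta(days=1), 0.0, timezone)
            ms = _overlap_ms(arr, dep, day0, day1)
            if ms > 0 or arr == dep:
                rows.append({"sp_row": idx, "date": d, "dwell_ms": ms})
    return pd.DataFrame(rows, columns=["sp_row", "date", "dwell_ms"])


def home_stay(
    staypoints: pd.DataFrame,
    assignments: np.ndarray,
    home: HomeInference,
    timezone: str = "UTC",
    denominator: str = "dwell",
) -> pd.DataFrame:
    """Per-day home-stay hours and percentage.

    Stay points spanning midnight contribute to each local day
    proportionally, so hours conserve total dwell time.  The percentage
    denominator is total stay-point dwell that day (default) or elapsed clock
    time (24 h) when ``denominator="elapsed"``.  Days with zero dwell in the
    denominator get a missing percentage.
    """
    if denominator not in ("dwell", "elapsed"):
        raise ValueError("denominator must be 'dwell' or 'elapsed'")
    split = _split_dwell_by_day(staypoints, timezone)
    if split.empty:
        return pd.DataFrame(columns=["date", "home_stay_hours", "total_dwell_hours", "home_stay_pct"])
    assignments = np.asarray(assignments)
    cid = pd.Series(assignments, index=staypoints.index)
    split["is_home"] = (
        home.determined and cid.loc[split["sp_row"]].to_numpy() == home.home_cluster_id
    )
    by_day = split.groupby("date").agg(
        total_ms=("dwell_ms", "sum"),
        home_ms=("dwell_ms", lambda s: s[split.loc[s.index, "is_home"]].sum()),
    )
    out = pd.DataFrame(
        {
            "date": by_day.index,
            "home_stay_hours": by_day["home_ms"].to_numpy() / 3_600_000.0,
            "total_dwell_hours": by_day["total_ms"].to_numpy() / 3_600_000.0,
        }
    ).reset_index(drop=True)
    if not home.determined:
        out["home_stay_hours"] = np.nan
        out["home_stay_pct"] = np.nan
        return out
    denom_h = out["total_dwell_hours"] if denominator == "dwell" else 24.0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * out["home_stay_hours"] / denom_h
    out["home_stay_pct"] = np.where(np.asarray(denom_h) > 0, pct, np.nan)
    return out


# ---------------------------------------------------------------------------
# count phenotypes
# ---------------------------------------------------------------------------

def count_phenotypes(
    staypoints: pd.DataFrame,
    trajectories: pd.DataFrame,
    assignments: np.ndarray,
    timezone: str = "UTC",
) -> pd.DataFrame:
    """Per-day counts: places visited, unique places and trajectories.

    A stay point counts once on the local day of its arrival (even when it
    spans midnight); a trajectory on the day of its start.  Unique places are
    distinct cluster ids among that day's stay points.
    """
    assignments = np.asarray(assignments)
    sp_days = [
        _local_date(int(t), timezone) for t in staypoints["arrival_ms"]
    ]
    tr_days = [_local_date(int(t), timezone) for t in trajectories["start_ms"]]
    days = sorted(set(sp_days) | set(tr_days))
    sp_day = pd.Series(sp_days, dtype=object)
    rows = []
    for d in days:
        on_day = np.array([x == d for x in sp_days], dtype=bool)
        rows.append(
            {
                "date": d,
                "places_visited": int(on_day.sum()),
                "unique_places": int(len(set(assignments[on_day]) - {-1})) if on_day.any() else 0,
                "trajectories": int(sum(x == d for x in tr_days)),
            }
        )
    return pd.DataFrame(rows, columns=["date", "places_visited", "unique_places", "trajectories"])


# ---------------------------------------------------------------------------
# normalized entropy
# ---------------------------------------------------------------------------

def dwell_distribution(
    staypoints: pd.DataFrame, assignments: np.ndarray
) -> tuple[np.ndarray, int]:
    """Per-cluster dwell-time proportions ``p_i`` (sum 1) and cluster count N."""
    assignments = np.asarray(assignments)
    dur = staypoints["duration_min"].to_numpy(float)
    keep = (assignments >= 0) & (dur > 0)
    if not keep.any():
        raise ValueError("no positive dwell time to build a distribution from")
    totals = pd.Series(dur[keep]).groupby(pd.Series(assignments[keep])).sum()
    p = totals.to_numpy(float)
    return p / p.sum(), len(p)


def normalized_entropy(p: np.ndarray) -> float:
    """Shannon entropy of dwell proportions over ``ln N``, in [0, 1].

    ``-sum p_i ln p_i / ln N``; defined as 0 for a single place (all time at
    one location) and 1 for a uniform distribution.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p must be a non-empty 1-d array")
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be strictly positive and sum to 1")
    n = len(p)
    if n == 1:
        return 0.0
    h = -float(np.sum(p * np.log(p)))
    return h / float(np.log(n))


# ---------------------------------------------------------------------------
# diurnal movement
# ---------------------------------------------------------------------------

def diurnal_movement(
    staypoints: pd.DataFrame,
    grid_interval_min: float = 10.0,
    period_band_h: tuple[float, float] = (23.5, 24.5),
    max_gap_min: float = 60.0,
    n_freqs: int = 33,
) -> float:
    """Log spectral energy of the location series in a band around 24 h.

    The latitude and longitude series (degrees) are sampled from stay-point
    centroids on a regular grid: inside a stay point the centroid is used;
    after departure the last known centroid is carried for at most
    ``max_gap_min``; longer gaps are left missing.  A least-squares spectral
    estimate (Lomb–Scargle) is evaluated on each mean-centered series at
    ``n_freqs`` periods spanning ``period_band_h`` and the summed power of
    both axes is returned on a natural-log scale, floored at
    ``ln(DIURNAL_ENERGY_FLOOR)``.  Requires at least 3 days of data
    (otherwise NaN).
    """
    if staypoints.empty:
        return float("nan")
    sps = staypoints.sort_values("arrival_ms")
    arr = sps["arrival_ms"].to_numpy(float)
    dep = sps["departure_ms"].to_numpy(float)
    lat = sps["centroid_lat"].to_numpy(float)
    lon = sps["centroid_lon"].to_numpy(float)
    span_days = (dep[-1] - arr[0]) / 86_400_000.0
    if span_days < 3.0:
        return float("nan")

    step = grid_interval_min * 60_000.0
    grid = np.arange(arr[0], dep[-1] + 1, step)
    idx = np.searchsorted(arr, grid, side="right") - 1
    idx = np.clip(idx, 0, len(arr) - 1)
    age_ms = grid - dep[idx]
    known = (grid >= arr[idx]) & (age_ms <= max_gap_min * 60_000.0)
    if known.sum() < 8:
        return float("nan")
    t_sec = (grid[known] - grid[0]) / 1000.0
    y_lat = lat[idx[known]]
    y_lon = lon[idx[known]]

    lo_h, hi_h = period_band_h
    if hi_h < lo_h:
        raise ValueError("period_band_h must be increasing")
    periods = np.array([lo_h]) if hi_h == lo_h else np.linspace(lo_h, hi_h, n_freqs)
    omegas = 2.0 * np.pi / (periods * 3600.0)
    energy = 0.0
    for y in (y_lat, y_lon):
        yc = y - y.mean()
        if np.any(yc != 0):
            energy += float(np.sum(lombscargle(t_sec, yc, omegas)))
    return float(np.log(max(energy, DIURNAL_ENERGY_FLOOR)))


# ---------------------------------------------------------------------------
# duration adjustment of count phenotypes
# ---------------------------------------------------------------------------

def adjust_counts_for_duration(
    cohort: pd.DataFrame,
    count_cols: list[str],
    n_days_col: str = "n_days_observed",
) -> pd.DataFrame:
    """Adjust count phenotypes for observation length across a cohort.

    Each count is regressed on the number of observed days (ordinary least
    squares across subjects); the adjusted value is the residual plus the
    grand mean, keeping the scale interpretable.  The residuals are exactly
    orthogonal to the duration regressor.  With identical ``n_days`` for all
    subjects the adjustment reduces to the identity (a warning is issued).
    """
    import statsmodels.api as sm

    if len(cohort) < 3:
        raise ValueError("duration adjustment needs >= 3 subjects")
    out = cohort.copy()
    ndays = cohort[n_days_col].to_numpy(float)
    constant_duration = np.ptp(ndays) == 0
    if constant_duration:
        warnings.warn("n_days_observed is constant; duration adjustment is a no-op")
    X = sm.add_constant(ndays)
    for col in count_cols:
        y = cohort[col].to_numpy(float)
        if constant_duration:
            out[f"{col}_adj"] = y
            continue
        fit = sm.OLS(y, X).fit()
        out[f"{col}_adj"] = fit.resid + y.mean()
    return out


# ---------------------------------------------------------------------------
# assembled phenotype table
# ---------------------------------------------------------------------------

def phenotype_table(
    subject_id: str,
    staypoints: pd.DataFrame,
    trajectories: pd.DataFrame,
    assignments: np.ndarray,
    timezone: str = "UTC",
    night_window: tuple[float, float] = (0.0, 6.0),
    homestay_denominator: str = "dwell",
    grid_interval_min: float = 10.0,
    period_band_h: tuple[float, float] = (23.5, 24.5),
    max_gap_min: float = 60.0,
    observed_days: set | None = None,
) -> pd.DataFrame:
    """Per-day phenotype rows plus one whole-window summary row.

    The summary row (``window = "all"``) carries window totals for the count
    phenotypes together with their per-observed-day rates, day-mean home
    stay, window-level normalized entropy and the diurnal-movement score.
    """
    home = infer_home(staypoints, assignments, timezone, night_window)
    hs = home_stay(staypoints, assignments, home, timezone, homestay_denominator)
    counts = count_phenotypes(staypoints, trajectories, assignments, timezone)

    merged = counts.merge(hs, on="date", how="outer").sort_values("date")
    merged = merged.reset_index(drop=True)
    for c in ("places_visited", "unique_places", "trajectories"):
        merged[c] = merged[c].fillna(0).astype(int)

    assignments = np.asarray(assignments)
    split = _split_dwell_by_day(staypoints, timezone)
    ent_by_day = {}
    if not split.empty:
        cid = pd.Series(assignments, index=staypoints.index)
        split["cluster"] = cid.loc[split["sp_row"]].to_numpy()
        for d, grp in split.groupby("date"):
            tot = grp.groupby("cluster")["dwell_ms"].sum()
            tot = tot[tot > 0]
            if len(tot):
                ent_by_day[d] = normalized_entropy(tot.to_numpy() / tot.sum())
    merged["normalized_entropy"] = [ent_by_day.get(d, np.nan) for d in merged["date"]]
    merged["diurnal_movement"] = np.nan

    if observed_days is None:
        observed_days = set(merged["date"])
    n_days = len(observed_days)

    if len(staypoints):
        p_all, _ = dwell_distribution(staypoints, assignments)
        ent_all = normalized_entropy(p_all)
    else:
        ent_all = np.nan
    summary = {
        "date": "all",
        "places_visited": int(len(staypoints)),
        "unique_places": int(len(set(assignments[assignments >= 0]))),
        "trajectories": int(len(trajectories)),
        "home_stay_hours": float(merged["home_stay_hours"].mean()),
        "total_dwell_hours": float(merged["total_dwell_hours"].sum()),
        "home_stay_pct": float(merged["home_stay_pct"].mean()),
        "normalized_entropy": ent_all,
        "diurnal_movement": diurnal_movement(
            staypoints, grid_interval_min, period_band_h, max_gap_min
        ),
        "places_visited_per_day": len(staypoints) / n_days if n_days else np.nan,
        "unique_places_per_day": float(merged["unique_places"].mean()),
        "trajectories_per_day": len(trajectories) / n_days if n_days else np.nan,
    }
    out = pd.concat([merged, pd.DataFrame([summary])], ignore_index=True)
    out.insert(0, "subject_id", subject_id)
    out["n_days_observed"] = n_days
    out["home_cluster_id"] = home.home_cluster_id if home.determined else -1
    return out
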