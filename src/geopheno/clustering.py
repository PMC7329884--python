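"""Recurrent-place clustering of stay points.

Stay points made at the same real-world place on different occasions are
merged into place clusters with density-based clustering (DBSCAN) over the
stay-point centroids, using the haversine metric and a neighborhood radius
``epsilon`` in meters.  With ``min_points = 1`` every stay point is assigned
to a cluster (singleton visits count as places); a place is *recurrent* when
it was visited at least twice.  The published operating point is
``epsilon`` = 150 m, tuned by maximizing the Adjusted Rand Index against
user-confirmed place labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .staypoints import EARTH_RADIUS_M


@dataclass(frozen=True)
class ClusteringParams:
    epsilon_m: float = 150.0
    min_points: int = 1

    def __post_init__(self) -> None:
        if self.epsilon_m <= 0:
            raise ValueError("epsilon_m must be > 0")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


def cluster_staypoints(
    staypoints: pd.DataFrame, params: ClusteringParams | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Cluster stay-point centroids into places.

    Parameters
    ----------
    staypoints:
        Stay-point table with ``centroid_lat``, ``centroid_lon``,
        ``arrival_ms``, ``departure_ms`` and ``duration_min`` columns.
    params:
        Neighborhood radius and core-point minimum.

    Returns
    -------
    assignments:
        Cluster id per stay point (row-aligned).  Ids are canonical: numbered
        0, 1, ... by the arrival time of each cluster's earliest visit, so
        memberships and ids are invariant to input order.  With the default
        ``min_points = 1`` there are no noise points; larger values may leave
        noise stay points, which keep id ``-1``.
    clusters:
        One row per cluster: ``cluster_id``, ``centroid_lat``/``lon`` (mean
        of member centroids), ``n_visits``, ``total_dwell_min``,
        ``first_arrival_ms`` and ``is_recurrent`` (``n_visits >= 2``).
    """
    params = params or ClusteringParams()
    if staypoints.empty:
        raise ValueError("cluster_staypoints requires at least one stay point")
    coords = np.radians(staypoints[["centroid_lat", "centroid_lon"]].to_numpy(float))
    raw = DBSCAN(
        eps=params.epsilon_m / EARTH_RADIUS_M,
        min_samples=params.min_points,
        metric="haversine",
        algorithm="ball_tree",
    ).fit_predict(coords)

    arrivals = staypoints["arrival_ms"].to_numpy()
    # canonicalize: order clusters by their earliest member arrival
    order = sorted(
        (lbl for lbl in np.unique(raw) if lbl != -1),
        key=lambda lbl: arrivals[raw == lbl].min(),
    )
    remap = {lbl: k for k, lbl in enumerate(order)}
    assignments = np.array([remap.get(lbl, -1) for lbl in raw], dtype=int)

    rows = []
    for cid in range(len(order)):
        member = assignments == cid
        rows.append(
            {
                "cluster_id": cid,
                "centroid_lat": float(staypoints.loc[member, "centroid_lat"].mean()),
                "centroid_lon": float(staypoints.loc[member, "centroid_lon"].mean()),
                "n_visits": int(member.sum()),
                "total_dwell_min": float(staypoints.loc[member, "duration_min"].sum()),
                "first_arrival_ms": int(arrivals[member].min()),
            }
        )
    clusters = pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "centroid_lat",
            "centroid_lon",
            "n_visits",
            "total_dwell_min",
            "first_arrival_ms",
        ],
    )
    clusters["is_recurrent"] = clusters["n_visits"] >= 2
    return assignments, clusters


def tune_epsilon(
    labelled: dict[str, tuple[pd.DataFrame, np.ndarray]],
    grid,
    min_points: int = 1,
) -> tuple[pd.DataFrame, float]:
    """Grid-search the clustering radius against ground-truth place labels.

    ``labelled`` maps subject id to ``(staypoints, true_place_labels)``.  For
    each ``epsilon`` in ``grid`` every subject's stay points are clustered and
    scored with the Adjusted Rand Index against the subject's true labels;
    the per-``epsilon`` mean and standard error of the mean across subjects
    are returned together with the argmax ``epsilon``.  Subjects with fewer
    than two stay points are excluded with a warning.
    """
    from .evaluate import adjusted_rand_index

    grid = list(grid)
    if not grid:
        raise ValueError("epsilon grid must be non-empty")
    usable = {}
    for sid, (sps, labels) in labelled.items():
        if len(sps) < 2:
            warnings.warn(f"subject {sid!r} has < 2 stay points; excluded from tuning")
            continue
        usable[sid] = (sps, np.asarray(labels))
    if len(usable) < 2:
        raise ValueError("tune_epsilon needs >= 2 subjects with ground-truth labels")

    rows = []
    for eps in grid:
        aris = []
        for sps, labels in usable.values():
            assign, _ = cluster_staypoints(
                sps, ClusteringParams(epsilon_m=float(eps), min_points=min_points)
            )
            aris.append(adjusted_rand_index(labels, assign))
        aris = np.asarray(aris)
        se = aris.std(ddof=1) / np.sqrt(len(aris)) if len(aris) > 1 else 0.0
        rows.append(
            {
                "epsilon_m": float(eps),
                "mean_ari": float(aris.mean()),
                "se_ari": float(se),
                "n_subjects": len(aris),
            }
        )
    table = pd.DataFrame(rows)
    best = float(table.loc[table["mean_ari"].idxmax(), "epsilon_m"])
    return table, best


def clustering_accuracy(
    assignments: np.ndarray,
    true_labels: np.ndarray,
    arrivals: np.ndarray | None = None,
) -> float:
    """Percentage of stay points placed in a cluster of their own true place.

    Each cluster is mapped to the majority ground-truth label among its
    members (ties broken toward the label visited earliest within the
    cluster); a stay point is correct when its own true label equals its
    cluster's majority label.
    """
    assignments = np.asarray(assignments)
    true_labels = np.asarray(true_labels)
    if assignments.shape != true_labels.shape:
        raise ValueError("assignments and true_labels must be aligned")
    n = len(assignments)
    if n == 0:
        raise ValueError("no stay points")
    if arrivals is None:
        arrivals = np.arange(n)
    correct = 0
    for cid in np.unique(assignments):
        member = assignments == cid
        labels_here = true_labels[member]
        counts: dict = {}
        first_seen: dict = {}
        for lbl, arr in zip(labels_here, np.asarray(arrivals)[member]):
            counts[lbl] = counts.get(lbl, 0) + 1
            first_seen[lbl] = min(first_seen.get(lbl, arr), arr)
        majority = max(counts, key=lambda l: (counts[l], -first_seen[l]))
        correct += int((labels_here == majority).sum())
    return 100.0 * correct / n
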