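"""Independent brute-force oracles used by the test suite.

Each function re-derives a pipeline quantity by the most literal method
available (window enumeration, pair counting, transitive closure,
least-squares fits) so the production implementations can be checked against
something that shares no code with them.
"""

from math import comb

import numpy as np

from geopheno.staypoints import haversine_m


def brute_force_staypoints(lat, lon, ts, theta_d_m, theta_t_ms):
    """Greedy left-to-right selection over all contiguous fix windows.

    A window (i, j) is valid when every member fix lies within ``theta_d_m``
    of fix i and its time span is at least ``theta_t_ms``.  Scanning anchors
    left to right, the maximal valid window at the current anchor is taken
    and the anchor jumps past it; otherwise the anchor advances by one.
    Returns inclusive (start, end) index pairs.
    """
    n = len(ts)
    out = []
    i = 0
    while i < n:
        best = None
        for j in range(i, n):
            if haversine_m(lat[i], lon[i], lat[j], lon[j]) > theta_d_m:
                break
            if ts[j] - ts[i] >= theta_t_ms:
                best = (i, j)
        if best is not None:
            out.append(best)
            i = best[1] + 1
        else:
            i += 1
    return out


def pair_counting_ari(a, b):
    """Adjusted Rand Index from the raw contingency table.

    Pair-counting with the expected-index correction:
    ARI = (sum_ij C(n_ij,2) - E) / (max - E), with
    E = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2) and
    max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.
    """
    a = list(a)
    b = list(b)
    n = len(a)
    cells: dict = {}
    for x, y in zip(a, b):
        cells[(x, y)] = cells.get((x, y), 0) + 1
    row: dict = {}
    col: dict = {}
    for x in a:
        row[x] = row.get(x, 0) + 1
    for y in b:
        col[y] = col.get(y, 0) + 1
    s_ij = sum(comb(v, 2) for v in cells.values())
    s_a = sum(comb(v, 2) for v in row.values())
    s_b = sum(comb(v, 2) for v in col.values())
    total = comb(n, 2)
    expected = s_a * s_b / total
    maximum = (s_a + s_b) / 2.0
    if maximum == expected:  # both partitions degenerate: identical by pairs
        return 1.0
    return (s_ij - expected) / (maximum - expected)


def transitive_closure_clusters(lats, lons, eps_m):
    """Connected components of the eps-neighborhood graph (union-find).

    With a core-point minimum of 1, density-based clustering reduces to the
    transitive closure of "within eps of each other".
    """
    n = len(lats)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if haversine_m(lats[i], lons[i], lats[j], lons[j]) <= eps_m:
                parent[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


def sinusoid_fit_power(t_sec, y, period_h):
    """Explained sum of squares / 2 of a least-squares sinusoid at one period.

    Fits ``y - mean(y) ~ a cos(w t) + b sin(w t)`` by ordinary least squares;
    half the explained sum of squares is the classical definition of the
    least-squares spectral power at that frequency.
    """
    w = 2.0 * np.pi / (period_h * 3600.0)
    yc = y - y.mean()
    X = np.column_stack([np.cos(w * t_sec), np.sin(w * t_sec)])
    coef, *_ = np.linalg.lstsq(X, yc, rcond=None)
    fitted = X @ coef
    return float(np.sum(fitted**2)) / 2.0


def set_partitions(items):
    """All partitions of a small item list (for exhaustive ARI checks)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield [[first]] + part


def partition_to_labels(partition, items):
    lbl = {}
    for k, block in enumerate(partition):
        for x in block:
            lbl[x] = k
    return [lbl[x] for x in items]
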