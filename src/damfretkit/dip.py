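"""Hartigan & Hartigan's dip test of unimodality.

The dip statistic of a sample is the smallest sup-norm distance between the
empirical CDF and any unimodal CDF (convex below its mode, concave above,
with an atom permitted at the mode).  It is computed here by the classical
modal-interval iteration: repeatedly form the greatest convex minorant (GCM)
and least concave majorant (LCM) of the empirical CDF on the current modal
interval, shrink the interval to where the two hulls are furthest apart, and
accumulate the deviations of the CDF from the hulls on the abandoned flanks.

P-values are calibrated by Monte Carlo against samples of the same size from
the uniform distribution (the asymptotically least-favourable unimodal null).
Null distributions are memoised per (n, n_null, seed) so that screening many
wells of equal size costs a single null simulation.
"""

from __future__ import annotations

import functools

import numpy as np

__all__ = ["dip_statistic", "dip_pvalue", "dip_test"]


def _lower_hull(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    """Indices of the lower convex hull vertices of (xs, ys), xs increasing."""
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # drop b if it lies on or above chord a->i
            if (xs[i] - xs[a]) * (ys[b] - ys[a]) >= (ys[i] - ys[a]) * (xs[b] - xs[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _upper_hull(xs: np.ndarray, ys: np.ndarray) -> list[int]:
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (xs[i] - xs[a]) * (ys[b] - ys[a]) <= (ys[i] - ys[a]) * (xs[b] - xs[a]):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _interp(xs: np.ndarray, ys: np.ndarray, hull: list[int], xq: float) -> float:
    """Piecewise-linear hull value at xq (xq within hull span)."""
    hx = xs[hull]
    j = int(np.searchsorted(hx, xq, side="right")) - 1
    if j < 0:
        return float(ys[hull[0]])
    if j >= len(hull) - 1:
        return float(ys[hull[-1]])
    a, b = hull[j], hull[j + 1]
    if xs[b] == xs[a]:
        return float(ys[a])
    t = (xq - xs[a]) / (xs[b] - xs[a])
    return float(ys[a] + t * (ys[b] - ys[a]))


def dip_statistic(values) -> float:
    """Dip statistic of a 1-D sample.

    Returns a value in [1/(2n), 0.25] for n >= 2 distinct-valued samples;
    a sample with all values equal has dip 0 (a point mass fits exactly).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("dip_statistic requires a non-empty sample")
    if n == 1 or x[0] == x[-1]:
        return 0.0

    # collapse ties: distinct values u with bottom counts lo (obs strictly
    # below u) and top counts hi (obs at or below u)
    u, counts = np.unique(x, return_counts=True)
    hi = np.cumsum(counts).astype(float)
    lo = hi - counts

    k = u.size
    lo_i, hi_i = 0, k - 1
    big_d = 1.0  # counts; enforces dip >= 1/(2n)

    while True:
        if u[hi_i] <= u[lo_i]:
            break
        sl = slice(lo_i, hi_i + 1)
        xs = u[sl]
        gcm = _lower_hull(xs, lo[sl])  # minorant touches jump bottoms
        lcm = _upper_hull(xs, hi[sl])  # majorant touches jump tops

        # largest vertical gap between the hull curves, checked at vertices
        d = -np.inf
        arg_x = xs[0]
        for t in gcm:
            gap = _interp(xs, hi[sl], lcm, xs[t]) - lo[sl][t]
            if gap > d:
                d, arg_x, side = gap, xs[t], "g"
        for s in lcm:
            gap = hi[sl][s] - _interp(xs, lo[sl], gcm, xs[s])
            if gap > d:
                d, arg_x, side = gap, xs[s], "l"

        if d <= big_d:
            break

        # new modal interval: nearest GCM touch at/left of the gap, nearest
        # LCM touch at/right of it
        gx = xs[gcm]
        lx = xs[lcm]
        gi = int(np.searchsorted(gx, arg_x, side="right")) - 1
        li = int(np.searchsorted(lx, arg_x, side="left"))
        gi = max(gi, 0)
        li = min(li, len(lcm) - 1)
        new_lo = lo_i + gcm[gi]
        new_hi = lo_i + lcm[li]
        if new_lo == lo_i and new_hi == hi_i:
            big_d = max(big_d, d)
            break

        # deviations of the empirical CDF from the hulls on abandoned flanks;
        # the boundary value itself belongs to the modal interval (its jump
        # can be absorbed by an atom at the mode), so it is excluded
        dl = 0.0
        for j in range(lo_i, new_lo):
            dl = max(dl, hi[j] - _interp(xs, lo[sl], gcm, u[j]))
        du = 0.0
        for j in range(new_hi + 1, hi_i + 1):
            du = max(du, _interp(xs, hi[sl], lcm, u[j]) - lo[j])
        big_d = max(big_d, dl, du)
        lo_i, hi_i = new_lo, new_hi
        if lo_i >= hi_i:
            break

    return float(big_d) / (2.0 * n)


@functools.lru_cache(maxsize=64)
def _null_dips(n: int, n_null: int, seed: int) -> tuple[float, ...]:
    rng = np.random.default_rng(seed)
    return tuple(
        sorted(dip_statistic(rng.uniform(size=n)) for _ in range(n_null))
    )


def dip_pvalue(dip: float, n: int, n_null: int = 2000, rng_seed: int = 0) -> float:
    """Monte-Carlo p-value of a dip statistic against the uniform null.

    P = (1 + #{null dips >= dip}) / (1 + n_null); add-one keeps the estimate
    strictly inside (0, 1).
    """
    null = np.asarray(_null_dips(n, n_null, rng_seed))
    n_ge = null.size - int(np.searchsorted(null, dip, side="left"))
    return (1.0 + n_ge) / (1.0 + len(null))


def dip_test(values, n_null: int = 2000, rng_seed: int = 0) -> tuple[float, float]:
    """Dip statistic and Monte-Carlo p-value for a sample.

    Requires n >= 4 observations (below that the statistic is uninformative).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError(f"dip test requires n >= 4 observations, got {x.size}")
    dip = dip_statistic(x)
    return dip, dip_pvalue(dip, x.size, n_null=n_null, rng_seed=rng_seed)
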