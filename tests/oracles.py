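"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the dip oracle is a
linear program over unimodal CDFs evaluated mode-by-mode; the betweenness
oracle counts shortest paths by BFS layers and the path-product identity;
the intermeans oracle scans all 256 candidate thresholds.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_lp(x) -> float:
    """min over unimodal G of sup|F_hat - G| by LP, exact for any sample.

    Restricting the mode to the distinct data values (with an atom allowed at
    the mode) loses nothing: a mode strictly inside a gap is feasible exactly
    when one of the two adjacent knot-mode programs is.
    """
    x = np.sort(np.asarray(x, float))
    n = len(x)
    u, counts = np.unique(x, return_counts=True)
    C = np.cumsum(counts) / n
    Cm = np.concatenate([[0.0], C[:-1]])
    K = len(u)
    if K == 1:
        return 0.0
    best = np.inf
    for m in range(K):
        nv = K + 2  # d, G_0..G_{K-1}, G_m^-
        iGm = K + 1
        A_ub, b_ub = [], []

        def add(coefs, b):
            r = np.zeros(nv)
            for j, c in coefs:
                r[j] += c
            A_ub.append(r)
            b_ub.append(b)

        def iG(i):
            return 1 + i

        def val_left(i):
            return iGm if i == m else iG(i)

        for i in range(K):
            if i == m:
                add([(iG(i), 1), (0, -1)], C[i])
                add([(iG(i), -1), (0, -1)], -C[i])
                add([(iGm, 1), (0, -1)], Cm[i])
                add([(iGm, -1), (0, -1)], -Cm[i])
            else:
                add([(iG(i), 1), (0, -1)], Cm[i])
                add([(iG(i), -1), (0, -1)], -C[i])
        seq = [iG(i) for i in range(m)] + [iGm, iG(m)] + [iG(i) for i in range(m + 1, K)]
        for a, b in zip(seq[:-1], seq[1:]):
            add([(a, 1), (b, -1)], 0.0)
        for i in range(1, m):  # convex left branch
            du1, du2 = u[i] - u[i - 1], u[i + 1] - u[i]
            add([(val_left(i), du1 + du2), (val_left(i - 1), -du2), (val_left(i + 1), -du1)], 0.0)
        for i in range(m + 1, K - 1):  # concave right branch
            du1, du2 = u[i] - u[i - 1], u[i + 1] - u[i]
            add([(iG(i), -(du1 + du2)), (iG(i - 1), du2), (iG(i + 1), du1)], 0.0)
        res = linprog(
            np.eye(nv)[0],
            A_ub=np.array(A_ub),
            b_ub=np.array(b_ub),
            bounds=[(0, None)] + [(0, 1)] * (K + 1),
            method="highs",
        )
        if res.status == 0 and res.fun < best:
            best = res.fun
    return float(best)


def betweenness_brute(nodes, edges) -> dict:
    """Raw betweenness by BFS distances and the sigma_sv * sigma_vt identity."""
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def bfs(src):
        dist = {src: 0}
        sigma = {src: 1}
        frontier = [src]
        while frontier:
            nxt = []
            for v in frontier:
                for w in adj[v]:
                    if w not in dist:
                        dist[w] = dist[v] + 1
                        sigma[w] = 0
                        nxt.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
            frontier = nxt
        return dist, sigma

    info = {v: bfs(v) for v in nodes}
    btw = dict.fromkeys(nodes, 0.0)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            ds, ss = info[s]
            if t not in ds:
                continue
            dt, st = info[t]
            total = ss[t]
            for v in nodes:
                if v in (s, t) or v not in ds or v not in dt:
                    continue
                if ds[v] + dt[v] == ds[t]:
                    btw[v] += ss[v] * st[v] / total
    return btw


def intermeans_crossing(hist) -> int:
    """Brute-force intermeans threshold over all 256 candidates: the largest
    bin t where the running midpoint (mean_below(t) + mean_above(t)) / 2
    still lies at or above t (the crossing of the intermeans condition)."""
    hist = np.asarray(hist, float)
    idx = np.arange(len(hist))
    best = None
    for t in range(len(hist) - 1):
        below, above = hist[: t + 1], hist[t + 1 :]
        if below.sum() == 0 or above.sum() == 0:
            continue
        mid = ((idx[: t + 1] * below).sum() / below.sum()
               + (idx[t + 1 :] * above).sum() / above.sum()) / 2.0
        if mid >= t:
            best = t
    return best


def mann_whitney_u_exact(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group labelings."""
    from itertools import combinations

    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)
        return u

    u_obs = sum((a > b) + 0.5 * (a == b) for a in x for b in y)
    mu = n1 * len(y) / 2.0
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(set(idx)) - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return u_obs, count / total
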