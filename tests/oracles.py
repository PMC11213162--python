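"""Independent brute-force oracles used to verify the vectorized library code.

Everything here is deliberately naive (explicit loops, textbook formulas) and
shares no code path with the implementation under test.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np
from scipy import stats


def weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Scalar weighted Pearson correlation, explicit formula."""
    w = w / w.sum()
    mx = float(np.sum(w * x))
    my = float(np.sum(w * y))
    cov = float(np.sum(w * (x - mx) * (y - my)))
    vx = float(np.sum(w * (x - mx) ** 2))
    vy = float(np.sum(w * (y - my) ** 2))
    return cov / np.sqrt(vx * vy)


def sliding_window_median_fc(data: np.ndarray, weights: np.ndarray,
                             shift: int = 1) -> np.ndarray:
    """Explicit loop over windows and ROI pairs; median aggregation."""
    m, t = data.shape
    width = len(weights)
    starts = list(range(0, t - width + 1, shift))
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            vals = [weighted_corr(data[i, s:s + width], data[j, s:s + width],
                                  weights) for s in starts]
            out[i, j] = out[j, i] = np.median(vals)
    return out


def dijkstra_all_pairs(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by per-source Dijkstra on a dense length
    matrix (0 = absent edge)."""
    m = lengths.shape[0]
    dist = np.full((m, m), np.inf)
    for src in range(m):
        dist[src, src] = 0.0
        heap = [(0.0, src)]
        seen = set()
        while heap:
            d, u = heapq.heappop(heap)
            if u in seen:
                continue
            seen.add(u)
            for v in range(m):
                if lengths[u, v] > 0 and d + lengths[u, v] < dist[src, v]:
                    dist[src, v] = d + lengths[u, v]
                    heapq.heappush(heap, (dist[src, v], v))
    return dist


def path_metrics(fc: np.ndarray) -> dict[str, float]:
    """GE/ME/Radius/Diameter from Dijkstra on lengths 1/w (positive edges)."""
    w = np.where(fc > 0, fc, 0.0)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    dist = dijkstra_all_pairs(lengths)
    m = dist.shape[0]
    off = ~np.eye(m, dtype=bool)
    ge = float(np.mean([1.0 / dist[i, j] if np.isfinite(dist[i, j]) else 0.0
                        for i in range(m) for j in range(m) if i != j]))
    ecc = dist.max(axis=1)
    if np.all(np.isfinite(ecc)):
        return {"ge": ge, "me": float(ecc.mean()), "radius": float(ecc.min()),
                "diameter": float(ecc.max())}
    return {"ge": ge, "me": np.nan, "radius": np.nan, "diameter": np.nan}


def triad_census(fc: np.ndarray) -> dict[str, float]:
    """Exhaustive triple loop over ROI triples."""
    m = fc.shape[0]
    counts = [0, 0, 0, 0]
    total = 0
    energy_sum = 0.0
    for x, y, z in itertools.combinations(range(m), 3):
        wxy, wxz, wyz = fc[x, y], fc[x, z], fc[y, z]
        if wxy == 0 or wxz == 0 or wyz == 0:
            continue
        total += 1
        counts[sum(v > 0 for v in (wxy, wxz, wyz))] += 1
        energy_sum += wxy * wxz * wyz
    if total == 0:
        return {k: np.nan for k in ("t0", "t1", "t2", "t3", "un")}
    return {"t0": counts[0], "t1": counts[1], "t2": counts[2], "t3": counts[3],
            "un": -energy_sum / total}


def tmh(fc: np.ndarray) -> dict[str, float]:
    """Two-pass loop for positive and negative hub-tendency indices."""
    m = fc.shape[0]
    out = {}
    for key, keep in (("tmh_p", lambda v: v > 0), ("tmh_n", lambda v: v < 0)):
        degrees = []
        for i in range(m):
            d = sum(abs(fc[i, j]) for j in range(m) if j != i and keep(fc[i, j]))
            degrees.append(d)
        total = sum(degrees)
        out[key] = (sum(d * d for d in degrees) / total) if total > 0 else np.nan
    return out


def kruskal_mst_edges(fc: np.ndarray) -> set[frozenset[int]]:
    """Kruskal on distance 1 - w over positive edges; returns the edge set."""
    m = fc.shape[0]
    edges = sorted((1.0 - fc[i, j], i, j)
                   for i in range(m) for j in range(i + 1, m) if fc[i, j] > 0)
    parent = list(range(m))

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    chosen = set()
    for d, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            chosen.add(frozenset((i, j)))
    return chosen


def clustering_geometric(fc: np.ndarray) -> float:
    """Mean geometric-mean weighted clustering coefficient, triple loop."""
    w = np.where(fc > 0, fc, 0.0)
    m = w.shape[0]
    cs = []
    for i in range(m):
        neighbors = [j for j in range(m) if w[i, j] > 0]
        k = len(neighbors)
        if k < 2:
            cs.append(0.0)
            continue
        s = 0.0
        for j in neighbors:
            for h in neighbors:
                if j != h:
                    s += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        cs.append(s / (k * (k - 1)))
    return float(np.mean(cs))


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p, tie-corrected normal approximation with
    continuity correction, written from the textbook formulas."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u = max(u1, n1 * n2 - u1)
    mu = n1 * n2 / 2
    _, counts = np.unique(pooled, return_counts=True)
    tie = float((counts ** 3 - counts).sum())
    n = n1 + n2
    sd = np.sqrt(n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1))))
    if sd == 0:
        return 1.0
    z = (u - mu - 0.5) / sd
    return min(1.0, 2 * stats.norm.sf(z))
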