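"""Independent brute-force oracles used by the test suite.

Everything here is computed from first principles (Floyd-Warshall over the
dense adjacency, explicit triple loops for triangles, explicit rank sums),
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np

TOL = 1e-9


def distance_matrix(A: np.ndarray, weighted: bool) -> np.ndarray:
    """All-pairs shortest path lengths by Floyd-Warshall; inf if unreachable."""
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if A[i, j] > 0:
                D[i, j] = 1.0 / A[i, j] if weighted else 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def cpl_oracle(A: np.ndarray, weighted: bool) -> float:
    D = distance_matrix(A, weighted)
    n = A.shape[0]
    vals = [D[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals)) if vals else np.inf

def eglob_oracle(A: np.ndarray, weighted: bool) -> float:
    D = distance_matrix(A, weighted)
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1)) if n > 1 else 0.0


def ereg_oracle(A: np.ndarray, weighted: bool) -> np.ndarray:
    D = distance_matrix(A, weighted)
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                out[i] += 1.0 / D[i, j]
    return out / (n - 1) if n > 1 else out


def clustering_oracle(A: np.ndarray, weighted: bool) -> np.ndarray:
    """Nodal clustering: triangle counting; Onnela geometric mean if weighted."""
    n = A.shape[0]
    out = np.zeros(n)
    W = A / A.max() if (weighted and A.max() > 0) else (A > 0).astype(float)
    for i in range(n):
        neigh = [j for j in range(n) if A[i, j] > 0]
        k = len(neigh)
        if k < 2:
            continue
        tri = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = neigh[a], neigh[b]
                if A[j, h] > 0:
                    tri += (W[i, j] * W[i, h] * W[j, h]) ** (1.0 / 3.0)
        out[i] = 2.0 * tri / (k * (k - 1))
    return out


def local_efficiency_oracle(A: np.ndarray, weighted: bool) -> np.ndarray:
    n = A.shape[0]
    out = np.zeros(n)
    for i in range(n):
        neigh = [j for j in range(n) if A[i, j] > 0]
        if len(neigh) < 2:
            continue
        sub = A[np.ix_(neigh, neigh)]
        out[i] = eglob_oracle(sub, weighted)
    return out


def betweenness_oracle(A: np.ndarray, weighted: bool) -> np.ndarray:
    """Betweenness as the fraction of shortest paths through each node.

    Shortest-path counts from Floyd-Warshall distances: sigma(s,t) sums
    counts over intermediate predecessors; a node v lies on an s-t shortest
    path iff d(s,v) + d(v,t) = d(s,t).
    """
    n = A.shape[0]
    D = distance_matrix(A, weighted)
    # count shortest paths by DP over nodes sorted by distance from s
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(D[s])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or not np.isfinite(D[s, t]):
                continue
            cnt = 0.0
            for u in range(n):
                if A[u, t] > 0:
                    du = 1.0 / A[u, t] if weighted else 1.0
                    if abs(D[s, u] + du - D[s, t]) < TOL:
                        cnt += sigma[s, u]
            sigma[s, t] = cnt
    bc = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if s >= t or s == v or t == v:
                    continue
                if not np.isfinite(D[s, t]) or sigma[s, t] == 0:
                    continue
                if abs(D[s, v] + D[v, t] - D[s, t]) < TOL:
                    bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def kendalls_w_oracle(series: np.ndarray) -> float:
    """Kendall's W from explicit average ranks and rank sums."""
    series = np.asarray(series, dtype=float)
    m, n = series.shape
    ranks = np.zeros_like(series)
    for row in range(m):
        vals = series[row]
        for t in range(n):
            less = np.sum(vals < vals[t])
            equal = np.sum(vals == vals[t])
            ranks[row, t] = less + (equal + 1) / 2.0
    rank_sums = ranks.sum(axis=0)
    S = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    return 12.0 * S / (m**2 * (n**3 - n))


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    cov = (x * y).sum() / n - x.mean() * y.mean()
    vx = (x**2).sum() / n - x.mean() ** 2
    vy = (y**2).sum() / n - y.mean() ** 2
    return cov / np.sqrt(vx * vy)


def global_connectivity_oracle(series: np.ndarray, r_max: float) -> np.ndarray:
    """Double-loop mean Fisher-z correlation per voxel (series: n_vox x T)."""
    n = series.shape[0]
    out = np.zeros(n)
    for v in range(n):
        total = 0.0
        for u in range(n):
            if u == v:
                continue
            r = pearson_oracle(series[v], series[u])
            total += np.arctanh(np.clip(r, -r_max, r_max))
        out[v] = total / (n - 1)
    return out
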