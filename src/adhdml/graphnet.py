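"""Brain-graph construction and graph-theoretical metrics.

Connectivity matrices are proportionally thresholded (retaining a fixed
fraction of each subject's strongest positive connections) into weighted or
binarized graphs. Eight global metrics (clustering coefficient, local
efficiency, characteristic path length, global efficiency, gamma, lambda,
small-worldness sigma and modularity Q) and five nodal metrics (strength,
clustering, local efficiency, regional efficiency, betweenness centrality)
are computed at several sparsity levels and averaged, with gamma/lambda
normalized by an ensemble of degree-preserving random rewirings.

Conventions: weighted path distances are d_ij = 1/w_ij; weighted clustering
uses the Onnela geometric-mean formulation; betweenness is normalized by
(R-1)(R-2)/2 so it is a fraction of shortest paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .funcfeat import ConnectivityMatrix

__all__ = [
    "SPARSITY_LEVELS",
    "BrainGraph",
    "GlobalMetrics",
    "threshold_proportional",
    "global_graph_metrics",
    "nodal_graph_metrics",
    "normalized_metrics",
    "metrics_across_sparsities",
]

SPARSITY_LEVELS = (0.10, 0.15, 0.20, 0.25, 0.30)

GLOBAL_METRIC_NAMES = ("CC", "E_loc", "CPL", "E_glob", "gamma", "lambda", "sigma", "Q")
NODAL_METRIC_NAMES = ("strength", "degree", "CC", "E_loc", "E_reg", "BC")


@dataclass
class BrainGraph:
    """Thresholded, undirected brain graph.

    ``adjacency`` is symmetric, nonnegative, zero-diagonal; in binarized
    mode retained edges have weight 1.
    """

    adjacency: np.ndarray
    roi_names: list[str]
    mode: str = "weighted"
    sparsity: float = np.nan

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if (A < 0).any():
            raise ValueError("adjacency must be nonnegative")
        if np.abs(np.diag(A)).max(initial=0.0) > 0:
            raise ValueError("adjacency diagonal must be zero")
        if self.mode not in ("weighted", "binarized"):
            raise ValueError("mode must be 'weighted' or 'binarized'")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        for i, j in zip(iu, ju):
            w = self.adjacency[i, j]
            G.add_edge(int(i), int(j), weight=w, distance=1.0 / w)
        return G


@dataclass
class GlobalMetrics:
    CC: float = np.nan
    E_loc: float = np.nan
    CPL: float = np.nan
    E_glob: float = np.nan
    gamma: float = np.nan
    lam: float = np.nan
    sigma: float = np.nan
    Q: float = np.nan
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {
            "CC": self.CC, "E_loc": self.E_loc, "CPL": self.CPL,
            "E_glob": self.E_glob, "gamma": self.gamma, "lambda": self.lam,
            "sigma": self.sigma, "Q": self.Q,
        }


def threshold_proportional(
    m: ConnectivityMatrix, p: float, mode: str = "weighted"
) -> BrainGraph:
    """Retain the fraction ``p`` of the strongest positive connections.

    Keeps the ``round(p * R(R-1)/2)`` largest positive z-values as edges;
    all other entries (including every negative value) become 0. Ties are
    broken deterministically by (weight desc, i asc, j asc). If fewer
    positive entries exist than requested, all positives are kept with a
    warning.
    """
    if not (0 < p <= 1):
        raise ValueError("sparsity p must be in (0, 1]")
    R = m.n_rois
    iu, ju = np.triu_indices(R, k=1)
    w = m.z[iu, ju]
    n_target = int(round(p * R * (R - 1) / 2))
    pos = w > 0
    n_pos = int(pos.sum())
    if n_pos < n_target:
        warnings.warn(
            f"only {n_pos} positive connections available for target "
            f"{n_target}; keeping all positives",
            stacklevel=2,
        )
        n_keep = n_pos
    else:
        n_keep = n_target
    order = np.lexsort((ju, iu, -w))  # weight desc, then i asc, j asc
    keep = order[:n_keep]
    keep = keep[w[keep] > 0]
    A = np.zeros((R, R))
    vals = np.ones(len(keep)) if mode == "binarized" else w[keep]
    A[iu[keep], ju[keep]] = vals
    A[ju[keep], iu[keep]] = vals
    return BrainGraph(adjacency=A, roi_names=list(m.roi_names), mode=mode, sparsity=p)


# ---------------------------------------------------------------------------
# Metric building blocks


def _pairwise_distances(G: nx.Graph, weighted: bool) -> dict[int, dict[int, float]]:
    if weighted:
        return dict(nx.all_pairs_dijkstra_path_length(G, weight="distance"))
    return dict(nx.all_pairs_shortest_path_length(G))


def _cpl_eglob(G: nx.Graph, weighted: bool) -> tuple[float, float, np.ndarray]:
    """Characteristic path length, global efficiency and nodal E_reg.

    CPL averages distances over connected pairs only (+inf with no edges);
    E_glob and E_reg count disconnected pairs as efficiency 0.
    """
    n = G.number_of_nodes()
    dist = _pairwise_distances(G, weighted)
    total_d = 0.0
    n_connected = 0
    inv_sum = np.zeros(n)
    for i in range(n):
        di = dist.get(i, {})
        for j in range(n):
            if j == i:
                continue
            d = di.get(j)
            if d is not None and d > 0:
                total_d += d
                n_connected += 1
                inv_sum[i] += 1.0 / d
    cpl = total_d / n_connected if n_connected else np.inf
    e_reg = inv_sum / (n - 1) if n > 1 else inv_sum
    e_glob = float(e_reg.mean())
    return cpl, e_glob, e_reg


def _nodal_clustering(G: nx.Graph, weighted: bool) -> np.ndarray:
    weight = "weight" if weighted else None
    cc = nx.clustering(G, weight=weight)
    return np.array([cc[i] for i in range(G.number_of_nodes())])


def _nodal_local_efficiency(G: nx.Graph, weighted: bool) -> np.ndarray:
    """Local efficiency of each node: E_glob of its neighborhood subgraph."""
    n = G.number_of_nodes()
    out = np.zeros(n)
    for i in range(n):
        neigh = list(G.neighbors(i))
        if len(neigh) < 2:
            continue
        sub = nx.convert_node_labels_to_integers(G.subgraph(neigh))
        _, e_glob, _ = _cpl_eglob(sub, weighted)
        out[i] = e_glob
    return out


def _modularity(G: nx.Graph, weighted: bool, seed: int, restarts: int = 5) -> float:
    """Louvain modularity Q: best of ``restarts`` seeded runs.

    The partition itself is not stable across runs, so only Q is exposed.
    Returns 0 for graphs with no edges (trivial one-community partition).
    """
    if G.number_of_edges() == 0:
        return 0.0
    weight = "weight" if weighted else None
    best = -np.inf
    for k in range(restarts):
        parts = nx.community.louvain_communities(G, weight=weight, seed=seed + k)
        q = nx.community.modularity(G, parts, weight=weight or "weight")
        best = max(best, q)
    return float(best)


def global_graph_metrics(g: BrainGraph, seed: int = 0) -> GlobalMetrics:
    """Five of the eight global metrics (gamma/lambda/sigma are separate).

    CC is the mean nodal clustering coefficient; E_loc the mean nodal local
    efficiency; CPL the mean shortest-path length over connected pairs
    (reported as +inf and flagged for edgeless graphs); E_glob the mean
    inverse shortest-path length; Q the Louvain modularity.
    """
    if g.n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    G = g.to_networkx()
    weighted = g.mode == "weighted"
    flags = []
    if g.n_edges == 0:
        flags.append("no_edges")
    cpl, e_glob, _ = _cpl_eglob(G, weighted)
    metrics = GlobalMetrics(
        CC=float(_nodal_clustering(G, weighted).mean()),
        E_loc=float(_nodal_local_efficiency(G, weighted).mean()),
        CPL=cpl,
        E_glob=e_glob,
        Q=_modularity(G, weighted, seed),
        flags=flags,
    )
    return metrics


def nodal_graph_metrics(g: BrainGraph) -> dict[str, np.ndarray]:
    """Per-node metrics as a structured (R x 6) array-backed dict.

    Returns a dict of arrays: strength (weight sum; equals degree for
    binarized graphs), degree, clustering CC_i, local efficiency E_loc_i,
    regional efficiency E_reg_i (mean inverse distance to every other node)
    and betweenness centrality BC_i (fraction of all-pairs shortest paths
    through the node, normalized to [0, 1]). Isolated nodes score 0 on all.
    """
    G = g.to_networkx()
    weighted = g.mode == "weighted"
    n = g.n_nodes
    strength = g.adjacency.sum(axis=1)
    degree = (g.adjacency > 0).sum(axis=1).astype(float)
    _, _, e_reg = _cpl_eglob(G, weighted)
    bc = nx.betweenness_centrality(
        G, normalized=True, weight="distance" if weighted else None
    )
    return {
        "strength": strength,
        "degree": degree,
        "CC": _nodal_clustering(G, weighted),
        "E_loc": _nodal_local_efficiency(G, weighted),
        "E_reg": e_reg,
        "BC": np.array([bc[i] for i in range(n)]),
    }


def _rewired_ensemble_graph(
    g: BrainGraph, rng: np.random.Generator, method: str
) -> nx.Graph:
    if method == "erdos_renyi":
        return nx.gnm_random_graph(
            g.n_nodes, g.n_edges, seed=int(rng.integers(2**31))
        )
    # degree-preserving double-edge swaps, weights travel with their edges
    G = g.to_networkx()
    edges = list(G.edges(data=True))
    if len(edges) < 2:
        return G
    n_swaps = 10 * len(edges)
    attempts = 0
    done = 0
    while done < n_swaps and attempts < 100 * n_swaps:
        attempts += 1
        k1, k2 = rng.integers(G.number_of_edges(), size=2)
        edge_list = list(G.edges(data=True))
        (a, b, d1), (c, d, d2) = edge_list[k1], edge_list[k2]
        if len({a, b, c, d}) < 4:
            continue
        if G.has_edge(a, d) or G.has_edge(c, b):
            continue
        G.remove_edge(a, b)
        G.remove_edge(c, d)
        G.add_edge(a, d, **d1)
        G.add_edge(c, b, **d2)
        done += 1
    return G


def normalized_metrics(
    g: BrainGraph,
    n_random: int = 100,
    seed: int = 0,
    null_model: str = "rewire",
) -> tuple[float, float, float]:
    """Normalized clustering (gamma), path length (lambda), small-worldness.

    gamma = CC / mean(CC_random), lambda = CPL / mean(CPL_random), sigma =
    gamma / lambda, against ``n_random`` random graphs with the same number
    of nodes and edges: degree-preserving rewirings by default
    (``null_model='erdos_renyi'`` for unconstrained random graphs).
    Deterministic given seed; gamma is NaN (flagged by a warning) if the
    random ensemble has zero clustering.
    """
    rng = np.random.default_rng(seed)
    G = g.to_networkx()
    weighted = g.mode == "weighted"
    cc = float(_nodal_clustering(G, weighted).mean())
    cpl, _, _ = _cpl_eglob(G, weighted)
    cc_rand = []
    cpl_rand = []
    for _ in range(n_random):
        Gr = _rewired_ensemble_graph(g, rng, null_model)
        if null_model == "erdos_renyi" and weighted:
            # assign the original weight multiset to the random edges
            weights = sorted(
                (d["weight"] for _, _, d in g.to_networkx().edges(data=True)),
                reverse=True,
            )
            perm = rng.permutation(len(weights))
            for (u, v), k in zip(Gr.edges(), perm):
                Gr[u][v]["weight"] = weights[k]
                Gr[u][v]["distance"] = 1.0 / weights[k]
        cc_rand.append(float(_nodal_clustering(Gr, weighted).mean()))
        cpl_r, _, _ = _cpl_eglob(Gr, weighted)
        cpl_rand.append(cpl_r)
    mean_cc = float(np.mean(cc_rand))
    finite_cpl = [c for c in cpl_rand if np.isfinite(c)]
    mean_cpl = float(np.mean(finite_cpl)) if finite_cpl else np.nan
    if mean_cc <= 0:
        warnings.warn("random ensemble has zero clustering; gamma undefined",
                      stacklevel=2)
        gamma = np.nan
    else:
        gamma = cc / mean_cc
    lam = cpl / mean_cpl if (np.isfinite(cpl) and mean_cpl and np.isfinite(mean_cpl)) else np.nan
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else np.nan
    return gamma, lam, sigma


def metrics_across_sparsities(
    m: ConnectivityMatrix,
    levels: tuple[float, ...] = SPARSITY_LEVELS,
    mode: str = "weighted",
    n_random: int = 100,
    seed: int = 0,
    include_normalized: bool = True,
) -> dict[str, float]:
    """Global and nodal metrics averaged across sparsity levels.

    Thresholds the matrix at each sparsity level, computes the eight global
    and per-node metrics, and returns their arithmetic means over levels as
    a flat dict (``global_*`` and ``nodal_<metric>_<roi>``). Non-finite
    values at a level are excluded from that metric's mean with a warning.
    """
    per_level: list[dict[str, float]] = []
    for p in levels:
        g = threshold_proportional(m, p, mode=mode)
        gm = global_graph_metrics(g, seed=seed)
        row = {f"global_{k}": v for k, v in gm.as_dict().items()}
        if include_normalized:
            gamma, lam, sigma = normalized_metrics(g, n_random=n_random, seed=seed)
            row["global_gamma"], row["global_lambda"], row["global_sigma"] = (
                gamma, lam, sigma,
            )
        else:
            for k in ("global_gamma", "global_lambda", "global_sigma"):
                row.pop(k, None)
        nm = nodal_graph_metrics(g)
        for metric, values in nm.items():
            for roi, v in zip(m.roi_names, values):
                row[f"nodal_{metric}_{roi}"] = float(v)
        per_level.append(row)
    keys = per_level[0].keys()
    out: dict[str, float] = {}
    for k in keys:
        vals = np.array([row[k] for row in per_level])
        finite = np.isfinite(vals)
        if not finite.all():
            warnings.warn(
                f"metric {k} undefined at {int((~finite).sum())} sparsity "
                "level(s); excluded from the average",
                stacklevel=2,
            )
        out[k] = float(vals[finite].mean()) if finite.any() else np.nan
    return out
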