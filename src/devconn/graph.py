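"""Weighted graph-theory features of thresholded connectivity matrices.

Each subject-level connectivity matrix is reduced to 12 scalar topology
metrics covering integration (global efficiency, local efficiency,
characteristic path length), segregation (clustering, modularity), centrality
(participation coefficient, within-module degree) and their null-normalized
companions plus the small-worldness index and a hub-prevalence score.

Conventions
-----------
* Edges carry the (nonnegative) correlation weights that survive
  proportional thresholding; distances are 1/weight on retained edges.
* Clustering is Onnela's weighted nodal coefficient (weights scaled by the
  graph maximum), averaged over nodes.
* Null-normalized metrics (modularity_z, participation_z,
  within_module_degree_z) and small-worldness are computed against an
  ensemble of degree-preserving rewired graphs with the original weight
  multiset shuffled onto the rewired topology.
* Nodal metrics are collapsed to scalars by an unweighted mean over nodes;
  the model consumes exactly 12 scalars in the order of `FEATURE_NAMES`.

The within-module degree scalar is the mean fraction of each node's strength
that stays inside its own module (so it is not a rescaled copy of its
ensemble z companion); the hub score is the fraction of nodes whose nodal
within-module strength z-score exceeds 1. Neither summary is standardized in
the field, so both are documented package choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import random as _pyrandom

import numpy as np
import igraph as _ig
from numba import njit
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityMatrix

__all__ = [
    "WeightedGraph",
    "FEATURE_NAMES",
    "threshold_graph",
    "community_partition",
    "global_metrics",
]

FEATURE_NAMES = (
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "characteristic_path_length",
    "small_worldness",
    "modularity_q",
    "modularity_z",
    "participation_mean",
    "participation_z",
    "within_module_degree_mean",
    "within_module_degree_z",
    "hub_score",
)


@dataclass
class WeightedGraph:
    """Nonnegative symmetric adjacency with zero diagonal."""

    adjacency: np.ndarray
    density: float

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if (a < 0).any():
            raise ValueError("adjacency weights must be nonnegative")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))


def threshold_graph(m: ConnectivityMatrix | np.ndarray, density: float = 0.15) -> WeightedGraph:
    """Proportional threshold: keep the strongest positive edges.

    Negative weights are zeroed first; then the top ``density`` fraction of
    the P(P-1)/2 possible edges (by weight, ties broken by the fixed
    row-major edge order) is retained. Weights of retained edges are kept.
    """
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    vals = m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m, dtype=float)
    p = vals.shape[0]
    w = vals.copy().astype(float)
    np.fill_diagonal(w, 0.0)
    w[w < 0] = 0.0
    iu, ju = np.triu_indices(p, k=1)
    upper = w[iu, ju]
    n_possible = upper.size
    k = int(round(density * n_possible))
    k = min(k, int(np.count_nonzero(upper)))
    if k == 0:
        raise ValueError("thresholding removed every edge (empty graph)")
    # stable sort on (-weight, index): ties resolved by edge order
    order = np.lexsort((np.arange(n_possible), -upper))
    keep = order[:k]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = upper[keep]
    out = out + out.T
    return WeightedGraph(out, density=k / n_possible)


def community_partition(g: WeightedGraph, seed: int = 0) -> tuple[np.ndarray, float]:
    """Louvain-style greedy modularity maximization (seeded).

    Returns integer module labels (0..M-1, ordered by first appearance) and
    the weighted modularity Q of the returned partition.
    """
    if g.n_edges == 0:
        raise ValueError("cannot partition an empty graph")
    src, dst = np.nonzero(np.triu(g.adjacency, k=1))
    weights = g.adjacency[src, dst]
    G = _ig.Graph(n=g.n_nodes, edges=np.column_stack([src, dst]).tolist())
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(int(seed))  # igraph draws from Python's RNG
        membership = np.asarray(G.community_multilevel(weights=weights.tolist()).membership)
    finally:
        _pyrandom.setstate(state)
    # canonical label order: by smallest node index in each community
    labels = np.empty(g.n_nodes, dtype=int)
    next_lab, seen = 0, {}
    for node in range(g.n_nodes):
        m = int(membership[node])
        if m not in seen:
            seen[m] = next_lab
            next_lab += 1
        labels[node] = seen[m]
    q = modularity_q(g.adjacency, labels)
    return labels, q


def modularity_q(adj: np.ndarray, labels: np.ndarray) -> float:
    """Weighted Newman modularity of a given partition."""
    k = adj.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    same = labels[:, None] == labels[None, :]
    return float(((adj - np.outer(k, k) / two_m) * same).sum() / two_m)


# ---------------------------------------------------------------------------
# nodal building blocks


def _shortest_path_lengths(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / adj, 0.0)
    return dijkstra(lengths, directed=False)


def _efficiency_from_dist(dist: np.ndarray) -> float:
    """Mean inverse distance over distinct pairs (disconnected pairs -> 0)."""
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    return float(inv[off].mean())


def _char_path_length(dist: np.ndarray) -> float:
    """Mean finite shortest-path distance over distinct pairs."""
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    d = dist[off]
    finite = np.isfinite(d)
    if not finite.all():
        warnings.warn("graph is disconnected; path length averaged over finite pairs")
    if not finite.any():
        return np.inf
    return float(d[finite].mean())


def _onnela_clustering(adj: np.ndarray) -> np.ndarray:
    """Onnela weighted nodal clustering coefficients."""
    wmax = adj.max()
    if wmax == 0:
        return np.zeros(adj.shape[0])
    w = (adj / wmax) ** (1.0 / 3.0)
    triangles = np.diagonal(w @ w @ w)
    deg = (adj > 0).sum(axis=1)
    denom = deg * (deg - 1)
    c = np.zeros(adj.shape[0])
    ok = denom > 0
    c[ok] = triangles[ok] / denom[ok]
    return c


def _local_efficiency(adj: np.ndarray) -> float:
    """Mean over nodes of the efficiency of each node's neighbor subgraph."""
    n = adj.shape[0]
    effs = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i] > 0)
        if nbrs.size < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        effs[i] = _efficiency_from_dist(_shortest_path_lengths(sub))
    return float(effs.mean())


def _participation(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Nodal participation coefficient 1 - sum_m (kappa_im / k_i)^2."""
    n = adj.shape[0]
    k = adj.sum(axis=1)
    modules = np.unique(labels)
    kappa = np.zeros((n, modules.size))
    for j, mod in enumerate(modules):
        kappa[:, j] = adj[:, labels == mod].sum(axis=1)
    p = np.zeros(n)
    ok = k > 0
    p[ok] = 1.0 - ((kappa[ok] / k[ok, None]) ** 2).sum(axis=1)
    return p


def _within_module_strength(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Nodal strength restricted to the node's own module."""
    same = labels[:, None] == labels[None, :]
    return (adj * same).sum(axis=1)


def _within_module_fraction(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = adj.sum(axis=1)
    kin = _within_module_strength(adj, labels)
    frac = np.zeros_like(k)
    ok = k > 0
    frac[ok] = kin[ok] / k[ok]
    return frac


def _nodal_within_module_z(adj: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Classic within-module degree z: standardize kappa_in within modules."""
    kin = _within_module_strength(adj, labels)
    z = np.zeros_like(kin)
    for mod in np.unique(labels):
        idx = labels == mod
        mu, sd = kin[idx].mean(), kin[idx].std()
        if sd > 0:
            z[idx] = (kin[idx] - mu) / sd
    return z


@njit(cache=False)
def _swap_edges(edges, present, pair_draws, coin_draws, n_swaps):  # pragma: no cover - jit
    m = edges.shape[0]
    swaps = 0
    for attempt in range(pair_draws.shape[0]):
        if swaps >= n_swaps:
            break
        a, b = pair_draws[attempt, 0], pair_draws[attempt, 1]
        if a == b:
            continue
        u, v = edges[a, 0], edges[a, 1]
        x, y = edges[b, 0], edges[b, 1]
        if coin_draws[attempt]:
            x, y = y, x
        if u == x or u == y or v == x or v == y:
            continue
        # proposed new edges (u, x) and (v, y)
        if present[u, x] or present[v, y]:
            continue
        present[u, v] = present[v, u] = False
        present[x, y] = present[y, x] = False
        present[u, x] = present[x, u] = True
        present[v, y] = present[y, v] = True
        edges[a, 0], edges[a, 1] = (u, x) if u < x else (x, u)
        edges[b, 0], edges[b, 1] = (v, y) if v < y else (y, v)
        swaps += 1


def _rewired_null(adj: np.ndarray, rng: np.random.Generator, n_swaps_per_edge: int = 5) -> np.ndarray:
    """Degree-preserving rewired graph with weights shuffled onto new edges.

    Maslov–Sneppen double-edge swaps on the binary topology, then the
    original weight multiset is randomly reassigned to the rewired edges.
    """
    iu, ju = np.nonzero(np.triu(adj, k=1))
    m = iu.size
    if m < 2:
        return adj.copy()
    edges = np.column_stack([iu, ju]).astype(np.int64)
    weights = adj[iu, ju].copy()
    present = adj > 0
    n_swaps = n_swaps_per_edge * m
    max_attempts = 20 * n_swaps
    pair_draws = rng.integers(0, m, size=(max_attempts, 2))
    coin_draws = rng.random(max_attempts) < 0.5
    _swap_edges(edges, present, pair_draws, coin_draws, n_swaps)
    perm = rng.permutation(m)
    out = np.zeros_like(adj)
    out[edges[:, 0], edges[:, 1]] = weights[perm]
    out[edges[:, 1], edges[:, 0]] = weights[perm]
    return out


def global_metrics(
    g: WeightedGraph,
    labels: np.ndarray | None = None,
    n_null: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """The 12-entry graph feature vector (order: `FEATURE_NAMES`).

    Parameters
    ----------
    g : WeightedGraph
        Thresholded graph.
    labels : ndarray, optional
        Module labels from `community_partition`; computed here if omitted.
    n_null : int
        Size of the degree-preserving null ensemble (>= 10) used for the
        z-scored metrics and small-worldness.
    seed : int
        Seeds both community detection (if run here) and the null ensemble.
    """
    if n_null < 10:
        raise ValueError("n_null must be >= 10")
    if labels is None:
        labels, q = community_partition(g, seed=seed)
    else:
        labels = np.asarray(labels)
        q = modularity_q(g.adjacency, labels)

    adj = g.adjacency
    dist = _shortest_path_lengths(adj)
    geff = _efficiency_from_dist(dist)
    cpl = _char_path_length(dist)
    clust = float(_onnela_clustering(adj).mean())
    leff = _local_efficiency(adj)
    part = float(_participation(adj, labels).mean())
    wmd = float(_within_module_fraction(adj, labels).mean())
    hub = float((_nodal_within_module_z(adj, labels) > 1).mean())

    rng = np.random.default_rng(seed)
    null_c, null_l, null_q, null_p, null_w = [], [], [], [], []
    for b in range(n_null):
        null_adj = _rewired_null(adj, rng)
        null_g = WeightedGraph(null_adj, density=g.density)
        nlab, nq = community_partition(null_g, seed=int(rng.integers(2**31 - 1)))
        ndist = _shortest_path_lengths(null_adj)
        null_c.append(_onnela_clustering(null_adj).mean())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_l.append(_char_path_length(ndist))
        null_q.append(nq)
        null_p.append(_participation(null_adj, nlab).mean())
        null_w.append(_within_module_fraction(null_adj, nlab).mean())

    def _z(obs, null):
        null = np.asarray(null, dtype=float)
        sd = null.std()
        if sd == 0 or not np.isfinite(sd):
            warnings.warn("zero/degenerate null SD; z-score reported as 0")
            return 0.0
        return float((obs - null.mean()) / sd)

    c_null = float(np.mean(null_c))
    l_null = float(np.mean([x for x in null_l if np.isfinite(x)]) or np.nan)
    if c_null > 0 and l_null > 0 and np.isfinite(cpl):
        sigma = (clust / c_null) / (cpl / l_null)
    else:
        warnings.warn("degenerate null means; small-worldness reported as NaN")
        sigma = np.nan

    vec = np.array(
        [
            geff,
            leff,
            clust,
            cpl,
            sigma,
            q,
            _z(q, null_q),
            part,
            _z(part, null_p),
            wmd,
            _z(wmd, null_w),
            hub,
        ]
    )
    assert vec.shape == (12,)
    return vec
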