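"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive: exhaustive path enumeration, direct
summation, O(n^2) pair counting. These routines never share code with the
package modules they check.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# graph metrics (small graphs only)


def brute_shortest_paths(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest 1/weight path lengths by exhaustive enumeration."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    nodes = range(n)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            best = np.inf
            for k in range(0, n - 1):
                for mids in itertools.permutations([m for m in nodes if m not in (s, t)], k):
                    path = (s, *mids, t)
                    length = 0.0
                    ok = True
                    for u, v in zip(path, path[1:]):
                        if adj[u, v] <= 0:
                            ok = False
                            break
                        length += 1.0 / adj[u, v]
                    if ok:
                        best = min(best, length)
            dist[s, t] = best
    return dist


def brute_global_efficiency(adj):
    d = brute_shortest_paths(adj)
    n = d.shape[0]
    vals = [1.0 / d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j]) and d[i, j] > 0]
    vals += [0.0 for i in range(n) for j in range(n) if i != j and not np.isfinite(d[i, j])]
    return float(np.mean(vals))


def brute_char_path_length(adj):
    d = brute_shortest_paths(adj)
    n = d.shape[0]
    off = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(off))


def brute_onnela_clustering(adj):
    n = adj.shape[0]
    wmax = adj.max()
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        tot = 0.0
        for j in nbrs:
            for h in nbrs:
                if j != h and adj[j, h] > 0:
                    tot += ((adj[i, j] / wmax) * (adj[i, h] / wmax) * (adj[j, h] / wmax)) ** (1 / 3)
        cs.append(tot / (k * (k - 1)))
    return float(np.mean(cs))


def brute_local_efficiency(adj):
    n = adj.shape[0]
    effs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j] > 0]
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        effs.append(brute_global_efficiency(sub))
    return float(np.mean(effs))


def brute_participation(adj, labels):
    n = adj.shape[0]
    out = []
    for i in range(n):
        k = adj[i].sum()
        if k == 0:
            out.append(0.0)
            continue
        s = 0.0
        for mod in np.unique(labels):
            kim = adj[i, labels == mod].sum()
            s += (kim / k) ** 2
        out.append(1.0 - s)
    return np.array(out)


def brute_within_module_fraction(adj, labels):
    n = adj.shape[0]
    out = []
    for i in range(n):
        k = adj[i].sum()
        out.append(0.0 if k == 0 else adj[i, labels == labels[i]].sum() / k)
    return np.array(out)


def brute_modularity(adj, labels):
    two_m = adj.sum()
    q = 0.0
    n = adj.shape[0]
    k = adj.sum(axis=1)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += adj[i, j] - k[i] * k[j] / two_m
    return q / two_m


# ---------------------------------------------------------------------------
# classification metrics


def brute_auc(y, p):
    """Pair-enumeration AUC with ties counted one half."""
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    total = 0.0
    for pp in pos:
        for nn in neg:
            if pp > nn:
                total += 1.0
            elif pp == nn:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# partial correlation


def brute_partial_correlation(x, y, c):
    """Residualize on [1 | c] by explicit normal equations, then Pearson."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    d = np.column_stack([np.ones(len(x)), np.asarray(c, float).reshape(len(x), -1)])
    proj = d @ np.linalg.pinv(d.T @ d) @ d.T
    rx = x - proj @ x
    ry = y - proj @ y
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# bivariate-normal orthant probability


def orthant_upper(rho: float, z: float = 1.0) -> float:
    """P(X > z, Y > z) for standard bivariate normal with correlation rho."""
    from scipy.stats import multivariate_normal, norm

    if rho >= 1.0 - 1e-12:
        return float(norm.sf(z))
    mvn = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
    # inclusion-exclusion from the joint CDF
    return float(1 - norm.cdf(z) - norm.cdf(z) + mvn.cdf([z, z]))


# ---------------------------------------------------------------------------
# Kendall's W by direct formula


def brute_kendalls_w(rankings):
    r = np.asarray(rankings, float)
    k, g = r.shape
    sums = r.sum(axis=0)
    s = ((sums - sums.mean()) ** 2).sum()
    return 12.0 * s / (k**2 * (g**3 - g))
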