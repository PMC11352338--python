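"""Brute-force network-metric oracle used only by the test suite.

Everything here works directly on a dense weight matrix ``W`` (``W[i, j] > 0``
is a directed edge i→j) and enumerates simple paths exhaustively, so it is
independent of the library implementations it checks.  Path distances are
accumulated left-to-right as ``1/weight`` prefix sums, the same float
arithmetic any shortest-path algorithm performs, so tie detection agrees at
machine precision.
"""

from __future__ import annotations

import itertools

import numpy as np


def _all_paths(W: np.ndarray, s: int, t: int):
    """Yield (distance, path) for every simple path s -> t."""
    n = len(W)
    stack = [(s, (s,), 0.0)]
    while stack:
        u, path, d = stack.pop()
        if u == t and len(path) > 1:
            yield d, path
            continue
        for v in range(n):
            if W[u, v] > 0 and v not in path:
                nd = d + 1.0 / W[u, v]
                if v == t:
                    yield nd, path + (v,)
                else:
                    stack.append((v, path + (v,), nd))


def shortest_path_info(W: np.ndarray, s: int, t: int):
    """(min distance, number of shortest paths, through-counts per node).

    Distance is inf when t is unreachable from s.
    """
    n = len(W)
    best, count, through = np.inf, 0, np.zeros(n)
    for d, path in _all_paths(W, s, t):
        if d < best:
            best, count = d, 1
            through = np.zeros(n)
            for v in path[1:-1]:
                through[v] += 1
        elif d == best:
            count += 1
            for v in path[1:-1]:
                through[v] += 1
    return best, count, through


def distance_matrix(W: np.ndarray) -> np.ndarray:
    n = len(W)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for s, t in itertools.permutations(range(n), 2):
        D[s, t] = shortest_path_info(W, s, t)[0]
    return D


def brute_global_efficiency(W: np.ndarray) -> float:
    n = len(W)
    D = distance_matrix(W)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    return float(np.sum(inv[off]) / (n * (n - 1)))


def brute_betweenness(W: np.ndarray) -> np.ndarray:
    """Normalized directed betweenness by exhaustive shortest-path counting."""
    n = len(W)
    b = np.zeros(n)
    if n < 3:
        return b
    for s, t in itertools.permutations(range(n), 2):
        _, count, through = shortest_path_info(W, s, t)
        if count > 0:
            b += through / count
    return b / ((n - 1) * (n - 2))


def brute_closeness_wf(W: np.ndarray) -> np.ndarray:
    """Incoming-distance closeness with the Wasserman–Faust correction."""
    n = len(W)
    D = distance_matrix(W)
    out = np.zeros(n)
    for u in range(n):
        dists = D[:, u]  # incoming distances
        reach = np.isfinite(dists) & (np.arange(n) != u)
        r = int(np.sum(reach))
        tot = float(np.sum(dists[reach]))
        if r > 0 and tot > 0:
            out[u] = (r / tot) * (r / (n - 1))
    return out


def brute_clustering_fagiolo(W: np.ndarray) -> np.ndarray:
    """Directed weighted clustering: geometric-mean triangles over total degree.

    Weights are rescaled by the graph maximum; with cube-rooted symmetrized
    weights S = Ŵ^(1/3) + (Ŵ^(1/3))ᵀ, node i scores (S³)_ii / 2 over
    d_tot(d_tot − 1) − 2·d_bidirectional.
    """
    n = len(W)
    A = (W > 0).astype(float)
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n)
    S = np.cbrt(W / wmax)
    S = S + S.T
    tri = np.diagonal(np.linalg.matrix_power(S, 3)) / 2.0
    d_tot = A.sum(axis=0) + A.sum(axis=1)
    d_bi = (A * A.T).sum(axis=1)
    denom = d_tot * (d_tot - 1) - 2 * d_bi
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return c
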