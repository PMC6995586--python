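"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration, finite differences) and shares no code with the package
routines it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------- sequences

def pairwise_identity_weights(rows: list[str], threshold: float) -> list[float]:
    """O(M^2 L) reweighting oracle: weight_a = 1 / #{b: id(a,b) >= t}."""
    M = len(rows)
    weights = []
    for a in range(M):
        m = 0
        for b in range(M):
            ident = sum(1 for x, y in zip(rows[a], rows[b]) if x == y)
            if ident >= threshold * len(rows[a]):
                m += 1
        weights.append(1.0 / m)
    return weights


def plugin_mi(col_i: str, col_j: str) -> float:
    """Classical plug-in MI (nats) from direct symbol counting, no weights."""
    n = len(col_i)
    from collections import Counter

    ci, cj = Counter(col_i), Counter(col_j)
    cij = Counter(zip(col_i, col_j))
    mi = 0.0
    for (a, b), nab in cij.items():
        pij = nab / n
        mi += pij * math.log(pij / ((ci[a] / n) * (cj[b] / n)))
    return mi


def enumerate_two_site_potts(J: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact joint distribution P(A,B) ~ exp(J[A,B]) and its MI (nats)."""
    P = np.exp(J)
    P /= P.sum()
    pa, pb = P.sum(axis=1), P.sum(axis=0)
    mi = 0.0
    for a in range(J.shape[0]):
        for b in range(J.shape[1]):
            if P[a, b] > 0:
                mi += P[a, b] * math.log(P[a, b] / (pa[a] * pb[b]))
    return P, mi


# ------------------------------------------------------------------- graphs

def brute_force_top_pairs(scores: np.ndarray, top_n: int, min_sep: int):
    """Exhaustive sort-and-filter selection oracle (1-based numbering)."""
    L = scores.shape[0]
    pairs = [
        (i + 1, j + 1, float(scores[i, j]))
        for i in range(L)
        for j in range(i + 1, L)
        if abs(i - j) >= min_sep
    ]
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return pairs[:top_n]


def brute_force_maximal_cliques(nodes: list, edges: set) -> list[frozenset]:
    """2^n subset enumeration of maximal cliques."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def is_clique(sub):
        return all(v in adj[u] for u, v in itertools.combinations(sub, 2))

    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not is_clique(sub):
                continue
            s = set(sub)
            extendable = any(s <= adj[w] for w in nodes if w not in s)
            if not extendable:
                cliques.append(frozenset(s))
    return sorted(cliques, key=lambda c: (-len(c), tuple(sorted(c))))


def all_partitions(items: list):
    """Every partition of a small set (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] | {first}] + part[k + 1 :]
        yield part + [{first}]


def brute_force_betweenness(nodes: list, lengths: dict) -> dict:
    """Node betweenness by Floyd-Warshall + shortest-path DAG counting.

    ``lengths``: dict (u, v) -> positive length (undirected).  Returns
    betweenness normalized by (n-1)(n-2)/2.
    """
    n = len(nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    INF = float("inf")
    d = [[0.0 if i == j else INF for j in range(n)] for i in range(n)]
    for (u, v), w in lengths.items():
        d[idx[u]][idx[v]] = min(d[idx[u]][idx[v]], w)
        d[idx[v]][idx[u]] = min(d[idx[v]][idx[u]], w)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]

    adj = {i: {} for i in range(n)}
    for (u, v), w in lengths.items():
        adj[idx[u]][idx[v]] = min(adj[idx[u]].get(idx[v], INF), w)
        adj[idx[v]][idx[u]] = min(adj[idx[v]].get(idx[u], INF), w)

    eps = 1e-12

    def sigma(s, t):
        # number of shortest s->t paths via DAG recursion on distance order
        if s == t:
            return 1
        total = 0
        for p, w in adj[t].items():
            if abs(d[s][p] + w - d[s][t]) < eps:
                total += sigma(s, p)
        return total

    bc = {v: 0.0 for v in nodes}
    for si in range(n):
        for ti in range(si + 1, n):
            if d[si][ti] == INF:
                continue
            s_total = sigma(si, ti)
            if s_total == 0:
                continue
            for vi in range(n):
                if vi in (si, ti):
                    continue
                if abs(d[si][vi] + d[vi][ti] - d[si][ti]) < eps:
                    bc[nodes[vi]] += sigma(si, vi) * sigma(vi, ti) / s_total
    norm = (n - 1) * (n - 2) / 2
    return {v: b / norm for v, b in bc.items()}


# ---------------------------------------------------------------- structure

def finite_difference_hessian(coords: np.ndarray, cutoff: float, k: float, h: float = 1e-5) -> np.ndarray:
    """Numerical Hessian of the harmonic pair potential at equilibrium."""
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            r0 = np.linalg.norm(coords[j] - coords[i])
            if 0 < r0 <= cutoff:
                pairs.append((i, j, r0))

    def energy(x):
        x = x.reshape(n, 3)
        e = 0.0
        for i, j, r0 in pairs:
            r = np.linalg.norm(x[j] - x[i])
            e += 0.5 * k * (r - r0) ** 2
        return e

    x0 = coords.ravel()
    m = 3 * n
    H = np.zeros((m, m))
    for a in range(m):
        for b in range(a, m):
            xpp = x0.copy(); xpp[a] += h; xpp[b] += h
            xpm = x0.copy(); xpm[a] += h; xpm[b] -= h
            xmp = x0.copy(); xmp[a] -= h; xmp[b] += h
            xmm = x0.copy(); xmm[a] -= h; xmm[b] -= h
            H[a, b] = H[b, a] = (
                energy(xpp) - energy(xpm) - energy(xmp) + energy(xmm)
            ) / (4 * h * h)
    return H
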