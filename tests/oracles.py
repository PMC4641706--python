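"""Independent brute-force oracles used to verify the package's fast paths.

Everything here is deliberately naive (explicit enumeration, set algebra,
exact tail sums) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def degrees_oracle(adj: np.ndarray) -> list[int]:
    n = adj.shape[0]
    return [sum(1 for j in range(n) if j != i and adj[i][j]) for i in range(n)]


def density_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    e = sum(1 for i in range(n) for j in range(i + 1, n) if adj[i][j])
    return 2.0 * e / (n * (n - 1))


def transitivity_oracle(adj: np.ndarray) -> float:
    """Global transitivity: 3 * triangles / connected triples."""
    n = adj.shape[0]
    triangles = 0
    for i, j, k in itertools.combinations(range(n), 3):
        if adj[i][j] and adj[j][k] and adj[i][k]:
            triangles += 1
    triples = 0
    for centre in range(n):
        d = sum(1 for j in range(n) if j != centre and adj[centre][j])
        triples += comb(d, 2)
    return 3.0 * triangles / triples if triples else 0.0


def centralization_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    degs = degrees_oracle(adj)
    return sum(max(degs) - d for d in degs) / ((n - 1) * (n - 2))


def neighbour_sets(adj: np.ndarray) -> list[set[int]]:
    n = adj.shape[0]
    return [{j for j in range(n) if j != i and adj[i][j]} for i in range(n)]


def rewiring_oracle(adj_c: np.ndarray, adj_d: np.ndarray):
    """(eg, el, common, dK) per node by explicit neighbour-set algebra."""
    nc, nd = neighbour_sets(adj_c), neighbour_sets(adj_d)
    out = []
    for i in range(adj_c.shape[0]):
        eg = len(nd[i] - nc[i])
        el = len(nc[i] - nd[i])
        common = len(nd[i] & nc[i])
        out.append((eg, el, common, len(nd[i]) - len(nc[i])))
    return out


def hypergeom_tail_oracle(overlap: int, universe: int, set_size: int, draws: int) -> float:
    """P(X >= overlap), X ~ Hypergeom(universe, set_size, draws), by exact sum."""
    total = comb(universe, draws)
    acc = 0
    for k in range(overlap, min(set_size, draws) + 1):
        acc += comb(set_size, k) * comb(universe - set_size, draws - k)
    return acc / total


def fisher_greater_oracle(n11: int, na: int, nb: int, universe: int) -> float:
    """One-sided Fisher p for overlap >= n11 of two sets of sizes na, nb,
    by enumerating all 2x2 tables with the same margins."""
    total = comb(universe, nb)
    acc = 0
    for k in range(n11, min(na, nb) + 1):
        acc += comb(na, k) * comb(universe - na, nb - k)
    return acc / total


def components_oracle(nodes: list, edges: list[tuple]) -> list[set]:
    """Connected components via union-find, independent of networkx."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return list(groups.values())


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the explicit step-up recipe."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
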