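"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive each quantity from its definition (enumeration,
closed-form combinatorics, textbook formulas) without sharing code with the
package internals they check.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def pearson_by_definition(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance / (sd * sd), computed with explicit sums."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / (n - 1))
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / (n - 1))
    return cov / (sx * sy)


def betweenness_by_enumeration(g: nx.Graph) -> dict:
    """Unnormalized betweenness via explicit shortest-path enumeration.

    For every unordered pair (s, t), enumerate all shortest paths and credit
    each interior node with its fraction; disconnected pairs contribute 0.
    """
    bc = {v: 0.0 for v in g.nodes()}
    nodes = sorted(g.nodes())
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n) via exact binomials."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


def holm_by_hand(p: list[float]) -> list[float]:
    """Holm step-down written directly from the sequential definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        candidate = min(1.0, (m - rank) * p[idx])
        running = max(running, candidate)
        adjusted[idx] = running
    return adjusted
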