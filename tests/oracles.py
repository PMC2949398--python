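"""Independent brute-force oracles used to cross-check the implementations.

These stay deliberately naive: full enumeration and first-principles
formulas, never the code paths they verify.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb
from typing import Sequence


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full enumeration of all tables with the observed
    margins, summing hypergeometric point probabilities <= that of the
    observed table (exact rational arithmetic)."""
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def point_prob(x: int) -> Fraction:
        return Fraction(comb(row1, x) * comb(row2, col1 - x), denom)

    observed = point_prob(a)
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    return sum(
        (point_prob(x) for x in range(lo, hi + 1) if point_prob(x) <= observed),
        Fraction(0),
    )


def clustering_oracle(edges: set[frozenset], node) -> float:
    """C via explicit neighbor-pair enumeration on a plain edge set."""
    neighbors = sorted({next(iter(e - {node})) for e in edges if node in e})
    k = len(neighbors)
    if k < 2:
        return 0.0
    links = sum(
        1
        for u, v in itertools.combinations(neighbors, 2)
        if frozenset((u, v)) in edges
    )
    return 2.0 * links / (k * (k - 1))


def bfs_distances_oracle(edges: set[frozenset], nodes: Sequence) -> dict:
    """All-pairs distances by naive breadth-first search."""
    adjacency = {n: set() for n in nodes}
    for e in edges:
        u, v = tuple(e)
        adjacency[u].add(v)
        adjacency[v].add(u)
    out = {}
    for source in nodes:
        dist = {source: 0.0}
        frontier = [source]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        out[source] = {n: dist.get(n, float("inf")) for n in nodes}
    return out


def spearman_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank (average ranks for ties) then Pearson, from first principles."""
    import numpy as np

    def average_ranks(values: Sequence[float]) -> list[float]:
        order = sorted(range(len(values)), key=lambda i: values[i])
        ranks = [0.0] * len(values)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx = np.array(average_ranks(list(x)))
    ry = np.array(average_ranks(list(y)))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def hypergeom_enrichment_oracle(
    background: set, module: set, gene_set: set
) -> Fraction:
    """P[overlap >= observed] by enumerating overlap counts exactly."""
    n_bg = len(background)
    set_bg = gene_set & background
    k_set = len(set_bg)
    n_mod = len(module)
    observed = len(gene_set & module)
    denom = comb(n_bg, n_mod)
    total = Fraction(0)
    for k in range(observed, min(k_set, n_mod) + 1):
        total += Fraction(comb(k_set, k) * comb(n_bg - k_set, n_mod - k), denom)
    return total
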