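"""Independent brute-force oracles used across the test suite.

Each oracle follows the defining formula literally (BFS path counting,
combinatorial sums, naive filter loops) and stays independent of the code
paths it checks.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from math import comb

import numpy as np


def bfs_paths(adj: dict, source):
    """Distances and shortest-path counts from ``source`` by plain BFS."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def brute_betweenness(adj: dict, normalized: bool = True) -> dict:
    """Σ_{s≠v≠t} σ_st(v)/σ_st over unordered pairs, by enumeration."""
    nodes = sorted(adj)
    n = len(nodes)
    bfs = {v: bfs_paths(adj, v) for v in nodes}
    score = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist_s, sigma_s = bfs[s]
        for t in nodes[i + 1:]:
            if t not in dist_s:
                continue
            dist_t, sigma_t = bfs[t]
            d_st, s_st = dist_s[t], sigma_s[t]
            for v in nodes:
                if v in (s, t) or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == d_st:
                    score[v] += sigma_s[v] * sigma_t[v] / s_st
    if normalized and n > 2:
        norm = (n - 1) * (n - 2) / 2
        score = {v: x / norm for v, x in score.items()}
    return score


def brute_closeness(adj: dict, mode: str = "normalized") -> dict:
    """1/Σd (raw) or the Wasserman–Faust component-scaled form, by BFS."""
    nodes = sorted(adj)
    n = len(nodes)
    out = {}
    for v in nodes:
        dist, _ = bfs_paths(adj, v)
        total = sum(d for u, d in dist.items() if u != v)
        r = len(dist)  # size of v's component
        if total == 0:
            out[v] = 0.0
        elif mode == "raw":
            out[v] = 1.0 / total
        else:
            out[v] = ((r - 1) / total) * ((r - 1) / (n - 1))
    return out


def brute_degree(adj: dict) -> dict:
    return {v: len(adj[v]) for v in adj}


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n), exact rational sum."""
    total = Fraction(0)
    denom = comb(N, n)
    for j in range(k, min(K, n) + 1):
        total += Fraction(comb(K, j) * comb(N - K, n - j), denom)
    return float(min(total, Fraction(1)))


def brute_diffnet(gene_expr, mirna_expr, catalog_pairs, de_genes,
                  condition_of, delta_threshold=0.2):
    """Literal reimplementation of the catalog→MGDRN filters.

    Loops over all catalog pairs, computes np.corrcoef per condition,
    applies the DE, sign, and difference filters exactly as stated, and
    returns {pair: (pcc_normal, pcc_tumor, direction)}.
    """
    samples = list(gene_expr.columns)
    normal = [s for s in samples if condition_of[s] == "normal"]
    tumor = [s for s in samples if condition_of[s] == "tumor"]
    result = {}
    for (mirna, gene) in sorted(catalog_pairs):
        if gene not in de_genes:
            continue
        if gene not in gene_expr.index or mirna not in mirna_expr.index:
            continue
        pccs = {}
        undefined = False
        for cond, cols in (("normal", normal), ("tumor", tumor)):
            x = gene_expr.loc[gene, cols].to_numpy(dtype=float)
            y = mirna_expr.loc[mirna, cols].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                undefined = True
                break
            pccs[cond] = float(np.corrcoef(x, y)[0, 1])
        if undefined:
            continue
        if not (pccs["normal"] < 0 or pccs["tumor"] < 0):
            continue
        delta = pccs["tumor"] - pccs["normal"]
        if abs(delta) > delta_threshold:
            direction = "up" if delta > 0 else "down"
            result[(mirna, gene)] = (pccs["normal"], pccs["tumor"], direction)
    return result


def random_bipartite_adj(rng: np.random.Generator, max_nodes: int = 30) -> dict:
    """Random simple bipartite graph as an adjacency dict (may be disconnected)."""
    n_left = int(rng.integers(2, max_nodes // 2 + 1))
    n_right = int(rng.integers(2, max_nodes - n_left + 1))
    left = [f"m{i}" for i in range(n_left)]
    right = [f"g{i}" for i in range(n_right)]
    adj = {v: set() for v in left + right}
    p = float(rng.uniform(0.1, 0.6))
    for u in left:
        for w in right:
            if rng.random() < p:
                adj[u].add(w)
                adj[w].add(u)
    return adj
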