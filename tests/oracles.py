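"""Independent brute-force reference implementations used only by tests.

Everything here avoids the library paths it checks: shortest paths via a
hand-rolled BFS over adjacency dicts, hypergeometric tails via exhaustive
enumeration of combinations, eigenvectors via dense numpy.linalg.eigh.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source) -> dict:
    """Hop distances from source over an adjacency dict."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in sorted(adj[u]):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def global_efficiency(adj: dict) -> float:
    """Mean inverse shortest-path length over ordered pairs / 2... computed
    as sum over ordered pairs divided by n(n-1), matching unordered mean."""
    nodes = sorted(adj)
    n = len(nodes)
    if n < 2:
        return 0.0
    total = 0.0
    for u in nodes:
        dist = bfs_distances(adj, u)
        for v in nodes:
            if v != u and v in dist:
                total += 1.0 / dist[v]
    return total / (n * (n - 1))


def graph_to_adj(graph) -> dict:
    """networkx graph -> plain adjacency dict (isolates kept)."""
    return {u: set(graph[u]) for u in graph.nodes}


def removal_scores(graph, gene_nodes) -> dict:
    """Node-removal efficiency change for each listed node, by recomputation."""
    adj = graph_to_adj(graph)
    base = global_efficiency(adj)
    out = {}
    for node in gene_nodes:
        sub = {u: vs - {node} for u, vs in adj.items() if u != node}
        out[node] = global_efficiency(sub) - base
    return out


def min_distance(graph, sources, target) -> int | None:
    """Smallest hop distance from any source node to target; None if unreachable."""
    adj = graph_to_adj(graph)
    best = None
    for s in sources:
        if s not in adj:
            continue
        dist = bfs_distances(adj, s)
        if target in dist and (best is None or dist[target] < best):
            best = dist[target]
    return best


def hypergeom_tail_enum(x: int, n_universe: int, big_k: int, k: int) -> float:
    """P(X >= x) for X = |pathway ∩ top-k| by enumerating all placements."""
    positions = range(n_universe)
    hits = 0
    total = 0
    for combo in itertools.combinations(positions, big_k):
        total += 1
        if sum(1 for c in combo if c < k) >= x:
            hits += 1
    return hits / total


def min_prefix_p_enum(ordered: list[str], members: set[str], n_universe: int):
    """(min p, k*) over prefixes, with the tail computed by enumeration."""
    big_k = len(members)
    best_p, best_k = 1.0, 0
    x = 0
    for k, g in enumerate(ordered, start=1):
        if g in members:
            x += 1
        if x == 0:
            continue
        p = hypergeom_tail_enum(x, n_universe, big_k, k)
        if p < best_p - 1e-15:
            best_p, best_k = p, k
    return best_p, best_k


def leading_eigen(adj_matrix: np.ndarray):
    """Leading eigenpair of a symmetric matrix via numpy, eigenvector sign-fixed
    non-negative and max-normalized."""
    vals, vecs = np.linalg.eigh(adj_matrix)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    v = np.abs(v)
    return v / v.max(), float(vals[-1])


def random_bipartite_universe(rng, max_pathways=6, max_genes=20):
    """Random gene-set collection + all-significant table facts for oracle tests.

    Returns (pathway dict, gene list). Genes are G00..; every pathway gets
    1..5 members.
    """
    n_p = int(rng.integers(2, max_pathways + 1))
    n_g = int(rng.integers(4, max_genes + 1))
    genes = [f"G{i:03d}" for i in range(n_g)]
    pathways = {}
    for i in range(n_p):
        size = int(rng.integers(1, min(6, n_g) + 1))
        idx = rng.choice(n_g, size=size, replace=False)
        pathways[f"P{i:02d}"] = [genes[j] for j in sorted(idx)]
    return pathways, genes
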