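"""Three-parameter pathway prioritization against the autophagy anchor.

Each pathway is scored by (1) similarity of its expression-weighted network
impact to the anchor's, (2) strength of its connection to the anchor (gene
overlap blended with inverse hop distance), and (3) a key-regulator index
(eigenvector centrality on the shared-gene pathway projection).  A weighted
mean of the three gives the combined coefficient; pathways pass the listing
rule when it exceeds the configured threshold (strictly).  The module also
extracts minimum-node-distance chains from a query gene set (primary-cilium
genes) to the anchor pathway through the membership graph.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import deque
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .centrality import CentralityScore, node_removal_centrality
from .config import RunConfig
from .network import (
    DiffExpressionTable,
    HeteroNetwork,
    PathwayCollection,
    build_network,
    filter_significant,
    gene_node,
    pathway_node,
)

logger = logging.getLogger("ciliagraph")


@dataclasses.dataclass(frozen=True)
class PathwayPriorityRecord:
    """One pathway's scores against the anchor."""

    pathway: str
    impact: float
    similarity: float
    connection_strength: float
    key_regulator: float
    combined: float
    rank: int
    passes_threshold: bool


@dataclasses.dataclass
class ChainResult:
    """Shortest membership-graph chain from a gene set to a pathway node."""

    source_set: list[str]
    target: str
    reachable: bool
    distance: int | None = None
    chain: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    missing_sources: list[str] = dataclasses.field(default_factory=list)


# ---------------------------------------------------------------------------
# Parameter (1): expression-weighted impact and similarity to the anchor
# ---------------------------------------------------------------------------

def pathway_impact(
    pathway: str,
    net: HeteroNetwork,
    scores: Iterable[CentralityScore],
    table: DiffExpressionTable,
) -> float:
    """Mean over retained genes of (−removal score) · |log2fc|.

    Central genes (negative removal scores) with strong fold changes push a
    pathway's impact up; an empty retained set scores 0.
    """
    if pathway not in net.retained:
        raise ValueError(f"pathway {pathway!r} not in network")
    score_of = {s.gene: s.score for s in scores}
    lfc = table.log2fc_of()
    genes = sorted(net.retained[pathway])
    if not genes:
        return 0.0
    vals = [(-score_of[g]) * abs(lfc[g]) for g in genes]
    return float(np.mean(vals))


def similarity_to_anchor(
    impacts: Mapping[str, float], anchor: str
) -> dict[str, float]:
    """1 − min–max-normalized |impact − anchor impact|; anchor maps to 1.

    With fewer than two non-anchor pathways, or when every divergence is
    equal, every similarity is 1 (there is no spread to normalize).
    """
    if anchor not in impacts:
        raise ValueError(f"anchor {anchor!r} has no impact value")
    ref = impacts[anchor]
    others = sorted(p for p in impacts if p != anchor)
    out = {anchor: 1.0}
    if not others:
        return out
    d_raw = {p: abs(impacts[p] - ref) for p in others}
    lo, hi = min(d_raw.values()), max(d_raw.values())
    for p in others:
        out[p] = 1.0 if hi == lo else 1.0 - (d_raw[p] - lo) / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# Parameter (2): connection strength to the anchor
# ---------------------------------------------------------------------------

def _raw_connection(
    pathway: str, anchor: str, net: HeteroNetwork, overlap_weight: float
) -> float:
    sig_p = net.retained[pathway]
    sig_a = net.retained[anchor]
    shared = len(sig_p & sig_a)
    ochiai = shared / math.sqrt(len(sig_p) * len(sig_a)) if sig_p and sig_a else 0.0
    try:
        hop = nx.shortest_path_length(
            net.membership, pathway_node(pathway), pathway_node(anchor)
        )
        proximity = 1.0 / (1.0 + hop)
    except nx.NetworkXNoPath:
        proximity = 0.0
    return overlap_weight * ochiai + (1.0 - overlap_weight) * proximity


def connection_strengths(
    net: HeteroNetwork, anchor: str, overlap_weight: float = 0.5
) -> dict[str, float]:
    """Anchor connection strength for every pathway, min–max normalized.

    Raw strength blends the Ochiai coefficient of retained-gene overlap with
    inverse membership-graph hop distance (1/(1+hop); 0 when unreachable).
    Normalization excludes the anchor, which is 1 by convention.  When all
    raw values coincide, they map to 0 if nothing is connected (raw 0) and
    to 1 otherwise.
    """
    if anchor not in net.retained:
        raise ValueError(f"anchor {anchor!r} not in network")
    others = sorted(p for p in net.retained if p != anchor)
    out = {anchor: 1.0}
    if not others:
        return out
    raw = {p: _raw_connection(p, anchor, net, overlap_weight) for p in others}
    lo, hi = min(raw.values()), max(raw.values())
    for p in others:
        if hi == lo:
            out[p] = 0.0 if hi == 0.0 else 1.0
        else:
            out[p] = (raw[p] - lo) / (hi - lo)
    return out


def connection_strength(
    pathway: str, anchor: str, net: HeteroNetwork, overlap_weight: float = 0.5
) -> float:
    """Normalized anchor connection strength of one pathway."""
    return connection_strengths(net, anchor, overlap_weight)[pathway]


# ---------------------------------------------------------------------------
# Parameter (3): key-regulator index
# ---------------------------------------------------------------------------

def _power_iteration(adj: np.ndarray, tol: float = 1e-10, max_iter: int = 10000):
    """Leading eigenpair of a symmetric non-negative matrix.

    Iterates on adj + c·I (same eigenvectors, strictly dominant Perron value,
    immune to the ±λ oscillation of bipartite-structured components) and
    reports the unshifted eigenvalue.  The eigenvector is max-normalized.
    """
    n = adj.shape[0]
    shift = float(adj.sum(axis=1).max()) + 1.0
    mat = adj + shift * np.eye(n)
    v = np.full(n, 1.0 / n)
    lam = 0.0
    for _ in range(max_iter):
        w = mat @ v
        lam = float(w.max())
        w /= lam
        if np.max(np.abs(w - v)) < tol:
            v = w
            break
        v = w
    return v / v.max(), lam - shift


def key_regulator_index(net: HeteroNetwork) -> dict[str, float]:
    """Eigenvector centrality on the weighted pathway projection, max 1.

    Connected components are scored separately (the leading eigenvector of a
    disconnected graph lives on one component only); each component's
    max-normalized eigenvector is scaled by its Perron value relative to the
    largest, so the strongest hub scores 1 and equally-weighted components
    tie.  Isolated pathways score 0.
    """
    proj = net.projection
    out = {n[1]: 0.0 for n in proj.nodes}
    if proj.number_of_edges() == 0:
        logger.warning("pathway projection has no edges; key-regulator index all 0")
        return out
    comps = []
    for comp in nx.connected_components(proj):
        nodes = sorted(comp)
        if len(nodes) < 2:
            continue
        adj = nx.to_numpy_array(proj, nodelist=nodes, weight="weight")
        vec, lam = _power_iteration(adj)
        comps.append((nodes, vec, lam))
    lam_max = max(lam for _, _, lam in comps)
    for nodes, vec, lam in comps:
        scale = lam / lam_max if lam_max > 0 else 0.0
        for node, value in zip(nodes, vec):
            out[node[1]] = float(value * scale)
    return out


# ---------------------------------------------------------------------------
# Combination, ranking, chains
# ---------------------------------------------------------------------------

def combine_and_rank(
    impacts: Mapping[str, float],
    similarity: Mapping[str, float],
    strength: Mapping[str, float],
    key_regulator: Mapping[str, float],
    config: RunConfig,
) -> list[PathwayPriorityRecord]:
    """Weighted mean of the three components, ranked closest-first.

    The anchor is the reference and is excluded from the ranked list.  Ties
    break by similarity (descending) then pathway name.  ``passes_threshold``
    uses a strict ``>`` against ``config.combined_threshold``.
    """
    anchor = config.anchor_name
    names = sorted(p for p in similarity if p != anchor)
    w1, w2, w3 = config.weights
    rows = []
    for p in names:
        comps = (similarity[p], strength[p], key_regulator.get(p, 0.0))
        for label, c in zip(("similarity", "connection_strength", "key_regulator"), comps):
            if not -1e-12 <= c <= 1.0 + 1e-12:
                raise ValueError(f"{label} for {p!r} outside [0,1]: {c}")
        combined = w1 * comps[0] + w2 * comps[1] + w3 * comps[2]
        rows.append((p, comps, min(max(combined, 0.0), 1.0)))
    rows.sort(key=lambda r: (-r[2], -r[1][0], r[0]))
    return [
        PathwayPriorityRecord(
            pathway=p,
            impact=float(impacts.get(p, 0.0)),
            similarity=float(c[0]),
            connection_strength=float(c[1]),
            key_regulator=float(c[2]),
            combined=float(combined),
            rank=i + 1,
            passes_threshold=combined > config.combined_threshold,
        )
        for i, (p, c, combined) in enumerate(rows)
    ]


def prioritize_pathways(
    pathways: PathwayCollection,
    table: DiffExpressionTable,
    config: RunConfig,
) -> tuple[list[PathwayPriorityRecord], HeteroNetwork, list[CentralityScore]]:
    """Full prioritization pipeline: filter, build, score, combine, rank."""
    anchor = config.anchor_name or pathways.anchor_name
    if anchor is None:
        raise ValueError("no anchor pathway designated")
    pathways = dataclasses.replace(pathways, anchor_name=anchor)
    flagged = filter_significant(table, config.alpha_deg)
    net = build_network(pathways, flagged)
    scores = node_removal_centrality(net)
    impacts = {
        p: pathway_impact(p, net, scores, flagged) for p in sorted(net.retained)
    }
    sim = similarity_to_anchor(impacts, anchor)
    strength = connection_strengths(net, anchor, config.overlap_weight)
    kri = key_regulator_index(net)
    records = combine_and_rank(impacts, sim, strength, kri, config)
    return records, net, scores


def min_node_distance(
    source: Sequence[str], target: str, net: HeteroNetwork
) -> ChainResult:
    """Breadth-first minimum hop count from any source gene to a pathway node.

    Distances count membership-graph edges, so a gene inside the target
    pathway is at distance 1 and two pathways sharing a gene are 2 apart.
    Among equally short chains the lexicographically smallest node sequence
    is returned.  Source genes absent from the network are reported; only if
    all are absent is it an error.
    """
    if target not in net.retained:
        raise ValueError(f"target pathway {target!r} not in network")
    source = list(dict.fromkeys(source))
    if not source:
        raise ValueError("empty source gene set")
    present = [g for g in source if net.membership.has_node(gene_node(g))]
    missing = [g for g in source if g not in present]
    if not present:
        raise ValueError("no source gene is present in the network")
    if missing:
        logger.info("%d source genes absent from network", len(missing))

    target_node = pathway_node(target)
    dist = {target_node: 0}
    queue = deque([target_node])
    while queue:
        u = queue.popleft()
        for v in net.membership[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)

    reachable = [g for g in present if gene_node(g) in dist]
    if not reachable:
        return ChainResult(
            source_set=source, target=target, reachable=False,
            missing_sources=missing,
        )
    dmin = min(dist[gene_node(g)] for g in reachable)
    # lexicographically smallest shortest chain: greedy descent along dist
    start = min(gene_node(g) for g in reachable if dist[gene_node(g)] == dmin)
    chain = [start]
    current = start
    while dist[current] > 0:
        current = min(v for v in net.membership[current] if dist.get(v) == dist[current] - 1)
        chain.append(current)
    return ChainResult(
        source_set=source,
        target=target,
        reachable=True,
        distance=dmin,
        chain=chain,
        missing_sources=missing,
    )
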