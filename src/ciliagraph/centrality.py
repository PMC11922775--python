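"""Node-removal gene centrality and ordered-query enrichment.

A gene's importance is the change in global efficiency caused by deleting its
node from the membership graph: negative scores mean the network loses
connectedness without the gene (central), positive scores mean the remaining
graph is better connected (peripheral).  Central genes, ordered most-central
first, feed an ordered-query enrichment: for each pathway the minimum over
prefix lengths of the hypergeometric upper-tail probability, with
Benjamini–Hochberg correction across pathways.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .network import (
    GENE,
    DiffExpressionTable,
    HeteroNetwork,
    PathwayCollection,
    _adjacency,
    _efficiency_from_matrix,
)

logger = logging.getLogger("ciliagraph")


@dataclasses.dataclass(frozen=True)
class CentralityScore:
    """Removal impact of one gene: connectedness(M − gene) − connectedness(M)."""

    gene: str
    score: float
    degree: int  # membership degree, used only for deterministic tie-breaks

    @property
    def is_central(self) -> bool:
        return self.score < 0.0


@dataclasses.dataclass
class OrderedGeneList:
    """Genes ordered most-important-first, with expression directions.

    ``genes`` is the full ordering (ascending score: most negative first);
    ``central`` is the sublist with strictly negative scores, used for
    enrichment and for the coordinated-expression scan.
    """

    genes: list[str]
    central: list[str] | None = None
    directions: dict[str, int] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.central is None:
            self.central = list(self.genes)


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    """Best-prefix hypergeometric enrichment of one pathway."""

    pathway: str
    k_star: int  # prefix length attaining the minimum p (0 if no overlap)
    p: float
    q: float  # Benjamini–Hochberg adjusted


def node_removal_centrality(net: HeteroNetwork) -> list[CentralityScore]:
    """Score every gene by full recomputation of efficiency without its node.

    Pathway nodes are never removal candidates.  Scores are exact (no
    sampling); each removal recomputes all-pairs shortest paths on the
    remaining graph.
    """
    mat, nodes = _adjacency(net.membership)
    base = _efficiency_from_matrix(mat)
    dense = np.asarray(mat.todense())
    scores: list[CentralityScore] = []
    for idx, node in enumerate(nodes):
        if node[0] != GENE:
            continue
        keep = np.arange(len(nodes)) != idx
        sub = dense[np.ix_(keep, keep)]
        eff = _efficiency_from_matrix(sub)
        scores.append(
            CentralityScore(
                gene=node[1],
                score=eff - base,
                degree=int(net.membership.degree(node)),
            )
        )
    return scores


def rank_genes(
    scores: Iterable[CentralityScore],
    directions: dict[str, int] | None = None,
) -> OrderedGeneList:
    """Order genes ascending by score (most central first).

    Ties break by higher membership degree, then lexicographic gene id.
    The central sublist keeps only strictly negative scores; positive-score
    genes sit at the periphery of the network.
    """
    ordered = sorted(scores, key=lambda s: (s.score, -s.degree, s.gene))
    genes = [s.gene for s in ordered]
    central = [s.gene for s in ordered if s.is_central]
    if not central:
        logger.warning("no central genes: every removal score is non-negative")
    dirs = directions or {}
    return OrderedGeneList(
        genes=genes,
        central=central,
        directions={g: dirs.get(g, 0) for g in genes},
    )


def ordered_enrichment(
    ordered: OrderedGeneList | Sequence[str],
    pathways: PathwayCollection,
    universe: set[str],
) -> list[EnrichmentResult]:
    """Minimum-prefix hypergeometric enrichment over an ordered gene list.

    For each pathway with K members in the universe, and each prefix length
    k = 1..L of the ordered list, the upper-tail probability of seeing at
    least x_k pathway members among the top k genes is computed; the
    pathway's p is the minimum over k, attained at prefix length ``k_star``.
    Benjamini–Hochberg correction is applied across pathways.  Results are
    sorted by q, then p, then name.
    """
    genes = list(ordered.central) if isinstance(ordered, OrderedGeneList) else list(ordered)
    if not genes:
        raise ValueError("ordered gene list is empty")
    if len(set(genes)) != len(genes):
        raise ValueError("ordered gene list contains duplicates")
    missing = [g for g in genes if g not in universe]
    if missing:
        raise ValueError(f"ordered genes absent from universe: {missing[:5]}")
    n_universe = len(universe)
    if n_universe < len(genes):
        raise ValueError(
            f"universe ({n_universe}) smaller than ordered list ({len(genes)})"
        )

    names = list(pathways.pathways)
    ps: list[float] = []
    kstars: list[int] = []
    for name in names:
        members = set(pathways.members(name)) & universe
        big_k = len(members)
        best_p, best_k = 1.0, 0
        if big_k:
            x = 0
            for k, g in enumerate(genes, start=1):
                if g in members:
                    x += 1
                if x == 0:
                    continue
                p_k = float(stats.hypergeom.sf(x - 1, n_universe, big_k, k))
                if p_k < best_p - 1e-15:
                    best_p, best_k = p_k, k
        ps.append(min(best_p, 1.0))
        kstars.append(best_k)

    qs = stats.false_discovery_control(ps, method="bh") if ps else []
    results = [
        EnrichmentResult(pathway=name, k_star=k, p=p, q=max(float(q), p))
        for name, k, p, q in zip(names, kstars, ps, qs)
    ]
    return sorted(results, key=lambda r: (r.q, r.p, r.pathway))
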