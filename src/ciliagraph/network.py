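"""Differential-expression layer and the gene–pathway network.

The model is deliberately simple: the only relation the inputs (pathway gene
sets plus a differential-expression table) support is *membership*, so the
network is a bipartite graph whose nodes are retained significant genes and
the pathways containing them.  A weighted pathway projection (edge weight =
number of shared retained genes) summarises pathway crosstalk.

Connectedness is measured as global efficiency — the mean inverse shortest
path length over all node pairs — because it varies continuously as the graph
fragments, which downstream node-removal scoring needs.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger("ciliagraph")

# Node labels in the membership graph: ("gene", id) or ("pathway", name).
GENE = "gene"
PATHWAY = "pathway"


def gene_node(gene_id: str) -> tuple[str, str]:
    return (GENE, gene_id)


def pathway_node(name: str) -> tuple[str, str]:
    return (PATHWAY, name)


@dataclasses.dataclass
class DiffExpressionTable:
    """Per-feature log2 fold change and adjusted p, with significance flags.

    ``data`` holds columns ``feature_id``, ``log2fc``, ``p_adj``,
    ``significant`` (bool) and ``direction`` (sign of log2fc, in {-1, 0, +1}).
    Feature ids are unique, case-sensitive strings.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"feature_id", "log2fc", "p_adj"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"DEG table missing columns: {sorted(missing)}")
        dup = self.data["feature_id"].duplicated()
        if dup.any():
            names = self.data.loc[dup, "feature_id"].tolist()
            raise ValueError(f"duplicate feature ids: {names[:5]}")
        bad = ~self.data["p_adj"].between(0.0, 1.0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"p_adj outside [0,1] at row {row} "
                f"(feature {self.data['feature_id'].iloc[row]!r})"
            )
        if "significant" not in self.data.columns:
            self.data = self.data.assign(significant=False)
        if "direction" not in self.data.columns:
            self.data = self.data.assign(
                direction=np.sign(self.data["log2fc"]).astype(int)
            )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, float, float]]
    ) -> "DiffExpressionTable":
        """Build from (feature_id, log2fc, p_adj) triples."""
        df = pd.DataFrame(records, columns=["feature_id", "log2fc", "p_adj"])
        df["log2fc"] = df["log2fc"].astype(float)
        df["p_adj"] = df["p_adj"].astype(float)
        return cls(df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def feature_ids(self) -> list[str]:
        return self.data["feature_id"].tolist()

    def significant_ids(self) -> set[str]:
        return set(self.data.loc[self.data["significant"], "feature_id"])

    def directions(self) -> dict[str, int]:
        """feature_id -> sign of log2fc."""
        return dict(zip(self.data["feature_id"], self.data["direction"].astype(int)))

    def log2fc_of(self) -> dict[str, float]:
        return dict(zip(self.data["feature_id"], self.data["log2fc"].astype(float)))


@dataclasses.dataclass
class PathwayCollection:
    """Named gene sets with an optional anchor pathway and query gene set.

    Member lists are de-duplicated but order-preserving; pathway names are
    unique and keep input order.
    """

    pathways: dict[str, list[str]]
    anchor_name: str | None = None
    query_set: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        deduped: dict[str, list[str]] = {}
        for name, members in self.pathways.items():
            deduped[name] = list(dict.fromkeys(members))
        self.pathways = deduped
        if self.anchor_name is not None and self.anchor_name not in self.pathways:
            raise ValueError(f"anchor pathway {self.anchor_name!r} not in collection")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def members(self, name: str) -> list[str]:
        return self.pathways[name]

    def universe(self) -> set[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for members in self.pathways.values():
            out.update(members)
        return out


@dataclasses.dataclass
class HeteroNetwork:
    """Bipartite membership graph plus its weighted pathway projection.

    ``membership`` links each retained significant gene to the pathways that
    contain it; there are no gene–gene or pathway–pathway edges.  In
    ``projection`` the weight of (p, q) is the exact count of retained genes
    the two pathways share.
    """

    membership: nx.Graph
    projection: nx.Graph
    retained: dict[str, set[str]]  # pathway -> retained significant members
    orphan_significant: list[str]  # significant genes in no loaded pathway
    anchor_name: str | None = None

    def gene_nodes(self) -> list[tuple[str, str]]:
        return sorted(n for n in self.membership if n[0] == GENE)

    def pathway_nodes(self) -> list[tuple[str, str]]:
        return sorted(n for n in self.membership if n[0] == PATHWAY)

    def pathway_names(self) -> list[str]:
        return [n[1] for n in self.pathway_nodes()]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filter_significant(table: DiffExpressionTable, alpha: float) -> DiffExpressionTable:
    """Flag features with ``p_adj < alpha`` (strict) as significant.

    Returns a new table; values other than the flags are unchanged.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    df = table.data.copy()
    df["significant"] = df["p_adj"] < alpha
    df["direction"] = np.sign(df["log2fc"]).astype(int)
    return DiffExpressionTable(df)


def build_network(
    pathways: PathwayCollection, table: DiffExpressionTable
) -> HeteroNetwork:
    """Build the membership graph over retained significant genes.

    Pathways with no retained gene are omitted; significant genes belonging
    to no loaded pathway are excluded from the graph and reported.  Raises if
    the anchor pathway (when designated) retains no gene, since every
    downstream comparison is made against it.
    """
    sig = table.significant_ids()
    retained: dict[str, set[str]] = {}
    for name, members in pathways.pathways.items():
        kept = sig.intersection(members)
        if kept:
            retained[name] = kept
    if pathways.anchor_name is not None and pathways.anchor_name not in retained:
        raise ValueError(
            f"anchor pathway {pathways.anchor_name!r} retains no significant gene"
        )

    membership = nx.Graph()
    for name in retained:
        membership.add_node(pathway_node(name), kind=PATHWAY)
    covered: set[str] = set()
    for name, kept in retained.items():
        for g in kept:
            membership.add_node(gene_node(g), kind=GENE)
            membership.add_edge(gene_node(g), pathway_node(name))
            covered.add(g)
    orphans = sorted(sig - covered)
    if orphans:
        logger.info("%d significant genes belong to no loaded pathway", len(orphans))

    projection = nx.Graph()
    names = sorted(retained)
    projection.add_nodes_from(pathway_node(n) for n in names)
    for i, p in enumerate(names):
        for q in names[i + 1 :]:
            shared = len(retained[p] & retained[q])
            if shared:
                projection.add_edge(pathway_node(p), pathway_node(q), weight=shared)

    return HeteroNetwork(
        membership=membership,
        projection=projection,
        retained=retained,
        orphan_significant=orphans,
        anchor_name=pathways.anchor_name,
    )


def _efficiency_from_matrix(adjacency: "np.ndarray | object") -> float:
    """Global efficiency from a (sparse or dense) adjacency matrix."""
    n = adjacency.shape[0]
    if n < 2:
        return 0.0
    dist = shortest_path(adjacency, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[np.isinf(dist)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _adjacency(graph: nx.Graph) -> tuple["object", list]:
    nodes = sorted(graph.nodes())
    mat = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight=None, format="csr")
    return mat, nodes


def connectedness(graph: nx.Graph) -> float:
    """Global efficiency: mean over unordered node pairs of 1/d(u, v).

    Unreachable pairs contribute 0; graphs with fewer than two nodes score 0.
    Lies in [0, 1]; equals 1 iff the graph is complete, 0 iff it has no edge.
    """
    if graph.number_of_nodes() == 0:
        return 0.0
    mat, _ = _adjacency(graph)
    return _efficiency_from_matrix(mat)


def write_edge_list(net: HeteroNetwork, path) -> None:
    """Dump membership and projection edges as TSV for external viewers."""
    rows = []
    for u, v in sorted(net.membership.edges()):
        a, b = sorted((u, v))
        rows.append((a[1], b[1], "membership", 1))
    for u, v, w in sorted(net.projection.edges(data="weight")):
        a, b = sorted((u, v))
        rows.append((a[1], b[1], "projection", w))
    pd.DataFrame(rows, columns=["node1", "node2", "kind", "weight"]).to_csv(
        path, sep="\t", index=False
    )
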