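import numpy as np
import pytest

import ciliagraph as cg


@pytest.fixture
def tiny_collection() -> cg.PathwayCollection:
    """Two overlapping gene sets A={g1,g2}, B={g2,g3}."""
    return cg.PathwayCollection(
        pathways={"A": ["g1", "g2"], "B": ["g2", "g3"]}, anchor_name="A"
    )


@pytest.fixture
def tiny_table() -> cg.DiffExpressionTable:
    """Three features, all significant at alpha=0.05."""
    return cg.DiffExpressionTable.from_records(
        [("g1", 1.0, 0.01), ("g2", -2.0, 0.001), ("g3", 0.5, 0.04)]
    )


@pytest.fixture
def tiny_network(tiny_collection, tiny_table) -> cg.HeteroNetwork:
    flagged = cg.filter_significant(tiny_table, 0.05)
    return cg.build_network(tiny_collection, flagged)


def make_network(pathways: dict, significant: set[str], anchor=None,
                 log2fc: dict | None = None) -> tuple:
    """Build a network from explicit gene sets and a significance set."""
    genes = sorted({g for m in pathways.values() for g in m})
    records = []
    for g in genes:
        sig = g in significant
        records.append((g, (log2fc or {}).get(g, 1.0), 0.01 if sig else 0.5))
    table = cg.DiffExpressionTable.from_records(records)
    flagged = cg.filter_significant(table, 0.05)
    collection = cg.PathwayCollection(pathways=pathways, anchor_name=anchor)
    return cg.build_network(collection, flagged), flagged, collection


@pytest.fixture
def recovery_spec():
    """Scaled synthetic universe used for planted-structure recovery."""
    def _spec(seed: int) -> cg.SyntheticSpec:
        return cg.SyntheticSpec(
            seed=seed,
            n_genes=250,
            n_pathways=25,
            frac_significant=0.4,
            planted_near_pathway="near_anchor",
            planted_far_pathway="far_pathway",
            planted_regulator_gene="G0007",
            planted_zone=(41, 30, +1),
        )
    return _spec
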