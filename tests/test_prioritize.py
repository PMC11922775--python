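"""Three-parameter pathway prioritization and minimum-node-distance chains."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

import ciliagraph as cg
from conftest import make_network
from oracles import leading_eigen, min_distance, random_bipartite_universe


class TestPathwayImpact:
    def test_zero_scores_zero_impact(self):
        net, flagged, _ = make_network(
            {"A": ["g1", "g2"]}, significant={"g1", "g2"}
        )
        scores = [
            cg.CentralityScore("g1", 0.0, 1), cg.CentralityScore("g2", 0.0, 1)
        ]
        assert cg.pathway_impact("A", net, scores, flagged) == 0.0

    def test_single_gene_arithmetic(self):
        net, flagged, _ = make_network(
            {"A": ["g1"]}, significant={"g1"}, log2fc={"g1": 2.0}
        )
        scores = [cg.CentralityScore("g1", -0.5, 1)]
        assert cg.pathway_impact("A", net, scores, flagged) == pytest.approx(1.0)

    def test_unknown_pathway_rejected(self, tiny_network, tiny_table):
        with pytest.raises(ValueError, match="not in network"):
            cg.pathway_impact("missing", tiny_network, [], tiny_table)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(21)
        pathways, genes = random_bipartite_universe(rng, max_pathways=5)
        lfc = {g: float(rng.normal(0, 2)) for g in genes}
        net, flagged, _ = make_network(pathways, significant=set(genes), log2fc=lfc)
        scores = cg.node_removal_centrality(net)
        score_of = {s.gene: s.score for s in scores}
        for p, kept in net.retained.items():
            expected = np.mean([(-score_of[g]) * abs(lfc[g]) for g in kept])
            assert cg.pathway_impact(p, net, scores, flagged) == pytest.approx(
                expected, rel=1e-12
            )


class TestSimilarityToAnchor:
    def test_anchor_maps_to_one(self):
        sim = cg.similarity_to_anchor({"anchor": 2.0, "p": 3.0}, "anchor")
        assert sim["anchor"] == 1.0

    def test_minmax_endpoints(self):
        sim = cg.similarity_to_anchor({"anchor": 2.0, "p": 2.0, "q": 5.0}, "anchor")
        assert sim["p"] == 1.0 and sim["q"] == 0.0

    def test_middle_pathway_strictly_between(self):
        sim = cg.similarity_to_anchor(
            {"anchor": 0.0, "p": 1.0, "q": 2.0, "r": 4.0}, "anchor"
        )
        assert sim["p"] == 1.0 and sim["r"] == 0.0
        assert 0.0 < sim["q"] < 1.0
        assert sim["q"] == pytest.approx(1.0 - (2.0 - 1.0) / (4.0 - 1.0))

    def test_single_pathway_defaults_to_one(self):
        assert cg.similarity_to_anchor({"anchor": 1.0}, "anchor") == {"anchor": 1.0}


class TestConnectionStrength:
    def test_full_overlap_raw_value(self):
        from ciliagraph.prioritize import _raw_connection

        net, _, _ = make_network(
            {"anchor": ["g1", "g2"], "p": ["g1", "g2"], "q": ["g3"]},
            significant={"g1", "g2", "g3"},
            anchor="anchor",
        )
        raw = _raw_connection("p", "anchor", net, overlap_weight=0.5)
        assert raw == pytest.approx(0.5 * 1.0 + 0.5 * (1.0 / 3.0))

    def test_disconnected_pathway_is_zero(self):
        net, _, _ = make_network(
            {"anchor": ["g1", "g2"], "p": ["g1"], "q": ["g9"]},
            significant={"g1", "g2", "g9"},
            anchor="anchor",
        )
        strengths = cg.connection_strengths(net, "anchor")
        assert strengths["q"] == 0.0
        assert strengths["p"] == 1.0  # sole connected pathway spans the minmax

    def test_anchor_is_one_by_convention(self, tiny_network):
        assert cg.connection_strengths(tiny_network, "A")["A"] == 1.0


class TestKeyRegulatorIndex:
    def test_star_hub_dominates(self):
        # hub shares genes with three leaves; leaves share nothing
        pathways = {
            "hub": ["a", "b", "c"],
            "l1": ["a", "x1"],
            "l2": ["b", "x2"],
            "l3": ["c", "x3"],
        }
        net, _, _ = make_network(pathways, significant={"a", "b", "c", "x1", "x2", "x3"})
        kri = cg.key_regulator_index(net)
        assert kri["hub"] == pytest.approx(1.0)
        leaves = [kri["l1"], kri["l2"], kri["l3"]]
        assert all(0 < v < 1 for v in leaves)
        assert leaves[0] == pytest.approx(leaves[1]) == pytest.approx(leaves[2])
        # closed-form star eigenvector: leaf/hub ratio is 1/sqrt(3)
        assert leaves[0] == pytest.approx(1 / np.sqrt(3), rel=1e-8)

    def test_isolated_pathway_zero(self):
        net, _, _ = make_network(
            {"A": ["g1", "g2"], "B": ["g2", "g3"], "C": ["g9"]},
            significant={"g1", "g2", "g3", "g9"},
        )
        assert cg.key_regulator_index(net)["C"] == 0.0

    def test_equal_disconnected_pairs_tie_at_one(self):
        net, _, _ = make_network(
            {"A": ["s", "x"], "B": ["s", "y"], "C": ["t", "u"], "D": ["t", "v"]},
            significant={"s", "t", "x", "y", "u", "v"},
        )
        kri = cg.key_regulator_index(net)
        assert kri == pytest.approx({"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0})

    def test_matches_dense_eigensolver_blockwise(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            pathways, genes = random_bipartite_universe(rng)
            net, _, _ = make_network(pathways, significant=set(genes))
            proj = net.projection
            if proj.number_of_edges() == 0:
                continue
            kri = cg.key_regulator_index(net)
            comps = []
            for comp in nx.connected_components(proj):
                nodes = sorted(comp)
                if len(nodes) < 2:
                    continue
                adj = nx.to_numpy_array(proj, nodelist=nodes, weight="weight")
                vec, lam = leading_eigen(adj)
                comps.append((nodes, vec, lam))
            lam_max = max(l for _, _, l in comps)
            for nodes, vec, lam in comps:
                for node, v in zip(nodes, vec):
                    assert kri[node[1]] == pytest.approx(
                        v * lam / lam_max, abs=1e-8
                    )


class TestCombineAndRank:
    def _config(self, **kw):
        return cg.RunConfig(anchor_name="anchor", **kw)

    def _rank(self, comps, config=None):
        names = list(comps)
        sim = {"anchor": 1.0, **{p: c[0] for p, c in comps.items()}}
        strength = {p: c[1] for p, c in comps.items()}
        kri = {p: c[2] for p, c in comps.items()}
        return cg.combine_and_rank({}, sim, strength, kri, config or self._config())

    def test_perfect_components_rank_first(self):
        recs = self._rank({"p": (1.0, 1.0, 1.0), "q": (0.1, 0.1, 0.1)})
        assert recs[0].pathway == "p"
        assert recs[0].combined == pytest.approx(1.0)
        assert recs[0].rank == 1 and recs[0].passes_threshold

    def test_exactly_threshold_fails(self):
        (rec,) = self._rank({"p": (0.35, 0.35, 0.35)})
        assert rec.combined == pytest.approx(0.35)
        assert not rec.passes_threshold

    def test_monotone_in_each_component(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            base = rng.uniform(size=3)
            (rec0,) = self._rank({"p": tuple(base)})
            j = int(rng.integers(3))
            bumped = base.copy()
            bumped[j] = min(1.0, bumped[j] + rng.uniform(0.01, 0.3))
            (rec1,) = self._rank({"p": tuple(bumped)})
            if bumped[j] > base[j]:
                assert rec1.combined > rec0.combined

    def test_component_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            self._rank({"p": (1.2, 0.5, 0.5)})

    def test_anchor_excluded_from_ranking(self):
        recs = self._rank({"p": (0.5, 0.5, 0.5)})
        assert [r.pathway for r in recs] == ["p"]


class TestMinNodeDistance:
    def test_member_gene_distance_one(self, tiny_network):
        res = cg.min_node_distance(["g1"], "A", tiny_network)
        assert res.reachable and res.distance == 1
        assert res.chain == [cg.gene_node("g1"), cg.pathway_node("A")]

    def test_cilium_to_autophagy_chain_through_kinase(self):
        """Toy mirror of the ciliary-kinesin to autophagy link: the cilium
        motor gene reaches autophagy only through a shared pathway and the
        kinase gene sitting in both."""
        net, _, _ = make_network(
            {
                "cAMP": ["Kif3a", "Prkaca"],
                "Autophagy": ["Prkaca", "Ulk1"],
            },
            significant={"Kif3a", "Prkaca", "Ulk1"},
            anchor="Autophagy",
        )
        res = cg.min_node_distance(["Kif3a"], "Autophagy", net)
        assert res.distance == 3
        assert res.chain == [
            cg.gene_node("Kif3a"),
            cg.pathway_node("cAMP"),
            cg.gene_node("Prkaca"),
            cg.pathway_node("Autophagy"),
        ]

    def test_disconnected_source_unreachable(self):
        net, _, _ = make_network(
            {"A": ["g1"], "B": ["g9"]}, significant={"g1", "g9"}
        )
        res = cg.min_node_distance(["g9"], "A", net)
        assert not res.reachable and res.distance is None

    def test_absent_sources_reported_all_absent_fatal(self, tiny_network):
        res = cg.min_node_distance(["nope", "g1"], "A", tiny_network)
        assert res.missing_sources == ["nope"] and res.distance == 1
        with pytest.raises(ValueError, match="no source gene"):
            cg.min_node_distance(["nope"], "A", tiny_network)

    def test_agrees_with_all_pairs_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            pathways, genes = random_bipartite_universe(rng, max_pathways=8, max_genes=25)
            net, _, _ = make_network(pathways, significant=set(genes))
            assert net.membership.number_of_nodes() <= 40
            names = sorted(net.retained)
            target = names[int(rng.integers(len(names)))]
            in_net = [g for g in genes if net.membership.has_node(cg.gene_node(g))]
            k = int(rng.integers(1, min(4, len(in_net)) + 1))
            sources = [in_net[i] for i in rng.choice(len(in_net), size=k, replace=False)]
            expected = min_distance(
                net.membership, [cg.gene_node(g) for g in sources],
                cg.pathway_node(target),
            )
            res = cg.min_node_distance(sources, target, net)
            if expected is None:
                assert not res.reachable
            else:
                assert res.distance == expected
                assert len(res.chain) - 1 == expected


class TestPlantedRecovery:
    def test_near_pathway_outranks_far(self, recovery_spec):
        wins = 0
        for seed in range(20):
            col, table, truth = cg.generate_universe(recovery_spec(seed))
            records, _, _ = cg.prioritize_pathways(
                col, table, cg.RunConfig(anchor_name="autophagy")
            )
            by_name = {r.pathway: r for r in records}
            near, far = by_name["near_anchor"], by_name["far_pathway"]
            assert not far.passes_threshold  # disconnected: combined ≤ 1/3
            if near.rank < far.rank:
                wins += 1
        assert wins >= 19  # ≥95% of 20 seeds

    def test_regulator_in_top3_centrality(self, recovery_spec):
        wins = 0
        for seed in range(20):
            col, table, truth = cg.generate_universe(recovery_spec(seed))
            flagged = cg.filter_significant(table, 0.05)
            net = cg.build_network(col, flagged)
            order = cg.rank_genes(
                cg.node_removal_centrality(net), flagged.directions()
            )
            if truth.regulator_gene in order.genes[:3]:
                wins += 1
        assert wins >= 19
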