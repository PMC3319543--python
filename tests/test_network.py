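import itertools
import logging
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pathmarker import (BetweennessTable, build_graph,
                        path_gene_betweenness, permutation_test,
                        seed_pair_shortest_paths, simulate_network)
from pathmarker.network import exact_permutation_pvalues
from conftest import make_edge_table


class TestBuildGraph:
    def test_complement_transform_thousand_scale(self):
        g = build_graph(make_edge_table([("A", "B", 900)]))
        assert g["A"]["B"]["weight"] == pytest.approx(100.0)

    def test_weight_ordering_inverts_confidence(self):
        g = build_graph(make_edge_table([("A", "B", 999), ("B", "C", 150)]))
        assert g["A"]["B"]["weight"] == pytest.approx(1.0)
        assert g["B"]["C"]["weight"] == pytest.approx(850.0)

    def test_unit_scale(self):
        g = build_graph(make_edge_table([("A", "B", 0.9)], scale="unit"))
        assert g["A"]["B"]["weight"] == pytest.approx(0.1)

    def test_score_at_cmax_rejected(self):
        et = make_edge_table([("A", "B", 999)])
        et.edges.loc[0, "score"] = 1000.0  # bypass table validation
        with pytest.raises(ValueError, match="non-positive"):
            build_graph(et)

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError, match="transform"):
            build_graph(make_edge_table([("A", "B", 900)]), transform="bogus")

    def test_high_confidence_route_beats_short_low_confidence(self):
        """Six-node fixture: the 3-hop high-confidence route must cost less
        than the 1-hop low-confidence edge, checked against exhaustive
        enumeration of every simple path."""
        et = make_edge_table([
            ("S", "T", 150),            # direct but weak: cost 850
            ("S", "A", 950), ("A", "B", 950), ("B", "T", 950),  # cost 150
            ("S", "C", 400), ("C", "T", 400),                   # cost 1200
        ])
        g = build_graph(et)
        best = min(
            (sum(g[u][v]["weight"] for u, v in itertools.pairwise(p)), p)
            for p in nx.all_simple_paths(g, "S", "T"))
        assert best[1] == ["S", "A", "B", "T"]
        rec = seed_pair_shortest_paths(g, ["S", "T"])[0]
        assert rec.nodes == ["S", "A", "B", "T"]
        assert rec.cost == pytest.approx(best[0]) == pytest.approx(150.0)


class TestSeedPairPaths:
    def test_six_seeds_give_fifteen_paths(self, planted_network):
        et, truth = planted_network
        g = build_graph(et)
        records = seed_pair_shortest_paths(g, truth.seed_gene_ids)
        assert len(records) == math.comb(6, 2) == 15
        assert all(r.reachable for r in records)

    def test_direct_cheap_edge_is_two_node_path(self):
        g = build_graph(make_edge_table([("A", "B", 990), ("A", "C", 500),
                                         ("C", "B", 500)]))
        rec = seed_pair_shortest_paths(g, ["A", "B"])[0]
        assert rec.nodes == ["A", "B"]

    def test_absent_seed_named_in_error(self):
        g = build_graph(make_edge_table([("A", "B", 900)]))
        with pytest.raises(KeyError, match="ZZZ"):
            seed_pair_shortest_paths(g, ["A", "ZZZ"])

    def test_disconnected_pair_flagged(self, caplog):
        g = build_graph(make_edge_table([("A", "B", 900), ("C", "D", 900)]))
        with caplog.at_level(logging.WARNING):
            records = seed_pair_shortest_paths(g, ["A", "C"])
        assert not records[0].reachable
        assert "disconnected" in caplog.text
        # unreachable pairs contribute nothing to betweenness
        bt = path_gene_betweenness(records, ["A", "C"])
        assert len(bt) == 0

    @pytest.mark.parametrize("seed", range(25))
    def test_costs_match_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        p = rng.uniform(0.1, 0.4)
        triples = []
        nodes = [f"n{i:02d}" for i in range(n)]
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < p or j == i + 1:  # chain keeps it connected
                triples.append((nodes[i], nodes[j],
                                float(rng.integers(100, 999))))
        g = build_graph(make_edge_table(triples))
        k = int(rng.integers(2, 6))
        seeds = [nodes[i] for i in rng.choice(n, size=k, replace=False)]
        fw = nx.floyd_warshall(g, weight="weight")
        for rec in seed_pair_shortest_paths(g, seeds):
            assert rec.cost == pytest.approx(fw[rec.source][rec.target])
            # and the recorded node sequence realizes that cost
            path_cost = sum(g[u][v]["weight"]
                            for u, v in itertools.pairwise(rec.nodes))
            assert path_cost == pytest.approx(rec.cost)

    def test_lexicographic_tie_break(self):
        # two co-optimal routes A-M-B and A-Z-B; the lexicographically
        # smaller interior node must be chosen deterministically
        g = build_graph(make_edge_table([("A", "M", 900), ("M", "B", 900),
                                         ("A", "Z", 900), ("Z", "B", 900)]))
        rec = seed_pair_shortest_paths(g, ["A", "B"])[0]
        assert rec.nodes == ["A", "M", "B"]
        both = seed_pair_shortest_paths(g, ["A", "B"], tie_mode="all")[0]
        assert sorted(p[1] for p in both.all_paths) == ["M", "Z"]
        bt = path_gene_betweenness([both], ["A", "B"])
        assert set(bt.table["gene"]) == {"M", "Z"}


class TestBetweenness:
    def test_star_graph_center_collects_all_pairs(self):
        k = 5
        triples = [(f"L{i}", "center", 900) for i in range(k)]
        g = build_graph(make_edge_table(triples))
        seeds = [f"L{i}" for i in range(k)]
        records = seed_pair_shortest_paths(g, seeds)
        bt = path_gene_betweenness(records, seeds)
        assert bt.table.iloc[0]["gene"] == "center"
        assert bt.table.iloc[0]["betweenness"] == math.comb(k, 2)

    def test_seeds_never_listed_and_bound_holds(self, planted_network):
        et, truth = planted_network
        g = build_graph(et)
        seeds = truth.seed_gene_ids
        records = seed_pair_shortest_paths(g, seeds)
        bt = path_gene_betweenness(records, seeds)
        assert not set(bt.table["gene"]) & set(seeds)
        assert bt.table["betweenness"].max() <= math.comb(len(seeds), 2)
        assert (bt.table["betweenness"] > 0).all()

    def test_planted_hub_tops_table_with_designed_count(self, planted_network):
        et, truth = planted_network
        g = build_graph(et)
        records = seed_pair_shortest_paths(g, truth.seed_gene_ids)
        bt = path_gene_betweenness(records, truth.seed_gene_ids)
        assert bt.table.iloc[0]["gene"] == truth.planted_hub_id
        assert bt.table.iloc[0]["betweenness"] == truth.hub_betweenness == 7
        # recovered paths are exactly the designed backbones
        for rec in records:
            assert rec.nodes == truth.backbone_paths[(rec.source, rec.target)]


class TestPermutation:
    def _observed(self, gene, b):
        return BetweennessTable(pd.DataFrame({"gene": [gene],
                                              "betweenness": [b]}))

    def test_gene_always_exceeding_gets_p_one(self):
        # center of a star lies on every permuted pair's path
        triples = [(f"L{i}", "center", 900) for i in range(4)]
        g = build_graph(make_edge_table(triples))
        bt = permutation_test(g, k=2, observed=self._observed("center", 1),
                              n_perm=200, rng_seed=1,
                              exclude=["center"])
        assert bt.table["p_value"].iloc[0] == 1.0

    def test_gene_never_on_paths_gets_p_zero(self):
        # leaf node is never interior to any shortest path
        triples = [(f"L{i}", "center", 900) for i in range(4)]
        g = build_graph(make_edge_table(triples))
        bt = permutation_test(g, k=2, observed=self._observed("L0", 1),
                              n_perm=200, rng_seed=1)
        assert bt.table["p_value"].iloc[0] == 0.0

    def test_k_larger_than_node_count_rejected(self):
        g = build_graph(make_edge_table([("A", "B", 900)]))
        with pytest.raises(ValueError):
            permutation_test(g, k=3, observed=self._observed("A", 1),
                             n_perm=10)

    def test_determinism_under_seed(self, planted_network):
        et, truth = planted_network
        g = build_graph(et)
        records = seed_pair_shortest_paths(g, truth.seed_gene_ids)
        obs = path_gene_betweenness(records, truth.seed_gene_ids)
        a = permutation_test(g, 6, obs, n_perm=50, rng_seed=9)
        b = permutation_test(g, 6, obs, n_perm=50, rng_seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        """8-node graph, k = 2: Monte-Carlo p-values at 2000 permutations
        lie within 3 binomial SEs of the exact values enumerated over all
        C(8,2) seed subsets."""
        # chain n0..n7 with strong links plus weak chords: the n0-n4 route
        # follows the chain, so interior genes exist
        nodes = [f"n{i}" for i in range(8)]
        triples = [(nodes[i], nodes[i + 1], 900.0) for i in range(7)]
        triples += [("n0", "n3", 400.0), ("n2", "n6", 350.0),
                    ("n1", "n5", 300.0), ("n4", "n7", 450.0)]
        g = build_graph(make_edge_table(triples))
        seeds = ["n0", "n4"]
        obs = path_gene_betweenness(seed_pair_shortest_paths(g, seeds),
                                    seeds)
        assert len(obs) >= 1
        n_perm = 2000
        mc = permutation_test(g, 2, obs, n_perm=n_perm, rng_seed=3)
        exact = exact_permutation_pvalues(g, 2, obs)
        for gene in obs.table["gene"]:
            p_mc = float(mc.table.set_index("gene").loc[gene, "p_value"])
            p_ex = float(exact.table.set_index("gene").loc[gene, "p_value"])
            se = math.sqrt(max(p_ex * (1 - p_ex), 1 / n_perm) / n_perm)
            assert abs(p_mc - p_ex) <= 3 * se

    def test_planted_hub_has_minimal_p(self, planted_network):
        et, truth = planted_network
        g = build_graph(et)
        records = seed_pair_shortest_paths(g, truth.seed_gene_ids)
        obs = path_gene_betweenness(records, truth.seed_gene_ids)
        bt = permutation_test(g, 6, obs, n_perm=300, rng_seed=5)
        table = bt.table.set_index("gene")
        p_hub = float(table.loc[truth.planted_hub_id, "p_value"])
        assert p_hub == table["p_value"].min()

    def test_null_calibration_uniformish(self):
        """On a structureless random graph, the p-value of a gene designated
        BEFORE seeing the seed draw (its observed betweenness may be 0, in
        which case p = 1) is a valid, approximately uniform p-value."""
        from pathmarker.network import _betweenness_counts
        pvals = []
        for rep in range(60):
            rng = np.random.default_rng(1000 + rep)
            nodes = [f"n{i}" for i in range(12)]
            triples = []
            for i, j in itertools.combinations(range(12), 2):
                if rng.random() < 0.35 or j == i + 1:
                    triples.append((nodes[i], nodes[j],
                                    float(rng.integers(200, 990))))
            g = build_graph(make_edge_table(triples))
            picked = rng.choice(12, 4, replace=False)
            gene = nodes[picked[0]]              # designated up front
            seeds = [nodes[i] for i in picked[1:]]
            b_obs = _betweenness_counts(g, seeds, {gene})[gene]
            if b_obs == 0:
                pvals.append(1.0)  # every permutation attains >= 0
                continue
            obs = BetweennessTable(pd.DataFrame({"gene": [gene],
                                                 "betweenness": [b_obs]}))
            bt = permutation_test(g, 3, obs, n_perm=100,
                                  rng_seed=int(rng.integers(2**31)))
            pvals.append(float(bt.table["p_value"].iloc[0]))
        # discrete permutation p-values are super-uniform; reject only
        # clear anti-conservatism
        ks = sps.kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01
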