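import itertools

import numpy as np
import pytest
from scipy import stats

from funcpred.network import (
    ConvergenceError,
    personalized_pagerank,
    preranked_gsea,
    validate_predictions,
)
from funcpred.types import PPIGraph

from .conftest import random_graph
from .oracles import dense_pagerank, naive_enrichment_score


class TestPersonalizedPageRank:
    def test_two_node_closed_form(self):
        g = PPIGraph(["a", "b"], [("a", "b", 1000)])
        pr = personalized_pagerank(g, {"a"}, damping=0.85, tol=1e-14)
        alpha = 0.85
        assert abs(pr.scores["a"] - 1 / (1 + alpha)) < 1e-12
        assert abs(pr.scores["b"] - alpha / (1 + alpha)) < 1e-12

    def test_all_seeds_on_regular_graph_uniform(self):
        # a 6-cycle is 2-regular; seeding every node gives the uniform vector
        nodes = [f"n{i}" for i in range(6)]
        edges = [(nodes[i], nodes[(i + 1) % 6], 1000) for i in range(6)]
        pr = personalized_pagerank(PPIGraph(nodes, edges), nodes)
        np.testing.assert_allclose(list(pr.scores.values()), 1 / 6, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_dense_oracle(self, seed):
        g = random_graph(50, 0.1, seed)
        pr = personalized_pagerank(g, {"n000", "n001", "n002"}, tol=1e-13)
        nodes, a = g.adjacency()
        r = dense_pagerank(a.toarray(), [0, 1, 2], 0.85)
        got = np.array([pr.scores[n] for n in nodes])
        assert np.abs(got - r).max() < 1e-8

    def test_mass_conservation(self):
        g = random_graph(40, 0.08, 5)
        tol = 1e-10
        pr = personalized_pagerank(g, {"n000"}, tol=tol)
        assert abs(sum(pr.scores.values()) - 1) < 10 * tol

    def test_seed_absent_from_graph_is_error(self):
        g = PPIGraph(["a", "b"], [("a", "b", 500)])
        with pytest.raises(ValueError, match="seed"):
            personalized_pagerank(g, {"zzz"})

    def test_non_convergence_reports_iterations(self):
        g = random_graph(30, 0.2, 7)
        with pytest.raises(ConvergenceError, match="2"):
            personalized_pagerank(g, {"n000"}, tol=1e-12, max_iter=2)

    def test_edge_to_seed_neighbour_monotone_on_trees(self):
        """Adding an edge seed-x to a random tree never decreases r(x)."""
        rng = np.random.default_rng(11)
        for trial in range(10):
            n = int(rng.integers(5, 21))
            nodes = [f"n{i:02d}" for i in range(n)]
            edges = [
                (nodes[i], nodes[int(rng.integers(0, i))], 800) for i in range(1, n)
            ]
            g = PPIGraph(nodes, edges)
            seed_node = nodes[0]
            adjacent = {u if v == seed_node else v
                        for (u, v) in g.edges if seed_node in (u, v)}
            candidates = [x for x in nodes[1:] if x not in adjacent]
            if not candidates:
                continue
            x = candidates[int(rng.integers(0, len(candidates)))]
            before = personalized_pagerank(g, {seed_node}, tol=1e-13).scores[x]
            new_edges = [(u, v, s) for (u, v), s in g.edges.items()]
            new_edges.append((seed_node, x, 800))
            g2 = PPIGraph(nodes, new_edges)
            after = personalized_pagerank(g2, {seed_node}, tol=1e-13).scores[x]
            assert after >= before - 1e-12


class TestPrerankedGSEA:
    def _ranking(self, n=10):
        return {f"x{i:02d}": float(2 * n - i) for i in range(n)}

    def test_top_block_gives_plus_one(self):
        rk = self._ranking()
        res = preranked_gsea(rk, {"x00", "x01", "x02"}, n_permutations=50, seed=0)
        assert res.es == pytest.approx(1.0)

    def test_bottom_block_gives_minus_one(self):
        rk = self._ranking()
        res = preranked_gsea(rk, {"x07", "x08", "x09"}, n_permutations=50, seed=0)
        assert res.es == pytest.approx(-1.0)

    def test_hand_computed_single_hit(self):
        rk = {"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0}
        res = preranked_gsea(rk, {"g2"}, n_permutations=50, seed=0)
        assert res.es == pytest.approx(2 / 3)

    def test_empirical_p_floor(self):
        rk = {f"x{i:03d}": float(500 - i) for i in range(200)}
        res = preranked_gsea(rk, {f"x{i:03d}" for i in range(5)},
                             n_permutations=9999, seed=3)
        assert res.pvalue >= 1 / 10000
        assert res.pvalue == pytest.approx(1 / 10000)

    def test_exhaustive_running_sum_oracle(self):
        """ES equals a literal one-step-at-a-time recomputation for every
        subset of every ranking of <= 8 genes (several score vectors,
        including ties)."""
        score_vectors = [
            [8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            [5.0, 5.0, 4.0, 3.0, 3.0, 2.0, 1.0, 0.5],
            [3.0, 1.0, 0.9, 0.5],
            [2.0, 1.5, 1.0],
        ]
        for scores in score_vectors:
            n = len(scores)
            genes = [f"g{i}" for i in range(n)]
            rk = dict(zip(genes, scores))
            order = sorted(rk, key=lambda g: (-rk[g], g))
            ordered_scores = [rk[g] for g in order]
            for r in range(1, n):
                for subset in itertools.combinations(genes, r):
                    res = preranked_gsea(rk, set(subset), n_permutations=1, seed=0)
                    flags = [g in set(subset) for g in order]
                    expected = naive_enrichment_score(ordered_scores, flags, 1.0)
                    assert res.es == pytest.approx(expected), (scores, subset)

    def test_disjoint_set_is_error(self):
        with pytest.raises(ValueError, match="disjoint"):
            preranked_gsea({"a": 1.0, "b": 0.5}, {"zzz"}, n_permutations=10)

    def test_seed_determinism(self):
        rk = self._ranking(50)
        s = {f"x{i:02d}" for i in range(4, 12)}
        a = preranked_gsea(rk, s, n_permutations=200, seed=9)
        b = preranked_gsea(rk, s, n_permutations=200, seed=9)
        assert (a.es, a.nes, a.pvalue) == (b.es, b.nes, b.pvalue)


class TestValidatePredictions:
    def _planted(self, seed=0):
        """Two-block graph: seeds and their neighbours live in block 0."""
        rng = np.random.default_rng(seed)
        nodes = [f"n{i:03d}" for i in range(80)]
        edges = []
        for i in range(80):
            for j in range(i + 1, 80):
                same = (i < 40) == (j < 40)
                p = 0.25 if same else 0.01
                if rng.random() < p:
                    edges.append((nodes[i], nodes[j], 800))
        return PPIGraph(nodes, edges), nodes

    def test_seed_adjacent_predictions_enriched(self):
        g, nodes = self._planted()
        seeds = set(nodes[:8])
        neighbours = set()
        for (u, v) in g.edges:
            if u in seeds and v not in seeds:
                neighbours.add(v)
            elif v in seeds and u not in seeds:
                neighbours.add(u)
        preds = sorted(neighbours)[:20]
        res, table = validate_predictions(g, seeds, preds,
                                          n_permutations=999, seed=1)
        assert res.nes > 0
        assert res.pvalue <= 0.01
        assert not set(table["gene_id"]) & seeds

    def test_random_predictions_p_uniform(self):
        """Null p-values approximately U(0,1): KS test over 200 replicates."""
        g, nodes = self._planted(seed=2)
        pr_seeds = set(nodes[:8])
        universe = [n for n in nodes if n not in pr_seeds]
        rng = np.random.default_rng(0)
        pvals = []
        for rep in range(200):
            preds = rng.choice(universe, size=10, replace=False)
            res, _ = validate_predictions(g, pr_seeds, preds,
                                          n_permutations=99, seed=rep)
            pvals.append(res.pvalue)
        stat, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_too_few_predictions_in_network_rejected(self):
        g, nodes = self._planted()
        with pytest.raises(ValueError, match="fewer than 2"):
            validate_predictions(g, {nodes[0]}, ["zzz"], n_permutations=10)

    def test_seed_determinism(self):
        g, nodes = self._planted()
        preds = nodes[50:60]
        a, _ = validate_predictions(g, set(nodes[:5]), preds, n_permutations=99, seed=4)
        b, _ = validate_predictions(g, set(nodes[:5]), preds, n_permutations=99, seed=4)
        assert (a.nes, a.pvalue) == (b.nes, b.pvalue)
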