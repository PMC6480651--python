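"""Hypergeometric enrichment, BH adjustment, PPI odds ratios, degree statistics."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from nucloc.function_analysis import (
    bh_adjust,
    build_ppi_graph,
    degree_stats,
    hypergeom_enrichment,
    hypergeometric_pvalue,
    ppi_odds,
    ppi_pair_counts,
)
from nucloc.io_formats import Edge


class TestHypergeometric:
    def test_closed_form_extreme_overlap(self):
        # a term annotating exactly the 5-protein target within a background of 100
        background = {f"p{i}" for i in range(100)}
        target = {f"p{i}" for i in range(5)}
        go = {pid: {"GO:X"} for pid in target}
        res = hypergeom_enrichment(target, background, go)[0]
        assert res.p_value == pytest.approx(1.0 / math.comb(100, 5), rel=1e-9)
        assert res.significant

    def test_uniform_term_not_significant(self):
        background = {f"p{i}" for i in range(100)}
        target = {f"p{i}" for i in range(20)}
        go = {pid: {"GO:U"} for pid in background}
        res = hypergeom_enrichment(target, background, go)[0]
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_tail_summation_oracle(self, rng):
        # direct summation of the hypergeometric pmf tail
        N, K, n = 60, 18, 25
        for k in range(0, min(K, n) + 1, 3):
            direct = sum(
                math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
                for i in range(k, min(K, n) + 1)
            )
            assert hypergeometric_pvalue(k, N, K, n) == pytest.approx(direct, abs=1e-12)

    def test_target_must_be_subset(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment({"x"}, {"y"}, {})

    def test_pvalues_uniform_under_permutation_null(self, rng):
        # permuting target membership makes overlaps hypergeometric. The
        # upper-tail p-value of a discrete statistic is super-uniform, so the
        # calibration check uses its uniform randomization
        # p = P(X > k) + U * P(X = k), which is exactly Uniform(0, 1) iff the
        # tail computation is correct.
        from scipy.stats import kstest

        N, K, n = 2000, 1000, 400
        draws = rng.hypergeometric(K, N - K, n, size=1000)
        u = rng.random(1000)
        pvals = [
            hypergeometric_pvalue(k + 1, N, K, n)
            + ui * (hypergeometric_pvalue(k, N, K, n) - hypergeometric_pvalue(k + 1, N, K, n))
            for k, ui in zip(draws, u)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_pvalues_superuniform_under_null(self, rng):
        # without randomization, P(p <= t) <= t must hold (conservative test)
        N, K, n = 2000, 1000, 400
        draws = rng.hypergeometric(K, N - K, n, size=1000)
        pvals = np.sort([hypergeometric_pvalue(int(k), N, K, n) for k in draws])
        ecdf = np.arange(1, 1001) / 1000
        assert np.all(ecdf - pvals <= 0.05)  # within sampling noise of <= 0


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_never_decreases_and_order_preserved(self, rng):
        p = rng.random(50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


def brute_force_odds(nodes: dict[str, frozenset], edges, labels):
    """Exhaustive pair enumeration of the odds-ratio definition."""
    pos = {c: 0.0 for c in itertools.combinations_with_replacement(sorted(labels), 2)}
    obs = {c: 0.0 for c in pos}

    def cells(u, v):
        out = set()
        for i in nodes[u]:
            for j in nodes[v]:
                out.add(tuple(sorted((i, j))))
        return out

    labeled = [n for n, ls in nodes.items() if ls]
    for u, v in itertools.combinations(sorted(labeled), 2):
        for c in cells(u, v):
            pos[c] += 1
    edge_set = {tuple(sorted(e)) for e in edges}
    for u, v in edge_set:
        if nodes.get(u) and nodes.get(v):
            for c in cells(u, v):
                obs[c] += 1
    total_obs = sum(obs.values())
    total_pos = sum(pos.values())
    out = {}
    for c in pos:
        exp = pos[c] / total_pos * total_obs if total_pos else 0.0
        out[c] = obs[c] / exp if exp > 0 else float("nan")
    return out


class TestPpiOdds:
    def _toy(self):
        labels = ("chromatin", "nucleolus", "kinetochore")
        rng = np.random.default_rng(4)
        nodes = {}
        for i in range(20):
            k = 1 + (rng.random() < 0.3)
            nodes[f"n{i}"] = frozenset(rng.choice(labels, size=k, replace=False).tolist())
        edges = []
        ids = sorted(nodes)
        for u, v in itertools.combinations(ids, 2):
            if rng.random() < 0.25:
                edges.append((u, v))
        return labels, nodes, edges

    def test_matches_brute_force_enumeration(self):
        labels, nodes, edges = self._toy()
        graph = build_ppi_graph(edges, nodes)
        odds = ppi_odds(graph, labels)
        expected = brute_force_odds(nodes, edges, labels)
        for (i, j), val in expected.items():
            got = odds.at[i, j]
            if math.isnan(val):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(val, abs=1e-12)
                assert odds.at[j, i] == pytest.approx(val, abs=1e-12)

    def test_no_edges_between_pair_gives_zero(self):
        nodes = {"a": frozenset({"chromatin"}), "b": frozenset({"chromatin"}),
                 "c": frozenset({"nucleolus"}), "d": frozenset({"nucleolus"})}
        graph = build_ppi_graph([("a", "b"), ("c", "d")], nodes)
        odds = ppi_odds(graph, ("chromatin", "nucleolus"))
        assert odds.at["chromatin", "nucleolus"] == 0.0

    def test_mass_conservation_exact(self):
        labels, nodes, edges = self._toy()
        counts = ppi_pair_counts(build_ppi_graph(edges, nodes), labels)
        exp = counts.num_exp()
        assert np.triu(exp.to_numpy()).sum() == pytest.approx(counts.num_obs_total, abs=1e-9)

    def test_no_labeled_edges_errors(self):
        graph = build_ppi_graph([("a", "b")], {})
        with pytest.raises(ValueError):
            ppi_odds(graph, ("chromatin",))


class TestDegreeStats:
    def test_star_graph(self):
        g = build_ppi_graph(
            [("hub", f"l{i}") for i in range(4)],
            groups={"hub": "center", **{f"l{i}": "leaf" for i in range(4)}},
        )
        stats = degree_stats(g)
        assert stats["mean_degree"]["center"] == 4.0
        assert stats["mean_degree"]["leaf"] == 1.0
        assert stats["n_components"] == 1

    def test_two_disjoint_triangles(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a"), ("x", "y"), ("y", "z"), ("z", "x")]
        stats = degree_stats(build_ppi_graph(edges))
        assert stats["component_sizes"] == [3, 3]
        assert stats["mean_degree"]["ungrouped"] == 2.0

    def test_group_rate_ordering_recovered(self, rng):
        # planted group-dependent edge rates must show up in mean degrees
        groups = {f"h{i}": "high" for i in range(30)} | {f"l{i}": "low" for i in range(30)}
        edges = []
        ids = sorted(groups)
        for u, v in itertools.combinations(ids, 2):
            rate = {("high", "high"): 0.4, ("low", "low"): 0.05}.get(
                tuple(sorted((groups[u], groups[v]))), 0.1
            )
            if rng.random() < rate:
                edges.append((u, v))
        stats = degree_stats(build_ppi_graph(edges, groups=groups))
        assert stats["mean_degree"]["high"] > stats["mean_degree"]["low"]

    def test_self_loops_and_duplicates_dropped(self):
        g = build_ppi_graph([("a", "a"), ("a", "b"), ("b", "a")])
        assert g.number_of_edges() == 1
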