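import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathcrosstalk import (
    PathwayGraph,
    Subpathway,
    SubpathwayParams,
    bh_adjust,
    call_risk_pathways,
    hypergeometric_enrichment,
    locate_subpathways,
    score_subpathways,
)


def path_pathway(n: int, pid: str = "P") -> PathwayGraph:
    g = nx.path_graph([f"v{i}" for i in range(1, n + 1)])
    return PathwayGraph(pathway_id=pid, name=pid, graph=g)


class TestLocate:
    def test_no_candidates_no_subpathways(self):
        assert locate_subpathways(path_pathway(6), set(), SubpathwayParams()) == []

    def test_distant_candidates_are_dropped(self):
        # v1..v7: distance(v1, v7) = 6 > n = 5; singleton components < s = 5
        out = locate_subpathways(path_pathway(7), {"v1", "v7"}, SubpathwayParams())
        assert out == []

    def test_close_candidates_merge_the_path(self):
        # v1..v5: distance 4 <= 5, all genes on the shortest path are merged
        out = locate_subpathways(path_pathway(5), {"v1", "v5"}, SubpathwayParams())
        assert len(out) == 1
        assert out[0].member_genes == {f"v{i}" for i in range(1, 6)}
        assert out[0].candidate_members == {"v1", "v5"}
        assert out[0].id == "P_1"

    def test_strict_distance_flag(self):
        # distance exactly n: kept with <=, dropped with strict <
        p6 = path_pathway(6)
        keep = locate_subpathways(p6, {"v1", "v6"}, SubpathwayParams(n=5))
        drop = locate_subpathways(p6, {"v1", "v6"}, SubpathwayParams(n=5, strict=True))
        assert len(keep) == 1 and drop == []

    def test_all_shortest_paths_are_collected(self):
        # two parallel shortest v1-v4 routes; both middles must be included
        g = nx.Graph([("v1", "a"), ("a", "v4"), ("v1", "b"), ("b", "v4"), ("v4", "c")])
        pw = PathwayGraph(pathway_id="P", name="P", graph=g)
        out = locate_subpathways(pw, {"v1", "v4"}, SubpathwayParams(n=5, s=3))
        assert out[0].member_genes == {"v1", "a", "b", "v4"}

    def test_edgeless_pathway_yields_nothing(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        pw = PathwayGraph(pathway_id="P", name="P", graph=g)
        assert locate_subpathways(pw, {"a", "b"}, SubpathwayParams()) == []

    def test_components_are_connected_and_big_enough(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            g = nx.gnp_random_graph(40, 0.08, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
            pw = PathwayGraph(pathway_id="P", name="P", graph=g)
            cands = set(rng.choice([f"v{i}" for i in range(40)], size=8, replace=False))
            for sp in locate_subpathways(pw, cands, SubpathwayParams()):
                assert sp.size >= 5
                assert nx.is_connected(g.subgraph(sp.member_genes))

    def test_shrinking_n_never_grows_subpathways(self):
        rng = np.random.default_rng(1)
        g = nx.gnp_random_graph(40, 0.08, seed=3)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        pw = PathwayGraph(pathway_id="P", name="P", graph=g)
        cands = set(rng.choice([f"v{i}" for i in range(40)], size=8, replace=False))
        for n_small, n_big in [(1, 3), (2, 5), (3, 6)]:
            small = locate_subpathways(pw, cands, SubpathwayParams(n=n_small, s=2))
            big = locate_subpathways(pw, cands, SubpathwayParams(n=n_big, s=2))
            union_small = set().union(*(sp.member_genes for sp in small)) if small else set()
            union_big = set().union(*(sp.member_genes for sp in big)) if big else set()
            assert union_small <= union_big


def brute_force_upper_tail(k, K, m, N):
    """Enumerate all C(N, m) draws from a labelled population."""
    population = list(range(N))
    successes = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(population, m):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_zero_candidates_gives_one(self):
        assert hypergeometric_enrichment(0, 4, 3, 10) == 1.0

    def test_worked_example(self):
        assert hypergeometric_enrichment(2, 4, 3, 10) == pytest.approx(1 / 3, abs=1e-12)

    def test_certain_event(self):
        assert hypergeometric_enrichment(5, 5, 5, 5) == 1.0

    def test_bounds_are_enforced(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(5, 4, 3, 10)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(1, 11, 3, 10)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(0, N + 1))
            m = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, m) + 1))
            assert hypergeometric_enrichment(k, K, m, N) == pytest.approx(
                brute_force_upper_tail(k, K, m, N), abs=1e-12)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_statsmodels_and_is_monotone(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert (np.diff(ours[order]) >= -1e-12).all()


def make_scored(ps):
    return [
        Subpathway(id=f"S{i}", parent_pathway_id=f"P{i}",
                   member_genes=frozenset({f"a{i}", f"b{i}", f"c{i}", f"d{i}", f"e{i}"}),
                   candidate_members=frozenset({f"a{i}"}), p_value=p)
        for i, p in enumerate(ps)
    ]


class TestRiskCalling:
    def test_single_significant_subpathway_retained(self):
        out = call_risk_pathways(make_scored([0.01]), SubpathwayParams())
        assert len(out) == 1 and out[0].fdr == pytest.approx(0.01)

    def test_bh_can_remove_everything(self):
        out = call_risk_pathways(make_scored([0.03, 0.9]), SubpathwayParams())
        assert out == []

    def test_empty_input(self):
        assert call_risk_pathways([], SubpathwayParams()) == []

    def test_planted_dense_pathway_is_recovered(self):
        """One candidate-dense pathway among sparse ones survives joint BH."""
        rng = np.random.default_rng(7)
        hits = 0
        n_runs = 10
        for run in range(n_runs):
            pathways, all_genes = [], []
            for i in range(8):
                genes = [f"p{i}g{j}" for j in range(12)]
                all_genes.extend(genes)
                g = nx.path_graph(genes)
                pathways.append(PathwayGraph(pathway_id=f"P{i}", name=f"P{i}", graph=g))
            # dense pathway 0: 6 candidates; others: 1 random candidate each
            cands = {f"p0g{j}" for j in range(6)}
            for i in range(1, 8):
                cands.add(f"p{i}g{int(rng.integers(12))}")
            located = []
            for pw in pathways:
                located.extend(locate_subpathways(pw, cands, SubpathwayParams()))
            scored = score_subpathways(located, cands, set(all_genes))
            risk = call_risk_pathways(scored, SubpathwayParams())
            if any(sp.parent_pathway_id == "P0" for sp in risk):
                hits += 1
        assert hits >= 9
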