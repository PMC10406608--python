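"""Homologous-group construction: filtering, MCL, pruning, merging."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from genecontent.clustering import (
    GraphProfileScorer,
    MergeCriteria,
    ProfileMatch,
    build_cluster_network,
    cluster_pipeline,
    filter_hits,
    mcl_cluster,
    merge_clusters,
    prune_to_diameter,
)
from genecontent.graphs import HGPartition, SimilarityGraph
from genecontent.simulate import simulate_similarity_graph


def _graph(rows, nodes=None):
    df = pd.DataFrame(
        rows, columns=["query", "subject", "score", "evalue", "cov_long", "cov_short"]
    )
    return SimilarityGraph(df, nodes=nodes or [])


# ---------------------------------------------------------------- filtering


@pytest.mark.parametrize(
    "cov_long,cov_short,evalue,kept",
    [
        (0.25, 0.85, 1e-5, True),   # all three thresholds met
        (0.25, 0.85, 1e-3, False),  # e-value too weak
        (0.15, 0.85, 1e-5, False),  # longer-protein coverage too low
        (0.25, 0.75, 1e-5, False),  # shorter-protein coverage too low
        (0.2, 0.8, 1e-4, True),     # inclusive boundaries
    ],
)
def test_coverage_evalue_filter(cov_long, cov_short, evalue, kept):
    g = _graph([("a", "b", 50.0, evalue, cov_long, cov_short)])
    out = filter_hits(g)
    assert (len(out.edges) == 1) is kept
    assert out.nodes == ["a", "b"]  # nodes survive even when edges drop


def test_filter_empty_graph_is_empty():
    g = _graph([], nodes=["x"])
    out = filter_hits(g)
    assert len(out.edges) == 0 and out.nodes == ["x"]


def test_filter_missing_coverage_is_malformed():
    df = pd.DataFrame([("a", "b", 5.0, 1e-9)], columns=["query", "subject", "score", "evalue"])
    with pytest.raises(ValueError, match="malformed"):
        filter_hits(SimilarityGraph(df))


# --------------------------------------------------------------------- MCL


def _reference_mcl(graph: SimilarityGraph, inflation=2.0, iters=300):
    """Independent dense MCL (oracle): different code path and cluster
    read-off (components of the symmetrised limit matrix)."""
    nodes = sorted(graph.nodes)
    ix = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for r in graph.edges.itertuples():
        M[ix[r.query], ix[r.subject]] = r.score
        M[ix[r.subject], ix[r.query]] = r.score
    for i in range(n):
        M[i, i] = M[i].max() if M[i].max() > 0 else 1.0
    M = M / M.sum(0)
    for _ in range(iters):
        M = np.linalg.matrix_power(M, 2)
        M = M**inflation
        M /= M.sum(0)
        M[M < 1e-9] = 0
        s = M.sum(0)
        s[s == 0] = 1
        M /= s
    g = nx.from_numpy_array((M + M.T) > 1e-6)
    return {frozenset(nodes[i] for i in comp) for comp in nx.connected_components(g)}


def test_two_triangles_make_two_clusters():
    rows = []
    for tri in (["a1", "a2", "a3"], ["b1", "b2", "b3"]):
        for i in range(3):
            for j in range(i + 1, 3):
                rows.append((tri[i], tri[j], 1.0, 1e-20, 0.9, 0.9))
    part = mcl_cluster(_graph(rows))
    assert part.as_sets() == {
        frozenset({"a1", "a2", "a3"}),
        frozenset({"b1", "b2", "b3"}),
    }


def test_isolated_node_is_singleton():
    part = mcl_cluster(_graph([], nodes=["only"]))
    assert part.as_sets() == {frozenset({"only"})}


def test_mcl_matches_reference_on_planted_partition():
    part3 = {f"f{i}": [f"f{i}|p{j}" for j in range(10)] for i in range(3)}
    g = simulate_similarity_graph(
        part3, intra_edge_prob=0.95, inter_edge_prob=0.05, seed=13
    )
    ours = mcl_cluster(g, inflation=2.0).as_sets()
    ref = _reference_mcl(g, inflation=2.0)
    assert ours == ref


def test_mcl_is_permutation_equivariant():
    part3 = {f"f{i}": [f"f{i}|p{j}" for j in range(6)] for i in range(3)}
    g = simulate_similarity_graph(part3, seed=21)
    base = mcl_cluster(g).as_sets()
    rng = np.random.default_rng(0)
    names = sorted(g.nodes)
    for _ in range(3):
        perm = dict(zip(names, rng.permutation(names)))
        edges = g.edges.copy()
        edges["query"] = edges["query"].map(perm)
        edges["subject"] = edges["subject"].map(perm)
        relabelled = SimilarityGraph(edges, nodes=list(perm.values()))
        got = mcl_cluster(relabelled).as_sets()
        expect = {frozenset(perm[p] for p in c) for c in base}
        assert got == expect


def test_partition_is_total_and_disjoint():
    part4 = {f"f{i}": [f"f{i}|p{j}" for j in range(8)] for i in range(4)}
    g = simulate_similarity_graph(part4, seed=30)
    hg = cluster_pipeline(g)
    assert sorted(hg.assignments) == sorted(g.nodes)
    sizes = sum(len(m) for m in hg.members.values())
    assert sizes == len(g.nodes)


# ----------------------------------------------------------- cluster network


def test_cluster_network_weight_formula():
    part = HGPartition.from_groups({"A": {"a1", "a2"}, "B": {"b1"}})
    g = _graph([("a1", "b1", 5.0, 1e-20, 0.9, 0.9)])
    cg = build_cluster_network(part, g)
    assert cg["A"]["B"]["weight"] == pytest.approx(1.0)  # 1 edge / min(2,1)

    part2 = HGPartition.from_groups(
        {"A": {"a1", "a2", "a3", "a4"}, "B": {"b1", "b2"}}
    )
    rows = [(f"a{i}", "b1", 5.0, 1e-20, 0.9, 0.9) for i in (1, 2, 3)]
    cg2 = build_cluster_network(part2, _graph(rows))
    assert cg2["A"]["B"]["count"] == 3
    assert cg2["A"]["B"]["weight"] == pytest.approx(3 / 2)  # 3 / min(4,2)


def test_no_inter_edges_gives_edgeless_network():
    part = HGPartition.from_groups({"A": {"a1", "a2"}, "B": {"b1"}})
    g = _graph([("a1", "a2", 5.0, 1e-20, 0.9, 0.9)])
    cg = build_cluster_network(part, g)
    assert cg.number_of_edges() == 0 and set(cg.nodes) == {"A", "B"}


# ------------------------------------------------------------------ pruning


def _path_graph(weights):
    g = nx.Graph()
    nodes = [chr(ord("A") + i) for i in range(len(weights) + 1)]
    for i, w in enumerate(weights):
        g.add_edge(nodes[i], nodes[i + 1], weight=w)
    return g


def test_diameter_three_path_unchanged():
    g = _path_graph([1.0, 2.0, 3.0])  # A-B-C-D, diameter 3
    out = prune_to_diameter(g)
    assert set(out.edges) == set(g.edges)


def test_weakest_middle_edge_removed_from_long_path():
    g = _path_graph([2.0, 3.0, 0.5, 2.0])  # five nodes, middle edge weakest
    out = prune_to_diameter(g, 3)
    comps = sorted(len(c) for c in nx.connected_components(out))
    assert comps == [2, 3]
    for comp in nx.connected_components(out):
        assert nx.diameter(out.subgraph(comp)) <= 3


def test_edgeless_graph_unchanged():
    g = nx.Graph()
    g.add_nodes_from("ABC")
    out = prune_to_diameter(g)
    assert out.number_of_edges() == 0 and set(out.nodes) == {"A", "B", "C"}


def test_prune_postcondition_on_random_graphs(rng):
    for k in range(25):
        n = int(rng.integers(5, 25))
        g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(1 << 30)))
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.random())
        out = prune_to_diameter(g, 3)
        assert set(out.nodes) == set(g.nodes)  # edges only are removed
        assert len(out.edges) <= len(g.edges)
        for comp in nx.connected_components(out):
            assert nx.diameter(out.subgraph(comp)) <= 3


# -------------------------------------------------------------------- merge


def _const_scorer(match):
    return lambda a, b: match


@pytest.mark.parametrize(
    "score,merged",
    [(80.0, True), (75.0, True), (70.0, False)],  # >= 75% of self-match 100
)
def test_merge_self_match_fraction(score, merged):
    part = HGPartition.from_groups({"A": {"a"}, "B": {"b"}})
    cg = nx.Graph()
    cg.add_edge("A", "B", weight=1.0)
    match = ProfileMatch(1e-12, 0.8, 0.3, score, 100.0)
    out = merge_clusters(cg, part, _const_scorer(match))
    assert (out.n_groups == 1) is merged


@pytest.mark.parametrize(
    "evalue,covp,covc,merged",
    [
        (1e-12, 0.8, 0.3, True),
        (1e-9, 0.8, 0.3, False),   # e-value above 1e-10
        (1e-12, 0.7, 0.3, False),  # profile coverage below 75%
        (1e-12, 0.8, 0.1, False),  # consensus coverage below 20%
    ],
)
def test_merge_requires_all_four_criteria(evalue, covp, covc, merged):
    part = HGPartition.from_groups({"A": {"a"}, "B": {"b"}})
    cg = nx.Graph()
    cg.add_edge("A", "B", weight=1.0)
    match = ProfileMatch(evalue, covp, covc, 90.0, 100.0)
    out = merge_clusters(cg, part, _const_scorer(match))
    assert (out.n_groups == 1) is merged


def test_merge_without_edges_returns_partition_unchanged():
    part = HGPartition.from_groups({"A": {"a"}, "B": {"b"}})
    cg = nx.Graph()
    cg.add_nodes_from(["A", "B"])
    out = merge_clusters(cg, part, _const_scorer(ProfileMatch(0, 1, 1, 1, 1)))
    assert out.as_sets() == part.as_sets()


def test_merge_is_transitive_coarsening():
    part = HGPartition.from_groups({"A": {"a"}, "B": {"b"}, "C": {"c"}})
    cg = nx.Graph()
    cg.add_edge("A", "B", weight=1.0)
    cg.add_edge("B", "C", weight=1.0)
    match = ProfileMatch(1e-12, 0.8, 0.3, 90.0, 100.0)
    out = merge_clusters(cg, part, _const_scorer(match))
    assert out.as_sets() == {frozenset({"a", "b", "c"})}


def test_scorer_failure_skips_pair_with_warning():
    part = HGPartition.from_groups({"A": {"a"}, "B": {"b"}})
    cg = nx.Graph()
    cg.add_edge("A", "B", weight=1.0)

    def bad(a, b):
        raise RuntimeError("no profile")

    with pytest.warns(RuntimeWarning, match="profile scorer failed"):
        out = merge_clusters(cg, part, bad)
    assert out.n_groups == 2


# ---------------------------------------------------------- whole pipeline


def test_pipeline_recovers_planted_families_exactly_without_noise():
    part = {f"f{i}": [f"f{i}|p{j}" for j in range(8)] for i in range(10)}
    g = simulate_similarity_graph(part, inter_edge_prob=0.0, seed=17)
    hg = cluster_pipeline(g)
    assert hg.as_sets() == {frozenset(ps) for ps in part.values()}
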