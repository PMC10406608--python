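"""Homologous-group construction from protein similarity graphs.

The stage chain is: asymmetric coverage / e-value filtering of the raw
all-vs-all hits, Markov clustering (MCL) of the surviving graph, a
cluster-level network whose edges are size-normalised inter-cluster
connection counts, iterative pruning of that network until every component
has unweighted diameter <= 3, and finally profile-based merging of cluster
pairs that remain connected, under four simultaneous criteria
(e-value <= 1e-10, asymmetric coverages >= 75% / >= 20%, and a match score
of at least 75% of the self-match).  The merged, filtered clusters are the
homologous groups (HGs) used by every downstream stage.

Profile scoring against consensus sequences is an external concern
(HMM searches in the original workflow); here it enters through the
pluggable ``profile_scorer`` contract, with :class:`GraphProfileScorer` as
a bundled desk-scale stand-in that aggregates raw edge statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import HGPartition, SimilarityGraph

__all__ = [
    "MergeCriteria",
    "ProfileMatch",
    "GraphProfileScorer",
    "filter_hits",
    "mcl_cluster",
    "build_cluster_network",
    "prune_to_diameter",
    "merge_clusters",
    "cluster_pipeline",
]


# ---------------------------------------------------------------- filtering


def filter_hits(
    graph: SimilarityGraph,
    cov_long_min: float = 0.2,
    cov_short_min: float = 0.8,
    evalue_max: float = 1e-4,
) -> SimilarityGraph:
    """Asymmetric coverage + e-value filter on a similarity graph.

    Keeps edges with coverage of the longer protein >= ``cov_long_min``
    (default 20%), coverage of the shorter >= ``cov_short_min`` (default
    80%) and e-value <= ``evalue_max`` (default 1e-4).  Nodes are kept even
    if all their edges are dropped.
    """
    edges = graph.edges
    for col in ("cov_long", "cov_short", "evalue"):
        if col not in edges.columns or edges[col].isna().any():
            raise ValueError(f"malformed input: missing or NaN column {col!r}")
    keep = (
        (edges["cov_long"] >= cov_long_min)
        & (edges["cov_short"] >= cov_short_min)
        & (edges["evalue"] <= evalue_max)
    )
    return SimilarityGraph(
        edges[keep].reset_index(drop=True),
        nodes=list(graph.nodes),
        self_scores=graph.self_scores,
    )


# ---------------------------------------------------------------------- MCL


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    convergence_tol: float = 1e-8,
    max_iter: int = 200,
    prune_threshold: float = 1e-8,
) -> HGPartition:
    """Markov clustering of a similarity graph.

    Runs the expansion (matrix squaring) / inflation (entrywise power then
    column renormalisation) iteration on the column-stochastic transition
    matrix, with self-loops set to each node's maximum incident weight and
    near-zero entries pruned at ``prune_threshold``.  Clusters are read off
    the converged matrix as attractor systems; proteins with no edges come
    out as singleton clusters.
    """
    if graph.n_nodes < 1:
        raise ValueError("graph must have at least one node")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    index = {p: i for i, p in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for row in graph.edges.itertuples(index=False):
        i, j = index[row.query], index[row.subject]
        w = float(row.score)
        A[i, j] = max(A[i, j], w)
        A[j, i] = A[i, j]
    incident_max = A.max(axis=0)
    np.fill_diagonal(A, np.where(incident_max > 0, incident_max, 1.0))

    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        E = M @ M
        E **= inflation
        E[E < prune_threshold] = 0.0
        colsum = E.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        E /= colsum
        if np.abs(E - M).max() < convergence_tol:
            M = E
            converged = True
            break
        M = E
    if not converged:
        warnings.warn(
            f"MCL did not converge in {max_iter} iterations; "
            "interpreting the current matrix",
            RuntimeWarning,
            stacklevel=2,
        )

    # attractors are rows with nonzero diagonal mass; overlapping attractor
    # rows describe one cluster
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    attractors = np.nonzero(np.diag(M) > prune_threshold)[0]
    for i in attractors:
        for j in np.nonzero(M[i] > prune_threshold)[0]:
            union(i, int(j))
    # safety net for columns with no attractor row (non-converged runs)
    for j in range(n):
        col = np.nonzero(M[:, j] > prune_threshold)[0]
        if col.size:
            union(j, int(col[np.argmax(M[col, j])]))

    groups: dict[int, set[str]] = {}
    for i, p in enumerate(nodes):
        groups.setdefault(find(i), set()).add(p)
    return HGPartition.from_groups(
        {f"c{k}": mem for k, mem in enumerate(sorted(groups.values(), key=min))}
    ).relabel()


# ----------------------------------------------------------- cluster network


def build_cluster_network(
    partition: HGPartition,
    graph: SimilarityGraph,
    norm: str = "min",
) -> nx.Graph:
    """Cluster-level network from inter-cluster protein edges.

    Edge weight between clusters A and B is the number of protein-level
    edges crossing between them, normalised to cluster size: divided by
    ``min(|A|, |B|)`` (default) or by the mean size (``norm="mean"``).
    Clusters with no crossing edges appear as isolated nodes.
    """
    counts: dict[tuple[str, str], int] = {}
    for row in graph.edges.itertuples(index=False):
        a = partition.group_of(row.query)
        b = partition.group_of(row.subject)
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    cg = nx.Graph()
    cg.add_nodes_from(partition.members)
    for (a, b), c in counts.items():
        na, nb = len(partition.members[a]), len(partition.members[b])
        denom = min(na, nb) if norm == "min" else (na + nb) / 2
        cg.add_edge(a, b, count=c, weight=c / denom)
    return cg


def prune_to_diameter(cg: nx.Graph, max_diameter: int = 3) -> nx.Graph:
    """Iteratively remove weakest links until all components are compact.

    While any connected component has unweighted diameter greater than
    ``max_diameter``, the minimum-weight edge of that component is removed
    (ties broken by lexicographic cluster-id pair).  Terminates in at most
    |E| removals; the result satisfies the diameter bound exactly.
    """
    if max_diameter < 1:
        raise ValueError("max_diameter must be >= 1")
    g = cg.copy()
    dirty = True
    while dirty:
        dirty = False
        for comp in list(nx.connected_components(g)):
            if len(comp) <= 2:
                continue
            sub = g.subgraph(comp)
            if nx.diameter(sub) <= max_diameter:
                continue
            u, v = min(
                sub.edges,
                key=lambda e: (sub.edges[e]["weight"], *sorted(e)),
            )
            g.remove_edge(u, v)
            dirty = True
    return g


# -------------------------------------------------------------------- merge


class ProfileMatch(NamedTuple):
    """Result of comparing one cluster's profile against another's consensus."""

    evalue: float
    coverage_profile: float
    coverage_consensus: float
    score: float
    self_score: float


ProfileScorer = Callable[[str, str], ProfileMatch]


@dataclass
class MergeCriteria:
    """Thresholds a surviving cluster pair must meet to be merged."""

    evalue_cutoff: float = 1e-10
    coverage_profile: float = 0.75
    coverage_consensus: float = 0.20
    self_match_fraction: float = 0.75
    max_diameter: int = 3

    def __post_init__(self) -> None:
        for name in ("coverage_profile", "coverage_consensus", "self_match_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.max_diameter < 1:
            raise ValueError("max_diameter must be >= 1")

    def passes(self, m: ProfileMatch) -> bool:
        return (
            m.evalue <= self.evalue_cutoff
            and m.coverage_profile >= self.coverage_profile
            and m.coverage_consensus >= self.coverage_consensus
            and m.score >= self.self_match_fraction * m.self_score
        )


class GraphProfileScorer:
    """Desk-scale stand-in for HMM-profile-vs-consensus cluster comparison.

    Scores a cluster pair from the underlying similarity graph: the match
    score is the mean score of edges crossing the pair, the e-value the
    minimum crossing e-value, the coverages the means of the edge coverage
    fields, and the self score the mean of the first cluster's members'
    self-match scores (falling back to mean intra-edge score).  This is not
    HMMER-equivalent; it only preserves the *shape* of the contract.
    """

    def __init__(self, graph: SimilarityGraph, partition: HGPartition):
        self.graph = graph
        self.partition = partition

    def __call__(self, a: str, b: str) -> ProfileMatch:
        mem_a = self.partition.members[a]
        mem_b = self.partition.members[b]
        e = self.graph.edges
        qa, sb = e["query"].isin(mem_a), e["subject"].isin(mem_b)
        qb, sa = e["query"].isin(mem_b), e["subject"].isin(mem_a)
        crossing = e[(qa & sb) | (qb & sa)]
        if crossing.empty:
            raise ValueError(f"no crossing edges between {a} and {b}")
        if self.graph.self_scores:
            selfs = [self.graph.self_scores.get(p, np.nan) for p in mem_a]
            self_score = float(np.nanmean(selfs))
        else:
            intra = e[e["query"].isin(mem_a) & e["subject"].isin(mem_a)]
            self_score = float(intra["score"].mean()) if len(intra) else float("inf")
        return ProfileMatch(
            evalue=float(crossing["evalue"].min()),
            coverage_profile=float(crossing["cov_long"].mean()),
            coverage_consensus=float(crossing["cov_short"].mean()),
            score=float(crossing["score"].mean()),
            self_score=self_score,
        )


def merge_clusters(
    cg: nx.Graph,
    partition: HGPartition,
    profile_scorer: ProfileScorer,
    criteria: MergeCriteria | None = None,
) -> HGPartition:
    """Union clusters across surviving network edges that pass all criteria.

    Merging is transitive (union-find over passing edges), so the output
    is a coarsening of the input partition.  A scorer failure on a pair
    skips that pair with a warning.
    """
    criteria = criteria or MergeCriteria()
    parent = {hg: hg for hg in partition.members}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in sorted(map(tuple, map(sorted, cg.edges))):
        try:
            match = profile_scorer(a, b)
        except Exception as exc:  # scorer contract: skip and warn
            warnings.warn(
                f"profile scorer failed on ({a}, {b}): {exc}", RuntimeWarning,
                stacklevel=2,
            )
            continue
        if criteria.passes(match):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    merged: dict[str, set[str]] = {}
    for hg, mem in partition.members.items():
        merged.setdefault(find(hg), set()).update(mem)
    return HGPartition.from_groups(merged).relabel()


# ----------------------------------------------------------------- pipeline


def cluster_pipeline(
    graph: SimilarityGraph,
    inflation: float = 2.0,
    cov_long_min: float = 0.2,
    cov_short_min: float = 0.8,
    evalue_max: float = 1e-4,
    criteria: MergeCriteria | None = None,
    profile_scorer: ProfileScorer | None = None,
    norm: str = "min",
) -> HGPartition:
    """filter -> MCL -> cluster network -> diameter pruning -> merge."""
    criteria = criteria or MergeCriteria()
    filtered = filter_hits(graph, cov_long_min, cov_short_min, evalue_max)
    partition = mcl_cluster(filtered, inflation=inflation)
    cg = build_cluster_network(partition, filtered, norm=norm)
    cg = prune_to_diameter(cg, criteria.max_diameter)
    scorer = profile_scorer or GraphProfileScorer(filtered, partition)
    return merge_clusters(cg, partition, scorer, criteria)
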