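"""Marker-gene filters applied before species-tree inference.

Candidate single-copy marker families are screened by four bespoke rules:
removal of terminal (same-species) duplications from gene trees, a mean
amino-acid-distance ceiling (< 1.5), an ancestral-paralogue screen on the
first split of a hierarchical clustering of distances, and minimum
alignment length / species-count requirements (>= 60 aa, >= 30 species).
Alignment, trimming and tree inference themselves are upstream concerns;
distances may come from any source (a Poisson-corrected distance is
bundled as a convenient default).
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .reconcile import default_species_of
from .trees import Tree, build_tree

__all__ = [
    "remove_terminal_duplicates",
    "mean_distance_filter",
    "ancestral_paralog_screen",
    "alignment_size_filter",
    "poisson_distance",
]


def remove_terminal_duplicates(
    tree: Tree,
    species_of: Callable[[str], str] = default_species_of,
    distances: pd.DataFrame | None = None,
) -> Tree:
    """Collapse same-species terminal clades to a single representative.

    Any maximal subtree whose leaves all belong to one species becomes a
    single leaf.  The kept representative is the leaf with the smallest
    mean distance to the leaves of other species when ``distances`` are
    supplied, otherwise the lexicographically smallest label.  Idempotent;
    never removes the last leaf of a species.
    """
    if tree.n_tips < 2:
        raise ValueError("tree must have at least two leaves")
    species_sets: list[set[str]] = [set() for _ in range(tree.n_nodes)]
    for v in tree.postorder():
        if tree.is_tip(v):
            species_sets[v] = {species_of(tree.labels[v])}
        else:
            for c in tree.children[v]:
                species_sets[v] |= species_sets[c]

    def representative(leaves: list[int]) -> int:
        labels = [tree.labels[t] for t in leaves]
        if distances is not None:
            others = [
                lab
                for lab in distances.index
                if species_of(lab) != species_of(labels[0])
            ]
            if others:
                means = {
                    lab: distances.loc[lab, others].mean()
                    for lab in labels
                    if lab in distances.index
                }
                if means:
                    return leaves[labels.index(min(means, key=lambda x: (means[x], x)))]
        return leaves[labels.index(min(labels))]

    # walk down from the root; replace maximal single-species subtrees
    children: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    lengths: dict[int, float] = {}
    supports: dict[int, float] = {}

    def visit(v: int) -> int:
        if len(species_sets[v]) == 1 and not tree.is_tip(v):
            keep = representative(tree.subtree_tips(v))
            labels[v] = tree.labels[keep]
            if tree.lengths[v] is not None:
                lengths[v] = tree.lengths[v]
            return v
        if tree.is_tip(v):
            labels[v] = tree.labels[v]
        else:
            children[v] = [visit(c) for c in tree.children[v]]
        if tree.lengths[v] is not None:
            lengths[v] = tree.lengths[v]
        if tree.supports[v] is not None:
            supports[v] = tree.supports[v]
        return v

    root = visit(tree.root)
    out = build_tree(root, children, labels=labels, lengths=lengths, supports=supports)
    # a root whose children collapsed into one leaf still needs >= 2 tips
    return out


def mean_distance_filter(d: pd.DataFrame | np.ndarray, threshold: float = 1.5) -> bool:
    """Pass iff the mean pairwise distance is below the threshold."""
    D = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or D.shape[0] < 2:
        raise ValueError("need a square distance matrix over >= 2 sequences")
    off = ~np.eye(D.shape[0], dtype=bool)
    return float(D[off].mean()) < threshold


def ancestral_paralog_screen(
    d: pd.DataFrame,
    species_of: Callable[[str], str] = default_species_of,
    min_shared: int = 2,
    linkage: str = "average",
) -> bool:
    """Screen for duplications predating the family's deepest split.

    Hierarchically clusters the sequences (``linkage`` method, average by
    default) and inspects the two sides of the root split: if both sides
    share at least ``min_shared`` species, the family looks like a pair of
    ancestral paralogues and fails (returns False).  This operationalises
    a "low phylogenetic relations at the first split" criterion; it is one
    plausible reading, documented as such.
    """
    if len(d) < 3:
        raise ValueError("screen needs at least 3 sequences")
    Z = hierarchy.linkage(squareform(d.to_numpy(dtype=float), checks=False), method=linkage)
    cut = hierarchy.cut_tree(Z, n_clusters=2).ravel()
    side_a = {species_of(lab) for lab, c in zip(d.index, cut) if c == 0}
    side_b = {species_of(lab) for lab, c in zip(d.index, cut) if c == 1}
    return len(side_a & side_b) < min_shared


def alignment_size_filter(
    length_aa: int,
    n_species: int,
    min_length: int = 60,
    min_species: int = 30,
) -> bool:
    """Pass iff the trimmed alignment is long enough and broad enough."""
    if length_aa < 0 or n_species < 0:
        raise ValueError("length and species count must be non-negative")
    return length_aa >= min_length and n_species >= min_species


def poisson_distance(sequences: Mapping[str, str]) -> pd.DataFrame:
    """Poisson-corrected pairwise distance, -ln(1 - p), over aligned seqs.

    A simple stand-in for maximum-likelihood amino-acid distances; gaps
    ('-') are excluded pairwise.  Saturated pairs (p >= 1) get inf.
    """
    names = list(sequences)
    L = {len(s) for s in sequences.values()}
    if len(L) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[names[i]], sequences[names[j]]
            pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not pairs:
                D[i, j] = D[j, i] = np.inf
                continue
            p = sum(1 for x, y in pairs if x != y) / len(pairs)
            D[i, j] = D[j, i] = np.inf if p >= 1 else -np.log(1 - p)
    return pd.DataFrame(D, index=names, columns=names)
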