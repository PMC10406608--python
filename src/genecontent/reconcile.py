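"""Gene-tree / species-tree reconciliation by LCA mapping.

Implements the reconciliation roles of the analysis: parsimony rooting of
gene trees (the root is placed on the edge minimising duplications +
losses), contraction of weakly supported edges (support < 80 by default)
into polytomies, LCA mapping with duplication labelling, per-edge loss
counting, and delimitation of orthogroups as the maximal speciation-only
subtrees obtained by cutting the gene tree at every duplication node.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

from .trees import Tree, build_tree

__all__ = [
    "Reconciliation",
    "OrthoGroup",
    "default_species_of",
    "collapse_weak_edges",
    "lca_reconcile",
    "root_gene_tree",
    "delimit_orthogroups",
]


def default_species_of(label: str) -> str:
    """Leaf labels are ``species|protein`` by convention."""
    return label.split("|", 1)[0]


# ------------------------------------------------------------ reconciliation


@dataclass
class Reconciliation:
    """LCA reconciliation of a rooted gene tree against a species tree.

    ``mapping`` sends every gene-tree node to a species-tree node;
    ``events`` labels internal gene-tree nodes speciation/duplication;
    ``losses`` counts the species-tree edges skipped on the branch above
    each gene-tree node.
    """

    gene_tree: Tree
    species_tree: Tree
    mapping: dict[int, int]
    events: dict[int, str]
    losses: dict[int, int]

    @property
    def total_duplications(self) -> int:
        return sum(1 for e in self.events.values() if e == "duplication")

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())


def lca_reconcile(
    gtree: Tree,
    stree: Tree,
    species_of: Callable[[str], str] = default_species_of,
) -> Reconciliation:
    """Map every gene-tree node to the species tree and count events.

    Each internal node maps to the LCA of its children's mappings and is a
    duplication if a child co-maps with it, or — for polytomies — if two
    children co-map to the same species-tree node (the conservative
    reading: duplication only when forced).  Losses on the branch above a
    node are the species-tree edges skipped between the parent's and the
    node's mapping, minus one if the parent is a speciation.
    """
    tip_idx = stree.tip_index()
    sdepth = stree.depths()
    mapping: dict[int, int] = {}
    events: dict[int, str] = {}
    for v in gtree.postorder():
        if gtree.is_tip(v):
            sp = species_of(gtree.labels[v])
            if sp not in tip_idx:
                raise KeyError(f"unknown species {sp!r} (leaf {gtree.labels[v]!r})")
            mapping[v] = tip_idx[sp]
        else:
            child_maps = [mapping[c] for c in gtree.children[v]]
            mapping[v] = stree.mrca(child_maps)
            dup = any(m == mapping[v] for m in child_maps) or (
                len(child_maps) > len(set(child_maps))
            )
            events[v] = "duplication" if dup else "speciation"
    losses: dict[int, int] = {}
    for v in gtree.postorder():
        if v == gtree.root:
            continue
        p = gtree.parent[v]
        dist = sdepth[mapping[v]] - sdepth[mapping[p]]
        if events[p] == "duplication":
            losses[v] = dist
        else:
            losses[v] = max(dist - 1, 0)
    return Reconciliation(gtree, stree, mapping, events, losses)


# ------------------------------------------------------------------ rooting


def _unrooted_adjacency(tree: Tree):
    """Adjacency view of a rooted tree with a degree-2 root suppressed.

    Returns (adjacency, edge attribute dict) where edges are frozensets of
    node ids and attributes carry (length, support).
    """
    adj: dict[int, set[int]] = {v: set() for v in range(tree.n_nodes)}
    attrs: dict[frozenset[int], tuple[float | None, float | None]] = {}
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        p = tree.parent[v]
        adj[v].add(p)
        adj[p].add(v)
        attrs[frozenset((v, p))] = (tree.lengths[v], tree.supports[v])
    r = tree.root
    if len(adj[r]) == 2:
        a, b = sorted(adj[r])
        la, sa = attrs.pop(frozenset((a, r)))
        lb, sb = attrs.pop(frozenset((b, r)))
        adj[a].discard(r)
        adj[b].discard(r)
        adj[a].add(b)
        adj[b].add(a)
        del adj[r]
        length = None if la is None and lb is None else (la or 0.0) + (lb or 0.0)
        support = sa if sa is not None else sb
        attrs[frozenset((a, b))] = (length, support)
    return adj, attrs


def _root_on_edge(tree: Tree, adj, attrs, edge: frozenset[int]) -> Tree:
    """Build a rooted tree with a new root bisecting ``edge``."""
    u, v = sorted(edge)
    root_key = ("root",)
    children: dict[object, list[object]] = {root_key: [u, v]}
    labels: dict[object, str] = {}
    lengths: dict[object, float] = {}
    supports: dict[object, float] = {}
    el, es = attrs[edge]
    if el is not None:
        lengths[u] = el / 2
        lengths[v] = el / 2
    if es is not None:
        supports[u] = es
        supports[v] = es

    stack = [(u, v), (v, u)]
    while stack:
        node, came_from = stack.pop()
        if tree.is_tip(node):
            labels[node] = tree.labels[node]
        kids = sorted(adj[node] - {came_from})
        if kids:
            children[node] = kids
        for k in kids:
            le, su = attrs[frozenset((node, k))]
            if le is not None:
                lengths[k] = le
            if su is not None:
                supports[k] = su
            stack.append((k, node))
    return build_tree(root_key, children, labels=labels, lengths=lengths, supports=supports)


def root_gene_tree(
    gtree: Tree,
    stree: Tree,
    species_of: Callable[[str], str] = default_species_of,
) -> Tree:
    """Root a gene tree by minimising duplications + losses.

    Every edge of the unrooted topology is tried as a root position and
    scored by LCA reconciliation; ties are broken by fewer duplications,
    then by the lexicographically smallest bipartition of leaf labels.
    """
    adj, attrs = _unrooted_adjacency(gtree)
    if not attrs:  # single-edge (two-leaf) degenerate tree
        return gtree

    def bipartition_key(edge: frozenset[int]) -> tuple[str, ...]:
        u, v = sorted(edge)
        side: set[str] = set()
        stack = [(u, v)]
        while stack:
            node, came_from = stack.pop()
            if node not in adj or not (adj[node] - {came_from}):
                side.add(gtree.labels[node])
            for k in adj.get(node, set()) - {came_from}:
                stack.append((k, node))
        other = {gtree.labels[t] for t in gtree.tips()} - side
        return min(tuple(sorted(side)), tuple(sorted(other)))

    best = None
    for edge in sorted(attrs, key=bipartition_key):
        rooted = _root_on_edge(gtree, adj, attrs, edge)
        rec = lca_reconcile(rooted, stree, species_of)
        key = (
            rec.total_duplications + rec.total_losses,
            rec.total_duplications,
            bipartition_key(edge),
        )
        if best is None or key < best[0]:
            best = (key, rooted)
    return best[1]


# ----------------------------------------------------------- weak edges


def collapse_weak_edges(tree: Tree, support_threshold: float = 80.0) -> Tree:
    """Contract internal edges with support below threshold into polytomies."""
    absorbed: dict[int, int] = {}

    def rep(v: int) -> int:
        while v in absorbed:
            v = absorbed[v]
        return v

    for v in reversed(range(tree.n_nodes)):
        if tree.is_tip(v) or v == tree.root:
            continue
        s = tree.supports[v]
        if s is not None and s < support_threshold:
            absorbed[v] = tree.parent[v]

    children: dict[int, list[int]] = {}
    for v in range(tree.n_nodes):
        if v == tree.root or v in absorbed:
            continue
        p = rep(tree.parent[v])
        children.setdefault(p, []).append(v)
    for kids in children.values():
        kids.sort()
    labels = {v: tree.labels[v] for v in tree.tips()}
    lengths = {
        v: tree.lengths[v]
        for v in range(tree.n_nodes)
        if tree.lengths[v] is not None and v not in absorbed
    }
    supports = {
        v: tree.supports[v]
        for v in range(tree.n_nodes)
        if tree.supports[v] is not None and v not in absorbed
    }
    return build_tree(tree.root, children, labels=labels, lengths=lengths, supports=supports)


# -------------------------------------------------------------- orthogroups


@dataclass
class OrthoGroup:
    """A maximal speciation-only subtree of a reconciled gene tree."""

    members: tuple[str, ...]
    species_counts: Counter = field(default_factory=Counter)
    gain_node: int | None = None

    @property
    def species(self) -> set[str]:
        return set(self.species_counts)


def delimit_orthogroups(
    rec: Reconciliation,
    species_of: Callable[[str], str] = default_species_of,
) -> list[OrthoGroup]:
    """Cut the gene tree at duplication nodes and collect leaf groups.

    Every edge from a duplication node to its children is cut; each
    remaining leaf-bearing component is one orthogroup.  The gain node of
    an orthogroup is the species-tree MRCA of its species (its Dollo
    origin).
    """
    g = rec.gene_tree
    comp: dict[int, int] = {g.root: g.root}
    for v in g.preorder():
        if v == g.root:
            continue
        p = g.parent[v]
        if rec.events.get(p) == "duplication":
            comp[v] = v
        else:
            comp[v] = comp[p]
    groups: dict[int, list[int]] = {}
    for t in g.tips():
        groups.setdefault(comp[t], []).append(t)
    out = []
    for _, leaves in sorted(groups.items()):
        members = tuple(sorted(g.labels[t] for t in leaves))
        counts = Counter(species_of(m) for m in members)
        gain = rec.species_tree.mrca_tips(counts)
        out.append(OrthoGroup(members, counts, gain))
    return out
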