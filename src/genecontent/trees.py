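"""Rooted trees with stable postorder node numbering.

Species trees and gene trees share one array-based representation in which
node ids are postorder integers: every node's id is strictly larger than any
id in its subtree, and the root is always ``n_nodes - 1``.  The numbering is
a pure function of the topology and child order, so it survives Newick
round-trips and makes "node 141"-style ancestral references reproducible.

Newick parsing is delegated to :mod:`dendropy`; emission is done here so
that node-number labels and supports can be controlled exactly.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Sequence

import dendropy

__all__ = ["Tree", "build_tree", "yule_tree_shape"]


class Tree:
    """A rooted (species or gene) tree over postorder-numbered nodes.

    Attributes
    ----------
    children : list[list[int]]
        Child ids per node (empty for tips); child ids are always smaller
        than the parent id.
    parent : list[int]
        Parent id per node, ``-1`` for the root.
    labels : list[str | None]
        Tip labels (``None`` on internal nodes).
    lengths : list[float | None]
        Length of the branch above each node (``None`` if absent).
    supports : list[float | None]
        Support of the branch above each internal node, if annotated.
    """

    __slots__ = ("children", "parent", "labels", "lengths", "supports", "_tip_index")

    def __init__(
        self,
        children: list[list[int]],
        parent: list[int],
        labels: list[str | None],
        lengths: list[float | None],
        supports: list[float | None],
    ):
        self.children = children
        self.parent = parent
        self.labels = labels
        self.lengths = lengths
        self.supports = supports
        self._tip_index: dict[str, int] | None = None

    # ------------------------------------------------------------------ basics

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    def is_tip(self, v: int) -> bool:
        return not self.children[v]

    def tips(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def tip_names(self) -> list[str]:
        return [self.labels[v] for v in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for v in range(self.n_nodes) if not self.children[v])

    def tip_index(self) -> dict[str, int]:
        """Map tip label -> node id (cached)."""
        if self._tip_index is None:
            self._tip_index = {self.labels[v]: v for v in self.tips()}
        return self._tip_index

    def postorder(self) -> range:
        # node ids *are* a postorder sequence by construction
        return range(self.n_nodes)

    def preorder(self) -> Iterable[int]:
        return reversed(range(self.n_nodes))

    # ------------------------------------------------------------- ancestry

    def depths(self) -> list[int]:
        """Edge depth from the root for every node."""
        d = [0] * self.n_nodes
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + 1
        return d

    def mrca(self, nodes: Iterable[int]) -> int:
        """Most recent common ancestor of a set of node ids.

        Repeatedly lifts the minimum-id node to its parent; correct because
        every ancestor has a larger postorder id than all of its descendants.
        """
        frontier = set(nodes)
        if not frontier:
            raise ValueError("mrca of an empty node set is undefined")
        while len(frontier) > 1:
            u = min(frontier)
            frontier.remove(u)
            frontier.add(self.parent[u])
        return frontier.pop()

    def mrca_tips(self, names: Iterable[str]) -> int:
        idx = self.tip_index()
        try:
            return self.mrca(idx[n] for n in names)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown tip name {exc.args[0]!r}") from None

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff ``a`` is an ancestor of (or equal to) ``b``."""
        while b != -1 and b <= a:
            if b == a:
                return True
            b = self.parent[b]
        return False

    def subtree_nodes(self, v: int) -> list[int]:
        out: list[int] = []
        stack = [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children[u])
        return out

    def subtree_tips(self, v: int) -> list[int]:
        return [u for u in self.subtree_nodes(v) if self.is_tip(u)]

    def subtree_tip_names(self, v: int) -> list[str]:
        return [self.labels[u] for u in self.subtree_tips(v)]

    # ---------------------------------------------------------------- newick

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        order = list(dt.postorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(order)}
        children = [[idx[id(c)] for c in nd.child_nodes()] for nd in order]
        parent = [
            idx[id(nd.parent_node)] if nd.parent_node is not None else -1
            for nd in order
        ]
        labels: list[str | None] = []
        lengths: list[float | None] = []
        supports: list[float | None] = []
        for nd in order:
            if nd.is_leaf():
                name = nd.taxon.label if nd.taxon is not None else nd.label
                labels.append(name)
                supports.append(None)
            else:
                labels.append(None)
                sup = None
                if nd.label is not None:
                    try:
                        sup = float(nd.label)
                    except ValueError:
                        sup = None
                supports.append(sup)
            lengths.append(nd.edge.length)
        return cls(children, parent, labels, lengths, supports)

    def to_newick(
        self,
        include_lengths: bool | None = None,
        node_numbers: bool = False,
        include_supports: bool = True,
    ) -> str:
        """Serialize to Newick.

        With ``node_numbers=True`` internal nodes are labelled ``n<id>`` so
        the postorder numbering is visible in the output (it is recomputed
        identically on re-parse in any case).
        """
        if include_lengths is None:
            include_lengths = any(x is not None for x in self.lengths)

        def fmt(v: int) -> str:
            if self.is_tip(v):
                s = str(self.labels[v]).replace(" ", "_")
            else:
                s = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
                if node_numbers:
                    s += f"n{v}"
                elif include_supports and self.supports[v] is not None:
                    s += format(self.supports[v], "g")
            if include_lengths and self.lengths[v] is not None:
                s += f":{self.lengths[v]:g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree {self.n_tips} tips, {self.n_nodes} nodes>"


def build_tree(
    root: object,
    children: Mapping[object, Sequence[object]],
    labels: Mapping[object, str] | None = None,
    lengths: Mapping[object, float] | None = None,
    supports: Mapping[object, float] | None = None,
) -> Tree:
    """Build a :class:`Tree` from an arbitrary-keyed parent/child structure.

    Node keys may be any hashable; they are renumbered into postorder
    integers (child order preserved).
    """
    labels = labels or {}
    lengths = lengths or {}
    supports = supports or {}
    order: list[object] = []
    # iterative postorder
    stack: list[tuple[object, bool]] = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        stack.append((node, True))
        for c in reversed(list(children.get(node, ()))):
            stack.append((c, False))
    idx = {k: i for i, k in enumerate(order)}
    ch = [[idx[c] for c in children.get(k, ())] for k in order]
    par = [-1] * len(order)
    for k in order:
        for c in children.get(k, ()):
            par[idx[c]] = idx[k]
    lab = [labels.get(k) for k in order]
    lng = [lengths.get(k) for k in order]
    sup = [supports.get(k) for k in order]
    return Tree(ch, par, lab, lng, sup)


def yule_tree_shape(
    n_tips: int,
    rng,
    birth_rate: float = 1.0,
    label: Callable[[int], str] | None = None,
) -> Tree:
    """Sample a rooted binary tree under a pure-birth (Yule) process.

    Lineages split at rate ``birth_rate`` each; the simulation stops after
    the ``n_tips``-th lineage appears plus one final waiting interval so
    that terminal branches have positive length.  Tips are labelled in
    left-to-right order (default ``sp01`` ... style, zero padded).
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    if label is None:
        width = len(str(n_tips))
        label = lambda i: f"sp{i + 1:0{width}d}"

    next_id = 0

    def fresh() -> int:
        nonlocal next_id
        next_id += 1
        return next_id - 1

    root = fresh()
    children: dict[int, list[int]] = {}
    birth_time = {root: 0.0}
    active = [root]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active[i]
        left, right = fresh(), fresh()
        children[node] = [left, right]
        birth_time[left] = birth_time[right] = t
        active[i] = left
        active.append(right)
    t += rng.exponential(1.0 / (birth_rate * len(active)))

    lengths: dict[int, float] = {}
    labels: dict[int, str] = {}
    order: list[int] = []
    stack = [root]
    while stack:  # preorder, to list tips left-to-right
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(children.get(node, ())))
    tip_counter = 0
    for node in order:
        if node == root:
            lengths[node] = 0.0
        elif node in children:
            # internal branch: own birth to own split
            lengths[node] = birth_time[children[node][0]] - birth_time[node]
        else:
            lengths[node] = t - birth_time[node]
            labels[node] = label(tip_counter)
            tip_counter += 1
    return build_tree(root, children, labels=labels, lengths=lengths)
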