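"""Dollo parsimony mapping of gene-family content onto a species tree.

Under Dollo parsimony a family is gained exactly once — at the MRCA of the
species that carry it — and every absence below that gain is explained by
independent losses, one per maximal member-free subtree.  Copy-number
dynamics within a family are reconstructed on the "present" skeleton by a
minimum-|Δ| integer assignment (Sankoff-style dynamic programme over
copy-number states), with ties resolved toward the parent's value so that
spurious duplication + loss pairs are never introduced.

Aggregating the per-family reconstructions over all families yields an
:class:`EventMap`: per species-tree node, the number of gains (family
originations), duplications and losses (in gene copies) and the ancestral
copy number, satisfying exactly

    copies(node) = copies(parent) + gains + duplications - losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .trees import Tree

__all__ = [
    "DolloMapping",
    "EventMap",
    "dollo_map",
    "reconstruct_counts",
    "aggregate_events",
    "net_change",
]


# ------------------------------------------------------------- Dollo mapping


@dataclass(frozen=True)
class DolloMapping:
    """A single family's Dollo solution: one gain, a set of loss branches.

    ``loss_branches`` holds the child-end node id of every branch on which
    the family was lost (the roots of the maximal member-free subtrees
    below the gain node).
    """

    gain_node: int
    loss_branches: frozenset[int]


def dollo_map(og_species: set[str], stree: Tree) -> DolloMapping:
    """Map a presence pattern onto the species tree by Dollo parsimony."""
    if not og_species:
        raise ValueError("cannot Dollo-map an empty species set")
    tip_idx = stree.tip_index()
    unknown = set(og_species) - set(tip_idx)
    if unknown:
        raise KeyError(f"species not in tree: {sorted(unknown)}")
    present_tips = {tip_idx[s] for s in og_species}
    gain = stree.mrca(present_tips)
    # postorder flag: subtree contains a present tip
    occupied = np.zeros(stree.n_nodes, dtype=bool)
    for v in stree.postorder():
        if stree.is_tip(v):
            occupied[v] = v in present_tips
        else:
            occupied[v] = any(occupied[c] for c in stree.children[v])
    losses = set()
    stack = [gain]
    while stack:
        v = stack.pop()
        for c in stree.children[v]:
            if occupied[c]:
                stack.append(c)
            else:
                losses.add(c)
    return DolloMapping(gain, frozenset(losses))


# -------------------------------------------------------- copy-number states


def reconstruct_counts(tip_counts: Mapping[str, int], stree: Tree) -> np.ndarray:
    """Minimum-|Δ| ancestral copy numbers for one family.

    Tips carry the observed copy numbers; the gain node and the internal
    "present" skeleton (nodes with at least one carrying descendant tip)
    get integer states >= 1 minimising the summed absolute copy-number
    change along skeleton branches.  Nodes outside the skeleton are 0.
    Ties in the top-down traceback are resolved toward the parent's state,
    then toward the smaller value.
    """
    present = {s: int(k) for s, k in tip_counts.items() if int(k) > 0}
    counts = np.zeros(stree.n_nodes, dtype=int)
    if not present:
        return counts
    mapping = dollo_map(set(present), stree)
    tip_idx = stree.tip_index()
    skeleton = _skeleton_nodes(mapping, stree)

    max_state = max(present.values())
    states = np.arange(1, max_state + 1)
    S = len(states)
    delta = np.abs(states[:, None] - states[None, :])  # |s - t|
    INF = np.iinfo(np.int64).max // 4

    cost: dict[int, np.ndarray] = {}
    for v in stree.postorder():
        if v not in skeleton:
            continue
        if stree.is_tip(v):
            c = np.full(S, INF, dtype=np.int64)
            c[present[stree.labels[v]] - 1] = 0
            cost[v] = c
        else:
            c = np.zeros(S, dtype=np.int64)
            for ch in stree.children[v]:
                if ch in skeleton:
                    c = c + (cost[ch][None, :] + delta).min(axis=1)
            cost[v] = c

    # traceback from the gain node
    root_cost = cost[mapping.gain_node]
    counts[mapping.gain_node] = int(states[int(np.argmin(root_cost))])
    order = [mapping.gain_node]
    while order:
        v = order.pop()
        sv = counts[v]
        for ch in stree.children[v]:
            if ch not in skeleton:
                continue
            total = cost[ch] + np.abs(states - sv)
            best = total.min()
            cands = states[total == best]
            # prefer the parent's value, else the candidate closest to it,
            # else the smaller one
            pick = min(cands, key=lambda s: (abs(int(s) - sv), int(s)))
            counts[ch] = int(pick)
            order.append(ch)
    return counts


def _skeleton_nodes(mapping: DolloMapping, stree: Tree) -> set[int]:
    """Nodes at which the family is present under the Dollo solution."""
    skeleton = set()
    stack = [mapping.gain_node]
    while stack:
        v = stack.pop()
        skeleton.add(v)
        for c in stree.children[v]:
            if c not in mapping.loss_branches:
                stack.append(c)
    return skeleton


# ----------------------------------------------------------------- EventMap


@dataclass
class EventMap:
    """Per-node event totals and ancestral copy numbers over many families.

    ``gains`` counts family originations at a node; ``duplications`` and
    ``losses`` count gene copies added/removed on the branch above the
    node (for the root: at the root itself).  ``family_copies`` holds the
    per-family reconstructed copy number at every node (families x nodes).
    """

    tree: Tree
    gains: np.ndarray
    duplications: np.ndarray
    losses: np.ndarray
    copy_number: np.ndarray
    family_copies: pd.DataFrame | None = None
    family_gain_node: dict[str, int] | None = None

    def check_bookkeeping(self) -> None:
        """Exact integer identity at every node (root checked against 0)."""
        for v in range(self.tree.n_nodes):
            parent_copies = (
                0 if v == self.tree.root else self.copy_number[self.tree.parent[v]]
            )
            expected = (
                parent_copies
                + self.gains[v]
                + self.duplications[v]
                - self.losses[v]
            )
            if self.copy_number[v] != expected:
                raise AssertionError(
                    f"bookkeeping identity violated at node {v}: "
                    f"{self.copy_number[v]} != {expected}"
                )

    def net_changes(self) -> np.ndarray:
        return self.gains + self.duplications - self.losses

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": np.arange(self.tree.n_nodes),
                "gains": self.gains,
                "duplications": self.duplications,
                "losses": self.losses,
                "copy_number": self.copy_number,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __add__(self, other: "EventMap") -> "EventMap":
        if other.tree.n_nodes != self.tree.n_nodes:
            raise ValueError("EventMaps must share a species tree")
        fc = None
        if self.family_copies is not None and other.family_copies is not None:
            fc = pd.concat([self.family_copies, other.family_copies])
        gains_map = dict(self.family_gain_node or {})
        gains_map.update(other.family_gain_node or {})
        return EventMap(
            self.tree,
            self.gains + other.gains,
            self.duplications + other.duplications,
            self.losses + other.losses,
            self.copy_number + other.copy_number,
            fc,
            gains_map or None,
        )


def aggregate_events(
    families: pd.DataFrame | Mapping[str, Mapping[str, int]],
    stree: Tree,
    mode: str = "counts",
) -> EventMap:
    """Dollo-map every family and total gains/duplications/losses per node.

    ``families`` is a copy-number matrix (families x species).  With
    ``mode="presence"`` copy numbers are collapsed to 0/1 before
    reconstruction, so duplications vanish and only gain/loss structure
    remains.
    """
    if not isinstance(families, pd.DataFrame):
        families = pd.DataFrame.from_dict(families, orient="index").fillna(0)
    if mode == "presence":
        families = (families > 0).astype(int)
    elif mode != "counts":
        raise ValueError(f"unknown mode {mode!r}")

    N = stree.n_nodes
    gains = np.zeros(N, dtype=int)
    dups = np.zeros(N, dtype=int)
    losses = np.zeros(N, dtype=int)
    copy_number = np.zeros(N, dtype=int)
    fam_counts = np.zeros((len(families), N), dtype=int)
    gain_node: dict[str, int] = {}

    for i, (fam, row) in enumerate(families.iterrows()):
        tip_counts = {s: int(k) for s, k in row.items() if int(k) > 0}
        if not tip_counts:
            continue
        counts = reconstruct_counts(tip_counts, stree)
        fam_counts[i] = counts
        g = int(stree.mrca_tips(tip_counts))
        gain_node[str(fam)] = g
        gains[g] += 1
        dups[g] += counts[g] - 1
        for v in range(N):
            if v == g:
                continue
            p = stree.parent[v]
            if counts[v] == 0 and counts[p] == 0:
                continue
            d = int(counts[v]) - int(counts[p])
            if d > 0:
                dups[v] += d
            else:
                losses[v] += -d
        copy_number += counts

    family_copies = pd.DataFrame(
        fam_counts, index=families.index, columns=np.arange(N)
    )
    return EventMap(
        stree, gains, dups, losses, copy_number, family_copies, gain_node
    )


def net_change(gains: int, losses: int) -> int:
    """Net repertoire change on a branch: gains minus losses."""
    if gains < 0 or losses < 0:
        raise ValueError("gains and losses must be non-negative")
    return gains - losses
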