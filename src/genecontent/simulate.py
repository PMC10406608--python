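"""Synthetic data with known truth for every downstream stage.

This module is the test bed for the whole pipeline: it generates

* species trees (pure-birth),
* gene-family histories along the tree under per-branch origination /
  duplication / loss, with a full truth channel (:class:`TrueHistory`),
* planted-partition protein similarity graphs whose true family
  memberships are known, and
* annotation tables with controlled domain / localization / GO
  composition, so that planted positives for every downstream classifier
  are constructible.

The generative model is a deliberately simple stand-in: the real analysis
only *infers* events from genomes and never defines a forward process, so
the per-branch Poisson event model here is our own choice (documented in
the methods note), selected because its per-branch event counts are the
quantities the inference stage reconstructs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graphs import SimilarityGraph
from .trees import Tree, yule_tree_shape

__all__ = [
    "TrueHistory",
    "FamilyProfile",
    "simulate_species_tree",
    "simulate_gene_content",
    "simulate_similarity_graph",
    "simulate_annotations",
    "proteins_from_matrix",
]


# --------------------------------------------------------------------- trees


def simulate_species_tree(n_tips: int, seed: int, birth_rate: float = 1.0) -> Tree:
    """Rooted binary species tree under a pure-birth process.

    Deterministic for a fixed ``(n_tips, seed, birth_rate)``; branch lengths
    are in expected substitutions per site (arbitrary pure-birth units).
    """
    if n_tips < 2:
        raise ValueError(f"n_tips must be >= 2, got {n_tips}")
    rng = np.random.default_rng(seed)
    return yule_tree_shape(n_tips, rng, birth_rate=birth_rate)


# ------------------------------------------------------------- gene content


@dataclass
class TrueHistory:
    """Ground-truth per-family event history on a species tree.

    ``duplications``/``losses`` count events on the branch *above* each node
    (column = node id); ``copies`` holds the true copy number at every node.
    The bookkeeping identity

        copies[node] = copies[parent] + duplications[branch] - losses[branch]

    holds exactly at every non-origin node, and the origin node starts at
    ``1 + duplications`` on its incoming branch.
    """

    tree: Tree
    family_ids: list[str]
    origin: np.ndarray          # (F,) origin node id per family
    duplications: np.ndarray    # (F, N) events on branch above node
    losses: np.ndarray          # (F, N)
    copies: np.ndarray          # (F, N) true copy number at node
    extinct: np.ndarray         # (F,) bool: extinct in every extant tip

    def check_consistency(self) -> None:
        """Assert the bookkeeping identity for every family and node."""
        t = self.tree
        for v in t.postorder():
            if v == t.root:
                continue
            p = t.parent[v]
            at_origin = self.origin == v
            expected = np.where(
                at_origin,
                1 + self.duplications[:, v] - self.losses[:, v],
                self.copies[:, p] + self.duplications[:, v] - self.losses[:, v],
            )
            # nodes outside the origin's subtree carry no copies and no events
            inert = (self.copies[:, p] == 0) & ~at_origin
            expected = np.where(inert, 0, expected)
            if not np.array_equal(self.copies[:, v], expected):
                bad = np.nonzero(self.copies[:, v] != expected)[0][:5]
                raise AssertionError(
                    f"bookkeeping identity violated at node {v}, families {bad}"
                )
        if (self.copies < 0).any():
            raise AssertionError("negative copy number in TrueHistory")


def simulate_gene_content(
    tree: Tree,
    origination_rate: float = 1.0,
    duplication_rate: float = 0.1,
    loss_rate: float = 0.1,
    n_families: int = 100,
    seed: int = 0,
    origin: str = "uniform",
) -> tuple[pd.DataFrame, TrueHistory]:
    """Evolve gene families along a species tree with known truth.

    Each family originates exactly once at a single node (``origin`` =
    ``"uniform"`` over all nodes, ``"root"``, or ``"weighted"`` by
    ``origination_rate`` x branch length) with one copy; on every branch
    below, duplication and loss event counts are drawn from Poisson
    distributions with mean ``rate x copies x branch_length`` (length 1
    where lengths are absent).  Losses are capped so copy numbers stay
    non-negative.

    Returns
    -------
    (matrix, history)
        ``matrix`` is a families x species copy-number DataFrame with
        globally extinct families dropped; ``history`` retains every
        family (extinct ones flagged).
    """
    if min(origination_rate, duplication_rate, loss_rate) < 0:
        raise ValueError("rates must be non-negative")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    N = tree.n_nodes
    F = n_families

    blen = np.array([x if x else 1.0 for x in tree.lengths], dtype=float)
    blen[blen <= 0] = 1.0

    if origin == "root":
        origins = np.full(F, tree.root, dtype=int)
    elif origin == "uniform":
        origins = rng.integers(0, N, size=F)
    elif origin == "weighted":
        w = origination_rate * blen
        w[tree.root] = origination_rate  # root has no incoming branch
        origins = rng.choice(N, size=F, p=w / w.sum())
    else:
        raise ValueError(f"unknown origin mode {origin!r}")

    copies = np.zeros((F, N), dtype=int)
    dup = np.zeros((F, N), dtype=int)
    loss = np.zeros((F, N), dtype=int)

    for v in tree.preorder():
        t_v = blen[v] if v != tree.root else 1.0
        at_origin = origins == v
        if at_origin.any():
            d0 = rng.poisson(duplication_rate * t_v, size=int(at_origin.sum()))
            copies[at_origin, v] = 1 + d0
            dup[at_origin, v] = d0
        if v == tree.root:
            continue
        p = tree.parent[v]
        evolving = (copies[:, p] > 0) & ~at_origin
        if not evolving.any():
            continue
        k = copies[evolving, p]
        d = rng.poisson(duplication_rate * k * blen[v])
        l = rng.poisson(loss_rate * k * blen[v])
        l = np.minimum(l, k + d)
        copies[evolving, v] = k + d - l
        dup[evolving, v] = d
        loss[evolving, v] = l

    width = len(str(F))
    fids = [f"fam{i + 1:0{width}d}" for i in range(F)]
    tip_ids = tree.tips()
    tip_names = [tree.labels[v] for v in tip_ids]
    extinct = copies[:, tip_ids].sum(axis=1) == 0
    history = TrueHistory(tree, fids, origins, dup, loss, copies, extinct)
    matrix = pd.DataFrame(
        copies[:, tip_ids][~extinct],
        index=[f for f, e in zip(fids, extinct) if not e],
        columns=tip_names,
    )
    matrix.index.name = "family"
    return matrix, history


def proteins_from_matrix(matrix: pd.DataFrame) -> dict[str, list[str]]:
    """Expand a copy-number matrix into per-family protein id lists.

    Protein ids have the form ``species|family.copy`` so that the species
    is recoverable from the id (the convention used throughout).
    """
    out: dict[str, list[str]] = {}
    for fam, row in matrix.iterrows():
        members = []
        for sp, k in row.items():
            members.extend(f"{sp}|{fam}.{i + 1}" for i in range(int(k)))
        out[str(fam)] = members
    return out


# --------------------------------------------------------- similarity graphs


def simulate_similarity_graph(
    true_partition: Mapping[str, Sequence[str]],
    intra_edge_prob: float = 0.9,
    inter_edge_prob: float = 0.02,
    seed: int = 0,
    coverage_fail_rate: float = 0.1,
    intra_score: tuple[float, float] = (200.0, 20.0),
    inter_score: tuple[float, float] = (40.0, 10.0),
) -> SimilarityGraph:
    """Planted-partition similarity graph over proteins with known families.

    Within-family pairs get edges with probability ``intra_edge_prob``,
    strong scores and tiny e-values; between-family pairs with probability
    ``inter_edge_prob`` and weak scores.  A ``coverage_fail_rate`` fraction
    of edges is given coverages that fail the standard asymmetric
    coverage filter (20% longer / 80% shorter), so filtering is testable.
    """
    if not true_partition:
        raise ValueError("partition must be non-empty")
    if not 0 <= inter_edge_prob <= 1:
        raise ValueError("inter_edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fam_of = {p: f for f, ps in true_partition.items() for p in ps}
    proteins = sorted(fam_of)
    rows = []
    for a, b in itertools.combinations(proteins, 2):
        same = fam_of[a] == fam_of[b]
        p_edge = intra_edge_prob if same else inter_edge_prob
        if rng.random() >= p_edge:
            continue
        if same:
            score = max(float(rng.normal(*intra_score)), 1.0)
            evalue = 10.0 ** -rng.uniform(20, 80)
        else:
            score = max(float(rng.normal(*inter_score)), 1.0)
            evalue = 10.0 ** -rng.uniform(4.5, 9)
        if rng.random() < coverage_fail_rate:
            cov_long, cov_short = rng.uniform(0.25, 1.0), rng.uniform(0.3, 0.75)
        else:
            cov_long, cov_short = rng.uniform(0.3, 1.0), rng.uniform(0.85, 1.0)
        rows.append((a, b, score, evalue, cov_long, cov_short))
    edges = pd.DataFrame(
        rows, columns=["query", "subject", "score", "evalue", "cov_long", "cov_short"]
    )
    self_scores = {p: intra_score[0] * 1.5 for p in proteins}
    return SimilarityGraph(edges, nodes=proteins, self_scores=self_scores)


# -------------------------------------------------------------- annotations


@dataclass
class FamilyProfile:
    """Generating probabilities for one family's annotations.

    ``domains`` maps domain id -> per-protein carry probability; a
    probability of 1.0 plants the domain in every member, which is how
    exact classifier positives (TF, transporter, fungal-specific) are
    constructed.
    """

    domains: Mapping[str, float] = field(default_factory=dict)
    localization: str = "cytosol"
    loc_score: tuple[float, float] = (20.0, 2.0)
    signal_peptide_prob: float = 0.0
    transmembrane_prob: float = 0.0
    go_terms: tuple[str, ...] = ()
    length: tuple[float, float] = (400.0, 50.0)


def simulate_annotations(
    matrix: pd.DataFrame,
    profiles: Mapping[str, FamilyProfile] | None = None,
    seed: int = 0,
    default_profile: FamilyProfile | None = None,
    supergroup_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Annotation table for every protein implied by a copy-number matrix.

    Columns: protein, species, family, length, domains (semicolon list),
    localization, loc_score, signal_peptide, transmembrane, go_terms,
    supergroup.  Deterministic for fixed seed.
    """
    rng = np.random.default_rng(seed)
    profiles = profiles or {}
    default_profile = default_profile or FamilyProfile()
    supergroup_of = supergroup_of or {}
    rows = []
    for fam, members in proteins_from_matrix(matrix).items():
        prof = profiles.get(fam, default_profile)
        for prot in members:
            sp = prot.split("|", 1)[0]
            doms = sorted(d for d, p in prof.domains.items() if rng.random() < p)
            length = max(int(round(rng.normal(*prof.length))), 30)
            rows.append(
                {
                    "protein": prot,
                    "species": sp,
                    "family": fam,
                    "length": length,
                    "domains": ";".join(doms),
                    "localization": prof.localization,
                    "loc_score": float(np.round(rng.normal(*prof.loc_score), 3)),
                    "signal_peptide": bool(rng.random() < prof.signal_peptide_prob),
                    "transmembrane": bool(rng.random() < prof.transmembrane_prob),
                    "go_terms": ";".join(prof.go_terms),
                    "supergroup": supergroup_of.get(sp, "Holomycota"),
                }
            )
    return pd.DataFrame(rows)
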