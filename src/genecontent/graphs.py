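"""Containers for protein similarity graphs and homologous-group partitions."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = ["SimilarityGraph", "HGPartition"]

EDGE_COLUMNS = ["query", "subject", "score", "evalue", "cov_long", "cov_short"]


@dataclass
class SimilarityGraph:
    """Undirected weighted protein similarity edge list.

    ``edges`` has columns query, subject, score, evalue, cov_long,
    cov_short (coverage of the longer / shorter protein).  Self-hits are
    never stored as edges; self-match scores live in ``self_scores``.
    ``nodes`` lists every protein, including ones with no surviving edges,
    so singleton clusters are representable.
    """

    edges: pd.DataFrame
    nodes: list[str] = field(default_factory=list)
    self_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ("query", "subject") if c not in self.edges.columns]
        if missing:
            raise ValueError(f"edge table lacks columns {missing}")
        if not self.nodes:
            self.nodes = sorted(
                set(self.edges["query"]).union(self.edges["subject"])
            )
        self_hits = self.edges["query"] == self.edges["subject"]
        if self_hits.any():
            raise ValueError("self-edges must not be stored in the edge list")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self, weight: str = "score") -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.query, row.subject, weight=getattr(row, weight))
        return g

    # ----------------------------------------------------------------- I/O

    def write_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, nodes: Iterable[str] | None = None) -> "SimilarityGraph":
        """Read a BLAST/MMSeqs2-style tabular edge list.

        Accepts either this package's headers or the common
        qseqid/sseqid/evalue/bitscore/qcov/scov dialect.
        """
        df = pd.read_csv(path, sep="\t")
        renames = {
            "qseqid": "query",
            "sseqid": "subject",
            "bitscore": "score",
            "qcov": "cov_long",
            "scov": "cov_short",
        }
        df = df.rename(columns={k: v for k, v in renames.items() if k in df.columns})
        df = df[df["query"] != df["subject"]].reset_index(drop=True)
        return cls(df, nodes=sorted(nodes) if nodes is not None else [])


@dataclass
class HGPartition:
    """Total, disjoint assignment of proteins to homologous groups."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        self._members: dict[str, set[str]] = {}
        for prot, hg in self.assignments.items():
            self._members.setdefault(hg, set()).add(prot)
        if any(not m for m in self._members.values()):
            raise ValueError("empty homologous group in partition")

    @property
    def members(self) -> dict[str, set[str]]:
        return self._members

    @property
    def n_groups(self) -> int:
        return len(self._members)

    def group_of(self, protein: str) -> str:
        return self.assignments[protein]

    def as_sets(self) -> set[frozenset[str]]:
        """Label-free view, for comparing partitions."""
        return {frozenset(m) for m in self._members.values()}

    def relabel(self) -> "HGPartition":
        """Canonical HG ids: ``HG<k>`` ordered by smallest member name."""
        ordered = sorted(self._members.values(), key=min)
        width = len(str(len(ordered)))
        assignments = {
            p: f"HG{i + 1:0{width}d}" for i, mem in enumerate(ordered) for p in mem
        }
        return HGPartition(assignments)

    @classmethod
    def from_groups(cls, groups: Mapping[str, Iterable[str]]) -> "HGPartition":
        return cls({p: hg for hg, ps in groups.items() for p in ps})

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            sorted(self.assignments.items()), columns=["protein", "hg_id"]
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "HGPartition":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["protein"], df["hg_id"])))
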