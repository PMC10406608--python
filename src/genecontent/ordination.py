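"""Gene-content ordination: binary distances, PCoA and a spanning tree.

Species are embedded by classical multidimensional scaling (PCoA) of a
binary (Jaccard-complement) distance computed over the presence/absence
profile of selected homologous groups, and a minimum spanning tree over
the same distances is reported for overlay.  HG selection follows the
repertoire-analysis convention: at least four member proteins and >= 50%
conservation in at least one named clade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "OrdinationResult",
    "select_pcoa_hgs",
    "binary_distance",
    "pcoa",
    "mst",
]


def select_pcoa_hgs(
    hg_sizes: Mapping[str, int],
    hg_species: Mapping[str, set[str]],
    clades: Mapping[str, set[str]],
    min_proteins: int = 4,
    min_conservation: float = 0.5,
) -> set[str]:
    """HGs with >= 4 proteins and >= 50% conservation in any clade."""
    out = set()
    for hg, size in hg_sizes.items():
        if size < min_proteins:
            continue
        species = hg_species.get(hg, set())
        for clade in clades.values():
            if clade and len(species & clade) / len(clade) >= min_conservation:
                out.add(hg)
                break
    return out


def binary_distance(presence: pd.DataFrame) -> pd.DataFrame:
    """Jaccard-complement distance between species' presence profiles.

    ``presence`` is species x HGs (any positive entry counts as present).
    d(i, j) = (b + c) / (a + b + c) with a = shared presences and b, c the
    asymmetric ones; two all-absent rows are at distance 0.
    """
    X = (presence.to_numpy() > 0).astype(int)
    inter = X @ X.T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, (union - inter) / np.where(union > 0, union, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=presence.index, columns=presence.index)


@dataclass
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix.

    ``coordinates`` is species x axes (positive-eigenvalue axes only);
    ``eigenvalues`` holds the full descending spectrum, negative values
    included, and ``proportion_explained`` is each positive eigenvalue's
    share of the positive spectrum.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame | np.ndarray, k: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis of a symmetric distance matrix.

    Double-centres -D^2/2, eigendecomposes, and returns coordinates
    eigenvector x sqrt(eigenvalue) for positive-eigenvalue axes (the first
    ``k`` if requested).  Negative eigenvalues are reported but never used
    for coordinates; no correction is applied.
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        ids = list(range(D.shape[0]))
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    if k is not None:
        coords = coords[:, :k]
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=ids,
            columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
        ),
        eigenvalues=eigvals,
        proportion_explained=proportion,
    )


def mst(d: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Minimum spanning tree of a distance matrix (Kruskal).

    Edges are considered in increasing (weight, id_u, id_v) order, so ties
    resolve lexicographically; the result has exactly n - 1 edges for a
    connected (finite-distance) input.
    """
    if isinstance(d, pd.DataFrame):
        ids = list(d.index)
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        ids = list(range(D.shape[0]))
    n = D.shape[0]
    edges = sorted(
        (D[i, j], ids[i], ids[j])
        for i in range(n)
        for j in range(i + 1, n)
    )
    parent = {u: u for u in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rows = []
    for w, u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            rows.append((u, v, w))
            if len(rows) == n - 1:
                break
    return pd.DataFrame(rows, columns=["u", "v", "weight"])
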