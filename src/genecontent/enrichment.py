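"""GO term over-representation by Fisher's exact test.

Per term the one-sided hypergeometric tail is computed for the study set
against the population.  Two modes are offered: ``classic`` tests every
term independently; ``elim`` walks the GO DAG from the most specific terms
upward and, whenever a term is significant, removes its annotated genes
from all ancestor terms before these are tested — a decorrelation step
that suppresses the parent-term echo of a specific signal.  (The weight01
algorithm popular in the R ecosystem mixes elim with weighting; rankings
from the two can differ.)

Raw p-values are reported, with an optional Benjamini-Hochberg column;
significance defaults to raw P < 0.05.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy import stats

__all__ = ["fisher_enrichment", "read_go_dag", "hypergeom_pvalue"]


def hypergeom_pvalue(k: int, n_study: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K annotated, n study)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n_study))


def read_go_dag(source: str | Path | Iterable[tuple[str, str]]) -> nx.DiGraph:
    """GO DAG as a child -> parent digraph.

    Accepts an edge iterable, a 2-column TSV (child, parent), or an OBO
    file (parsed with :mod:`obonet`; only ``is_a`` parentage is used).
    """
    dag = nx.DiGraph()
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix == ".obo":
            import obonet

            g = obonet.read_obo(path)
            # obonet edges run child -> parent already
            dag.add_edges_from((u, v) for u, v, key in g.edges(keys=True) if key == "is_a")
        else:
            df = pd.read_csv(path, sep="\t", header=None, comment="#")
            dag.add_edges_from(zip(df[0], df[1]))
    else:
        dag.add_edges_from(source)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("GO graph contains a cycle")
    return dag


def fisher_enrichment(
    study: set[str],
    population: set[str],
    term_map: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
    method: str = "classic",
    dag: nx.DiGraph | None = None,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-term over-representation of a study set within a population.

    ``term_map`` sends gene -> term ids; annotations are used as given
    (propagate up the DAG beforehand if desired).  With ``method="elim"``
    a DAG must be supplied; terms are processed most-specific-first and a
    significant term's genes are eliminated from its ancestors' gene sets
    before those are tested.
    """
    study = set(study)
    population = set(population)
    if not study:
        raise ValueError("study set must be non-empty")
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    if method not in ("classic", "elim"):
        raise ValueError(f"unknown method {method!r}")
    if method == "elim" and dag is None:
        raise ValueError("elim mode requires a GO DAG")

    genes_of: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in population:
            continue
        for t in terms:
            genes_of.setdefault(t, set()).add(gene)

    if method == "classic":
        order = sorted(genes_of)
    else:
        # most specific first: reverse topological order of child -> parent
        in_dag = [t for t in nx.topological_sort(dag) if t in genes_of]
        order = in_dag + sorted(set(genes_of) - set(dag.nodes))

    eliminated: dict[str, set[str]] = {t: set() for t in genes_of}
    N, n_study = len(population), len(study)
    rows = []
    for term in order:
        genes = genes_of[term] - eliminated[term]
        K = len(genes)
        k = len(genes & study)
        p = hypergeom_pvalue(k, n_study, K, N) if K else 1.0
        rows.append(
            {
                "term": term,
                "study_count": k,
                "study_size": n_study,
                "population_count": K,
                "population_size": N,
                "pvalue": min(p, 1.0),
                "significant": p < alpha,
            }
        )
        if method == "elim" and p < alpha and term in dag:
            for anc in nx.descendants(dag, term):  # ancestors in GO sense
                if anc in eliminated:
                    eliminated[anc] |= genes_of[term]
    out = pd.DataFrame(rows).sort_values(["pvalue", "term"]).reset_index(drop=True)
    if bh and len(out):
        out["p_bh"] = stats.false_discovery_control(out["pvalue"], method="bh")
    return out
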