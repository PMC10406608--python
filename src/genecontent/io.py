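"""Plain-text readers and writers for the pipeline's tables.

All tabular artefacts are TSV; trees are Newick; configuration is YAML.
Every writer round-trips with the corresponding reader.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .trees import Tree

__all__ = [
    "read_tree",
    "write_tree",
    "read_copy_matrix",
    "write_copy_matrix",
    "read_annotations",
    "write_annotations",
    "read_groups",
    "write_groups",
]


def read_tree(path: str | Path) -> Tree:
    return Tree.from_newick(Path(path).read_text())


def write_tree(tree: Tree, path: str | Path, node_numbers: bool = False) -> None:
    Path(path).write_text(tree.to_newick(node_numbers=node_numbers) + "\n")


def read_copy_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_copy_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="family")


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("signal_peptide", "transmembrane"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    for col in ("domains", "go_terms"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_groups(path: str | Path) -> dict[str, set[str]]:
    """Clade/group definition YAML: name -> list of species."""
    raw = yaml.safe_load(Path(path).read_text())
    return {str(k): set(v) for k, v in raw.items()}


def write_groups(groups: Mapping[str, set[str]], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump({k: sorted(v) for k, v in groups.items()}, sort_keys=True)
    )
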