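"""Rule-based repertoire classifiers over homologous groups.

Every classifier here is an exact rule, not a statistical model: given the
annotation table (domains, predicted localization with score, protein
length, signal-peptide and transmembrane flags, GO terms) and the
event-map output of the Dollo stage, each function applies one of the
repertoire definitions used in comparative fungal genomics:

* conservation of an HG within a named species group (>= 70% rule),
* protist-conserved HGs lost on the way to Dikarya,
* "novel core" HGs (gained after a reference ancestor, >= 70% conserved
  among the descendants of their gain node),
* fungal-specific domains (>= 99% of occurrences in Holomycota) and the
  HGs carried by them (>= 75% of members),
* majority annotation (> 50%, strict),
* transcription-factor families by DNA-binding-domain content with an
  exclusion-domain veto,
* plasma-membrane transporters (majority domain rule + modal localization
  with median score > 15),
* small secreted proteins (< 300 aa, signal peptide, no transmembrane
  helix),
* net-change dynamics ranking along a chain of ancestors, and the
  Shannon diversity of a TF-family repertoire.

Boundary conventions follow the source wording per rule: "> 50%" is
strict; the 70%, 75% and 99% thresholds are inclusive.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dollo import EventMap
from .trees import Tree

__all__ = [
    "conservation",
    "protist_conserved_lost",
    "novel_core",
    "fungal_specific_domains",
    "hg_fungal_domain_flag",
    "majority_annotation",
    "classify_tf",
    "classify_transporter",
    "classify_ssp",
    "dynamics_rank",
    "shannon_diversity",
    "classify_hgs",
]


# -------------------------------------------------------------- conservation


def conservation(hg_species: set[str], group: set[str]) -> float:
    """Fraction of a group's species in which the HG has a protein."""
    if not group:
        raise ValueError("conservation against an empty group is undefined")
    return len(set(hg_species) & set(group)) / len(group)


def protist_conserved_lost(
    hg_species: Mapping[str, set[str]],
    groups: Mapping[str, set[str]],
    event_map: EventMap,
    dikarya_species: set[str],
    holomycota_node: int | None = None,
    threshold: float = 0.70,
) -> set[str]:
    """HGs ancestrally present in Holomycota but absent from all Dikarya.

    An HG qualifies if it is present (per the Dollo reconstruction) at the
    Holomycota ancestor, has no member in any Dikarya species, and either
    reaches >= ``threshold`` conservation in at least one of the named
    groups or emerged at/before the Holomycota node.
    """
    if event_map.family_copies is None or event_map.family_gain_node is None:
        raise ValueError("event map lacks per-family reconstructions")
    if holomycota_node is None:
        holomycota_node = event_map.tree.root
    tree = event_map.tree
    out = set()
    for hg, species in hg_species.items():
        if hg not in event_map.family_gain_node:
            continue
        if event_map.family_copies.loc[hg, holomycota_node] < 1:
            continue
        if species & dikarya_species:
            continue
        early = tree.is_ancestor(event_map.family_gain_node[hg], holomycota_node)
        well_conserved = any(
            conservation(species, g) >= threshold for g in groups.values() if g
        )
        if early or well_conserved:
            out.add(hg)
    return out


def novel_core(
    gain_nodes: Mapping[str, int],
    hg_species: Mapping[str, set[str]],
    stree: Tree,
    reference_node: int,
    threshold: float = 0.70,
) -> set[str]:
    """HGs gained strictly after a reference ancestor and kept by its clade.

    The conservation requirement is evaluated over *all* descendant tips
    of the HG's own gain node and is inclusive (>= threshold).
    """
    out = set()
    for hg, gain in gain_nodes.items():
        if gain == reference_node or not stree.is_ancestor(reference_node, gain):
            continue
        clade = set(stree.subtree_tip_names(gain))
        if conservation(hg_species.get(hg, set()), clade) >= threshold:
            out.add(hg)
    return out


# ------------------------------------------------------------------ domains


def fungal_specific_domains(
    table: pd.DataFrame,
    focal_group: str = "Holomycota",
    threshold: float = 0.99,
) -> set[str]:
    """Domains with >= 99% of their occurrences in the focal supergroup.

    ``table`` is domains x supergroups occurrence counts; zero-count rows
    are skipped with a warning.
    """
    sums = table.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(
            f"skipping {int(zero.sum())} zero-count domains", RuntimeWarning,
            stacklevel=2,
        )
    share = table.loc[~zero, focal_group] / sums[~zero]
    return set(share.index[share >= threshold])


def hg_fungal_domain_flag(
    protein_domains: Sequence[set[str]],
    fungal_domains: set[str],
    threshold: float = 0.75,
) -> bool:
    """True iff >= 75% of member proteins carry a fungal-specific domain."""
    if not protein_domains:
        return False
    hits = sum(1 for doms in protein_domains if doms & fungal_domains)
    return hits / len(protein_domains) >= threshold


def majority_annotation(flags: Sequence[bool], threshold: float = 0.5) -> bool:
    """Strict-majority rule: more than ``threshold`` of members flagged."""
    if len(flags) == 0:
        raise ValueError("majority of an empty homologous group is undefined")
    return sum(bool(f) for f in flags) / len(flags) > threshold


# -------------------------------------------------------------- TF calling


def classify_tf(
    protein_domains: Sequence[set[str]],
    dbd_families: Mapping[str, str],
    exclusion_domains: set[str],
) -> str | None:
    """TF family of an HG from its DNA-binding-domain content, or None.

    The HG is a TF if a strict majority of members carry a DBD and no
    exclusion domain (ribonucleases, metallopeptidases, chromatin
    remodelling, splicing, ...) itself passes the majority rule.  The
    family is that of the most frequent DBD (ties: lexicographic).
    """
    if not protein_domains:
        return None
    dbds = set(dbd_families)
    has_dbd = [bool(doms & dbds) for doms in protein_domains]
    if not majority_annotation(has_dbd):
        return None
    for excl in sorted(exclusion_domains):
        if majority_annotation([excl in doms for doms in protein_domains]):
            return None
    freq: dict[str, int] = {}
    for doms in protein_domains:
        for d in doms & dbds:
            freq[d] = freq.get(d, 0) + 1
    top = max(sorted(freq), key=freq.get)
    return dbd_families[top]


def classify_transporter(
    protein_domains: Sequence[set[str]],
    transporter_domains: set[str],
    localizations: Sequence[tuple[str, float]],
    pm_label: str = "plasma membrane",
    score_min: float = 15.0,
) -> bool:
    """Transporter call: majority domain rule + plasma-membrane consensus.

    The HG must contain > 50% transporter-specific domains and the modal
    localization among members must be the plasma membrane with a median
    score strictly greater than ``score_min``.  Localization-mode ties
    fail the call.
    """
    if not protein_domains or not localizations:
        return False
    has_dom = [bool(doms & transporter_domains) for doms in protein_domains]
    if not majority_annotation(has_dom):
        return False
    labels = [lab for lab, _ in localizations]
    counts = pd.Series(labels).value_counts()
    top = counts.index[0]
    if top != pm_label or (len(counts) > 1 and counts.iloc[1] == counts.iloc[0]):
        return False
    pm_scores = [s for lab, s in localizations if lab == pm_label]
    return float(np.median(pm_scores)) > score_min


def classify_ssp(
    length: int,
    signal_peptide: bool,
    transmembrane: bool,
    max_length: int = 300,
) -> bool:
    """Small secreted protein: short, secreted, not membrane-anchored."""
    return length < max_length and bool(signal_peptide) and not transmembrane


# ----------------------------------------------------------------- dynamics


def dynamics_rank(
    event_map: EventMap,
    node_path: Sequence[int],
) -> pd.DataFrame:
    """Rank HGs by summed relative net change along a chain of ancestors.

    ``node_path`` must be a root-to-descendant chain (each node the parent
    of the next).  Per HG the score is the sum over consecutive branches of
    (copies(child) - copies(parent)) / max(copies(parent), 1); a family
    gained on the path therefore contributes its copy count.  Returned
    sorted descending (most expanding first).
    """
    if event_map.family_copies is None:
        raise ValueError("event map lacks per-family reconstructions")
    tree = event_map.tree
    for a, b in zip(node_path, node_path[1:]):
        if tree.parent[b] != a:
            raise ValueError(f"node path is not a parent-child chain at {a}->{b}")
    fc = event_map.family_copies
    score = np.zeros(len(fc))
    for a, b in zip(node_path, node_path[1:]):
        parent = fc[a].to_numpy()
        child = fc[b].to_numpy()
        score += (child - parent) / np.maximum(parent, 1)
    out = pd.DataFrame({"hg": fc.index, "net_change_score": score})
    return out.sort_values(
        ["net_change_score", "hg"], ascending=[False, True]
    ).reset_index(drop=True)


def shannon_diversity(family_counts: Iterable[float]) -> float:
    """Shannon index (natural log) of a repertoire's family composition."""
    counts = np.asarray(list(family_counts), dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("at least one family must be non-empty")
    return float(stats.entropy(counts / total))


# ----------------------------------------------------------- bulk interface


def classify_hgs(
    annotations: pd.DataFrame,
    membership: Mapping[str, str],
    dbd_families: Mapping[str, str] | None = None,
    exclusion_domains: set[str] | None = None,
    transporter_domains: set[str] | None = None,
    extracellular_label: str = "extracellular",
    pm_label: str = "plasma membrane",
    pm_score_min: float = 15.0,
    ssp_max_length: int = 300,
) -> pd.DataFrame:
    """Per-HG classification table from an annotation table + membership.

    Returns one row per HG with the size, species breadth, majority
    extracellular flag, SSP majority flag, TF family and transporter flag.
    """
    dbd_families = dbd_families or {}
    exclusion_domains = exclusion_domains or set()
    transporter_domains = transporter_domains or set()
    ann = annotations.copy()
    ann["hg"] = ann["protein"].map(membership)
    ann = ann.dropna(subset=["hg"])
    rows = []
    for hg, sub in ann.groupby("hg", sort=True):
        doms = [
            set(d.split(";")) if isinstance(d, str) and d else set()
            for d in sub["domains"]
        ]
        locs = list(zip(sub["localization"], sub["loc_score"].astype(float)))
        ssp_flags = [
            classify_ssp(int(l), bool(sp), bool(tm), ssp_max_length)
            for l, sp, tm in zip(
                sub["length"], sub["signal_peptide"], sub["transmembrane"]
            )
        ]
        rows.append(
            {
                "hg": hg,
                "n_proteins": len(sub),
                "n_species": sub["species"].nunique(),
                "extracellular": majority_annotation(
                    [lab == extracellular_label for lab in sub["localization"]]
                ),
                "ssp": majority_annotation(ssp_flags),
                "tf_family": classify_tf(doms, dbd_families, exclusion_domains),
                "transporter": classify_transporter(
                    doms, transporter_domains, locs, pm_label, pm_score_min
                ),
            }
        )
    return pd.DataFrame(rows)
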