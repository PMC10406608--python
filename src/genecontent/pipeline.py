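"""End-to-end orchestration: simulate -> cluster -> Dollo -> classify -> ordinate.

A :class:`PipelineConfig` holds every stage toggle and threshold (defaults
are the analysis' standard values); :func:`run_pipeline` executes the
enabled stages in order into a run directory and writes a JSON manifest
with the configuration, seed and a checksum for every output, so reruns
with an identical configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as gio
from .classify import classify_hgs
from .clustering import MergeCriteria, cluster_pipeline
from .dollo import aggregate_events
from .graphs import HGPartition
from .ordination import binary_distance, mst, pcoa
from .simulate import (
    proteins_from_matrix,
    simulate_annotations,
    simulate_gene_content,
    simulate_similarity_graph,
    simulate_species_tree,
)

logger = logging.getLogger("genecontent")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class StageToggles:
    simulate: bool = True
    cluster: bool = True
    dollo: bool = True
    classify: bool = True
    ordinate: bool = True


@dataclass
class SimulationParams:
    n_tips: int = 12
    n_families: int = 150
    origination_rate: float = 1.0
    duplication_rate: float = 0.1
    loss_rate: float = 0.1
    origin: str = "uniform"
    intra_edge_prob: float = 0.9
    inter_edge_prob: float = 0.02
    coverage_fail_rate: float = 0.1


@dataclass
class ClusteringParams:
    inflation: float = 2.0
    evalue_max: float = 1e-4
    cov_long_min: float = 0.2
    cov_short_min: float = 0.8
    merge_evalue: float = 1e-10
    merge_cov_profile: float = 0.75
    merge_cov_consensus: float = 0.20
    merge_self_fraction: float = 0.75
    max_diameter: int = 3


@dataclass
class DolloParams:
    mode: str = "counts"  # or "presence"
    support_threshold: float = 80.0


@dataclass
class ClassifyParams:
    conservation_threshold: float = 0.70
    majority_threshold: float = 0.50
    fungal_domain_threshold: float = 0.99
    hg_fungal_threshold: float = 0.75
    pm_score_min: float = 15.0
    ssp_max_length: int = 300


@dataclass
class OrdinationParams:
    min_proteins: int = 4
    min_conservation: float = 0.5


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: StageToggles = field(default_factory=StageToggles)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    dollo: DolloParams = field(default_factory=DolloParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    ordination: OrdinationParams = field(default_factory=OrdinationParams)
    species_tree: str | None = None   # paths, used when simulation is off
    copy_matrix: str | None = None

    def validate(self) -> None:
        c = self.clustering
        if c.inflation <= 1:
            raise ValueError("inflation must be > 1")
        for name in ("merge_cov_profile", "merge_cov_consensus", "merge_self_fraction"):
            v = getattr(c, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} out of range (0, 1]: {v}")
        if c.max_diameter < 1:
            raise ValueError("max_diameter must be >= 1")
        if self.dollo.mode not in ("counts", "presence"):
            raise ValueError(f"unknown dollo mode {self.dollo.mode!r}")
        for name in ("conservation_threshold", "majority_threshold",
                     "fungal_domain_threshold", "hg_fungal_threshold"):
            v = getattr(self.classify, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} out of range (0, 1]: {v}")
        if not self.stages.simulate and (
            self.species_tree is None or self.copy_matrix is None
        ):
            raise ValueError(
                "with simulation disabled, species_tree and copy_matrix paths "
                "are required"
            )

    # ------------------------------------------------------------- (de)serial

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        def build(dc_type, data, ctx):
            names = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(data) - set(names)
            if unknown:
                raise ValueError(
                    f"unknown configuration key(s) {sorted(unknown)} in {ctx}"
                )
            kwargs = {}
            for key, value in data.items():
                f = names[key]
                if dataclasses.is_dataclass(f.type) or (
                    isinstance(f.default_factory, type)
                    and dataclasses.is_dataclass(f.default_factory)
                ):
                    kwargs[key] = build(f.default_factory, value or {}, key)
                else:
                    kwargs[key] = value
            return dc_type(**kwargs)

        cfg = build(cls, raw or {}, "top level")
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute the enabled stages in order; return the written manifest."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        logger.info("wrote %s", path)
        return path

    sim = config.simulation
    if config.stages.simulate:
        tree = simulate_species_tree(sim.n_tips, seed=config.seed)
        matrix, history = simulate_gene_content(
            tree,
            origination_rate=sim.origination_rate,
            duplication_rate=sim.duplication_rate,
            loss_rate=sim.loss_rate,
            n_families=sim.n_families,
            seed=config.seed + 1,
            origin=sim.origin,
        )
        emit("species_tree.nwk", lambda p: gio.write_tree(tree, p, node_numbers=True))
        emit("copy_matrix.tsv", lambda p: gio.write_copy_matrix(matrix, p))
    else:
        tree = gio.read_tree(config.species_tree)
        matrix = gio.read_copy_matrix(config.copy_matrix)

    partition = None
    if config.stages.cluster:
        families = proteins_from_matrix(matrix)
        graph = simulate_similarity_graph(
            families,
            intra_edge_prob=sim.intra_edge_prob,
            inter_edge_prob=sim.inter_edge_prob,
            coverage_fail_rate=sim.coverage_fail_rate,
            seed=config.seed + 2,
        )
        emit("similarity.tsv", graph.write_tsv)
        cl = config.clustering
        partition = cluster_pipeline(
            graph,
            inflation=cl.inflation,
            cov_long_min=cl.cov_long_min,
            cov_short_min=cl.cov_short_min,
            evalue_max=cl.evalue_max,
            criteria=MergeCriteria(
                evalue_cutoff=cl.merge_evalue,
                coverage_profile=cl.merge_cov_profile,
                coverage_consensus=cl.merge_cov_consensus,
                self_match_fraction=cl.merge_self_fraction,
                max_diameter=cl.max_diameter,
            ),
        )
        emit("hg_membership.tsv", partition.write_tsv)

    event_map = None
    if config.stages.dollo:
        event_map = aggregate_events(matrix, tree, mode=config.dollo.mode)
        event_map.check_bookkeeping()
        emit("event_map.tsv", event_map.write_tsv)

    if config.stages.classify:
        annotations = simulate_annotations(matrix, seed=config.seed + 3)
        emit("annotations.tsv", lambda p: gio.write_annotations(annotations, p))
        membership = (
            partition.assignments
            if partition is not None
            else {p: fam for fam, ps in proteins_from_matrix(matrix).items() for p in ps}
        )
        table = classify_hgs(
            annotations,
            membership,
            pm_score_min=config.classify.pm_score_min,
            ssp_max_length=config.classify.ssp_max_length,
        )
        emit(
            "hg_classification.tsv",
            lambda p: table.to_csv(p, sep="\t", index=False),
        )

    if config.stages.ordinate:
        presence = (matrix > 0).astype(int).T  # species x families
        dist = binary_distance(presence)
        ord_res = pcoa(dist)
        emit(
            "pcoa_coordinates.tsv",
            lambda p: ord_res.coordinates.to_csv(p, sep="\t", index_label="species"),
        )
        emit(
            "pcoa_eigenvalues.tsv",
            lambda p: pd.Series(ord_res.eigenvalues, name="eigenvalue").to_csv(
                p, sep="\t", index_label="axis"
            ),
        )
        emit("mst_edges.tsv", lambda p: mst(dist).to_csv(p, sep="\t", index=False))

    manifest = {
        "package": "genecontent",
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
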