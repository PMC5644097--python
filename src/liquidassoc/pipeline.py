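"""End-to-end pipeline: preprocess -> null -> scan -> filters -> exports.

Configuration is a flat YAML mapping mirroring ``PipelineConfig``; unknown
keys are rejected. Every artifact directory receives a ``manifest.json``
recording the seed, the config hash, package versions and the stage counts,
so a run is auditable and reruns with identical config are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .io import (
    config_hash,
    read_expression_matrix,
    read_trait,
    write_edges,
    write_expression_matrix,
    write_manifest,
    write_reference,
    write_results,
    write_trait_results,
)
from .model import GeneTraitLA, LiquidAssociationScan
from .screening import ScanConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline knobs in one flat record (YAML-loadable)."""

    matrix: str = ""
    out_dir: str = "la_run"
    trait: str | None = None
    candidates: str | None = None  # newline-separated gene IDs for trait-LA
    focus_genes: list[str] = field(default_factory=list)
    max_missing_fraction: float = 0.20
    tail_quantile: float = 1e-5
    top_k_laps: int = 1000
    conditional_r_max: float = 0.17
    conditional_la_min: float = 0.60
    leader_min_linkages: int = 500_000
    n_permutations: int = 10_000
    n_perm_local: int = 10_000
    p_cutoff: float = 1e-4
    null_sampler: str = "cells"
    seed: int = 0

    def __post_init__(self) -> None:
        self.scan_config()  # validates the numeric thresholds

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            tail_quantile=self.tail_quantile,
            top_k_laps=self.top_k_laps,
            conditional_r_max=self.conditional_r_max,
            conditional_la_min=self.conditional_la_min,
            leader_min_linkages=self.leader_min_linkages,
            n_permutations=self.n_permutations,
            seed=self.seed,
            null_sampler=self.null_sampler,
        )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full screen and write all artifacts under ``out_dir``.

    Stages: preprocess -> reference distribution -> genome-wide scan ->
    top-k / conditional-LAP filters -> leaders -> (optional) gene-trait LA
    -> network export -> manifest. Any stage failure aborts with a
    stage-tagged message.

    Returns the manifest dictionary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(asdict(config))
    stage = "preprocess"
    try:
        matrix = read_expression_matrix(config.matrix)
        model = LiquidAssociationScan(
            matrix,
            config=config.scan_config(),
            max_missing_fraction=config.max_missing_fraction,
        )
        write_expression_matrix(model.matrix, out / "matrix.transformed.tsv")

        stage = "reference"
        reference = model.build_reference()
        write_reference(reference, out / "reference.tsv")

        stage = "scan"
        res = model.fit(reference=reference)
        res.to_tsv(out / "triplets.tsv")

        stage = "filters"
        write_results(res.conditional_laps(), out / "conditional_laps.tsv")
        counts = res.linkage_counts()
        with (out / "leaders.tsv").open("w") as fh:
            fh.write("gene_id\tsign\tn_linkages\n")
            for sign in ("positive", "negative"):
                idx = 0 if sign == "positive" else 1
                for gid in res.leaders(sign):
                    fh.write(f"{gid}\t{sign}\t{counts[gid][idx]}\n")

        stage = "network"
        edges, n_nodes, n_edges = res.network(config.focus_genes or None)
        write_edges(edges, out / "network_edges.tsv")

        trait_counts: dict[str, int] = {}
        if config.trait and config.candidates:
            stage = "trait-la"
            trait = read_trait(config.trait)
            candidates = [
                line.strip()
                for line in Path(config.candidates).read_text().splitlines()
                if line.strip()
            ]
            tmodel = GeneTraitLA(
                model.matrix, trait, candidates,
                p_cutoff=config.p_cutoff,
                n_perm=config.n_perm_local,
                seed=config.seed,
            )
            tres = tmodel.fit()
            tres.to_tsv(out / "trait_results.tsv")
            n_co, n_contra, n_both, n_scouts = tres.regulation_summary()
            trait_counts = {
                "trait_triplets": len(tres.results),
                "co_regulated_genes": n_co,
                "contra_regulated_genes": n_contra,
                "both_polarities": n_both,
                "unique_mediators": n_scouts,
            }

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": cfg_hash,
            "config": asdict(config),
            "network_nodes": n_nodes,
            "network_edges": n_edges,
            "stage_counts": {**res.stage_counts(), **trait_counts},
        }
        write_manifest(out / "manifest.json", manifest)
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"failed at stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest
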