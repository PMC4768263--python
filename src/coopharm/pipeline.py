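"""End-to-end discovery workflow driven by a single YAML config.

``run_discovery`` reads one or two screens, grows forests, correlates
nodes, selects pairs, optionally cross-confirms between screens, and
writes every stage artifact plus a run manifest to the output directory.
Stages are pure functions of their inputs, so reruns on unchanged inputs
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .io import (DrugTargetTable, GeneSetCollection, SensitivityMetric,
                 read_common_cancer_genes, read_dataset, read_drug_targets,
                 read_gene_sets, write_tree)
from .correlation import records_to_frame
from .model import CooperativeBiomarkerModel, DiscoveryResults
from .pairs import pairs_to_frame
from .tree import TreeParams

logger = logging.getLogger(__name__)

__all__ = ["DatasetConfig", "RunConfig", "ValidationError", "run_discovery"]


class ValidationError(ValueError):
    """Config/input problem detected before any computation (exit code 2)."""


@dataclass
class DatasetConfig:
    name: str
    alterations: Path
    expression: Path
    responses: Path
    metric: SensitivityMetric
    drugs: list[str] | None = None  # None = every drug in the response table


@dataclass
class RunConfig:
    datasets: list[DatasetConfig]
    gene_sets: Path
    drug_targets: Path
    common_cancer_genes: Path
    output_dir: Path
    tree: TreeParams = field(default_factory=TreeParams)
    fdr: float = 0.05
    min_cells: int = 5
    bh_scope: str = "per_node"
    forest_roots: str = "first"          # "first" | "all"
    require_cross_dataset: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = path.parent

        def _p(rel) -> Path:
            p = Path(rel)
            return p if p.is_absolute() else base / p

        try:
            datasets = [
                DatasetConfig(
                    name=d["name"],
                    alterations=_p(d["alterations"]),
                    expression=_p(d["expression"]),
                    responses=_p(d["responses"]),
                    metric=SensitivityMetric(
                        d["metric"]["name"],
                        bool(d["metric"]["higher_is_sensitive"]),
                    ),
                    drugs=list(d["drugs"]) if d.get("drugs") else None,
                )
                for d in doc["datasets"]
            ]
            tree_doc = doc.get("tree", {})
            flags = doc.get("flags", {})
            cfg = cls(
                datasets=datasets,
                gene_sets=_p(doc["gene_sets"]),
                drug_targets=_p(doc["drug_targets"]),
                common_cancer_genes=_p(doc["common_cancer_genes"]),
                output_dir=_p(doc["output_dir"]),
                tree=TreeParams(**tree_doc),
                fdr=float(doc.get("fdr", 0.05)),
                min_cells=int(doc.get("min_cells", 5)),
                bh_scope=flags.get("bh_scope", "per_node"),
                forest_roots=flags.get("forest_roots", "first"),
                require_cross_dataset=bool(
                    flags.get("require_cross_dataset", False)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"invalid run config {path}: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 1 <= len(self.datasets) <= 2:
            raise ValidationError("config must declare one or two datasets")
        for ds in self.datasets:
            for p in (ds.alterations, ds.expression, ds.responses):
                if not Path(p).exists():
                    raise ValidationError(f"input file not found: {p}")
        for p in (self.gene_sets, self.drug_targets,
                  self.common_cancer_genes):
            if not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")
        if not 0.0 < self.fdr < 1.0:
            raise ValidationError("fdr must be in (0, 1)")
        if self.bh_scope not in ("per_node", "per_tree"):
            raise ValidationError("flags.bh_scope must be per_node|per_tree")
        if self.forest_roots not in ("first", "all"):
            raise ValidationError("flags.forest_roots must be first|all")

    def snapshot(self) -> dict:
        doc = dataclasses.asdict(self)
        return json.loads(json.dumps(doc, default=str))


def _write_atomic_json(doc: dict, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    os.replace(tmp, path)


def run_discovery(config: RunConfig) -> dict[str, dict[str, DiscoveryResults]]:
    """Run every stage for every dataset/drug; returns
    dataset name -> drug -> results.  Artifacts and a manifest are written
    to ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.snapshot(),
        "version": __version__,
        "stages": {},
        "warnings": [],
        "status": "running",
    }
    t0 = time.perf_counter()
    try:
        results = _run_stages(config, out, manifest)
        manifest["status"] = "ok"
        return results
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failure"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest["wall_clock_s"] = round(time.perf_counter() - t0, 3)
        _write_atomic_json(manifest, out / "manifest.json")


def _run_stages(config: RunConfig, out: Path, manifest: dict):
    pathways = read_gene_sets(config.gene_sets)
    targets = read_drug_targets(config.drug_targets)
    common = read_common_cancer_genes(config.common_cancer_genes)

    results: dict[str, dict[str, DiscoveryResults]] = {}
    for ds_cfg in config.datasets:
        t_stage = time.perf_counter()
        dataset = read_dataset(ds_cfg.alterations, ds_cfg.expression,
                               ds_cfg.responses, ds_cfg.metric,
                               name=ds_cfg.name)
        model = CooperativeBiomarkerModel(
            dataset, pathways, targets, common,
            tree_params=config.tree, fdr=config.fdr,
            min_cells=config.min_cells, bh_scope=config.bh_scope,
            all_forest_roots=(config.forest_roots == "all"),
        )
        drugs = ds_cfg.drugs or dataset.drugs
        unknown = [d for d in drugs if d not in dataset.drugs]
        if unknown:
            raise ValidationError(
                f"dataset {ds_cfg.name}: unknown drug(s) {unknown}")
        per_drug: dict[str, DiscoveryResults] = {}
        for drug in drugs:
            res = model.fit(drug)
            per_drug[drug] = res
            safe = drug.replace("/", "_")
            for i, tree in enumerate(res.forest.trees, start=1):
                write_tree(tree, out / f"{ds_cfg.name}.{safe}.tree{i}.json")
            records_to_frame(res.correlations, ds_cfg.name).to_csv(
                out / f"{ds_cfg.name}.{safe}.correlations.tsv",
                sep="\t", index=False)
        results[ds_cfg.name] = per_drug
        manifest["stages"][ds_cfg.name] = {
            "cells": len(dataset.cells),
            "features": len(dataset.features),
            "drugs": len(drugs),
            "trees": sum(len(r.forest) for r in per_drug.values()),
            "correlation_records": sum(len(r.correlations)
                                       for r in per_drug.values()),
            "pairs": sum(len(r.pairs) for r in per_drug.values()),
            "wall_clock_s": round(time.perf_counter() - t_stage, 3),
        }

    if len(config.datasets) == 2:
        name_a, name_b = (c.name for c in config.datasets)
        all_a = [p for r in results[name_a].values() for p in r.pairs]
        all_b = [p for r in results[name_b].values() for p in r.pairs]
        from .pairs import cross_dataset_confirm
        confirmed, report = cross_dataset_confirm(all_a, all_b, targets)
        if config.require_cross_dataset:
            confirmed = [p for p in confirmed
                         if p.flags.cross_dataset_confirmed]
        pairs_to_frame(confirmed).to_csv(out / f"{name_a}.pairs.tsv",
                                         sep="\t", index=False)
        pairs_to_frame(all_b).to_csv(out / f"{name_b}.pairs.tsv",
                                     sep="\t", index=False)
        _write_atomic_json(dataclasses.asdict(report),
                           out / "concordance.json")
        manifest["stages"]["concordance"] = {
            "pairs_a": report.pairs_a, "pairs_b": report.pairs_b,
            "shared": report.shared, "jaccard": report.jaccard,
        }
    else:
        name_a = config.datasets[0].name
        all_a = [p for r in results[name_a].values() for p in r.pairs]
        pairs_to_frame(all_a).to_csv(out / f"{name_a}.pairs.tsv",
                                     sep="\t", index=False)
        logger.info("single-dataset run: concordance stage skipped")
    return results
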