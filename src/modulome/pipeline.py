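"""Pipeline orchestration: configuration, staged execution, run provenance.

A run executes qc → center → (dimension scan) → decompose → define → enrich →
diffact → activetrn over an expression TSV, metadata CSV and draft-TRN CSV,
writing every stage's tabular output plus a manifest (resolved config, seeds,
input hashes, stage file lists) into the output directory. Defaults are the
study-scale parameters (100 restarts, tolerance 1e-7, DBSCAN eps 0.1 / min
seed 50, QC cutoff 0.95, activity threshold 5, FDR 0.05, KS alpha 0.05);
desk-scale runs lower n_runs/min_cluster_seed together, keeping the rule that
a robust component recurs in at least half the restarts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .active_trn import build_active_trn, ks_active_imodulons
from .activity import diff_activity
from .compendium import (
    center_to_reference,
    filter_replicates,
    load_expression,
    replicate_correlation_summary,
    write_expression,
)
from .enrichment import RegulonTable, enrich_regulons
from .ica import decompose, select_dimension
from .imodulons import define_imodulons, explained_variance, imodulon_table, membership_table

logger = logging.getLogger("modulome.pipeline")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with study-scale defaults."""

    min_corr: float = 0.95
    log2: bool = False
    dimension: int | None = None  # None -> run the dimension scan
    dim_min: int = 20
    dim_max: int = 215
    dim_step: int = 5
    n_runs: int = 100
    tolerance: float = 1e-7
    epsilon: float = 0.1
    min_cluster_seed: int = 50
    max_iter: int = 1000
    k2_cutoff: float = 50.0
    activity_threshold: float = 5.0
    fdr_level: float = 0.05
    ks_alpha: float = 0.05
    ks_fdr: bool = False  # BH-correct the KS screen across iModulons
    master_seed: int = 42
    # condition ids driving the comparison stages
    diff_group1_conditions: list[str] = field(default_factory=list)
    diff_group2_conditions: list[str] = field(default_factory=list)
    reference_conditions: list[str] = field(default_factory=list)
    target_conditions: list[str] = field(default_factory=list)

    def validate(self, n_samples: int | None = None) -> None:
        positive = {
            "min_corr": self.min_corr, "n_runs": self.n_runs,
            "tolerance": self.tolerance, "epsilon": self.epsilon,
            "min_cluster_seed": self.min_cluster_seed,
            "activity_threshold": self.activity_threshold,
            "fdr_level": self.fdr_level, "ks_alpha": self.ks_alpha,
        }
        for name, value in positive.items():
            if value <= 0:
                raise PipelineError(f"config: {name} must be positive, got {value}")
        if self.dim_min > self.dim_max:
            raise PipelineError("config: dim_min must be <= dim_max")
        if n_samples is not None:
            top = self.dimension if self.dimension is not None else self.dim_max
            if top > n_samples - 1:
                raise PipelineError(
                    f"config: ICA dimension {top} must be < n_samples ({n_samples})"
                )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _samples_for(metadata, conditions: list[str]) -> list[str]:
    return metadata.index[metadata["condition_id"].isin(conditions)].tolist()


def run_pipeline(
    config: PipelineConfig,
    expr_path,
    meta_path,
    trn_path,
    out_dir,
) -> dict:
    """Run every configured stage; returns the manifest (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "modulome_version": __version__,
        "master_seed": config.master_seed,
        "inputs": {
            "expression": _sha256(expr_path),
            "metadata": _sha256(meta_path),
            "trn": _sha256(trn_path),
        },
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                outputs = fn()
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            manifest["stages"][name] = outputs
            return outputs

        return wrap

    # ---- qc --------------------------------------------------------------
    compendium = load_expression(expr_path, meta_path, log2=config.log2)
    config.validate(n_samples=len(compendium.samples))

    @stage("qc")
    def _qc():
        nonlocal compendium
        compendium, removed = filter_replicates(compendium, min_corr=config.min_corr)
        summary = replicate_correlation_summary(compendium)
        (out / "removed_samples.txt").write_text("\n".join(removed) + ("\n" if removed else ""))
        with open(out / "correlation_summary.json", "w") as fh:
            json.dump({k: summary[k] for k in ("median", "min", "n_pairs")}, fh)
        write_expression(compendium, out / "filtered_expression.tsv")
        return ["filtered_expression.tsv", "removed_samples.txt", "correlation_summary.json"]

    # ---- center ----------------------------------------------------------
    @stage("center")
    def _center():
        nonlocal compendium
        compendium = center_to_reference(compendium)
        write_expression(compendium, out / "centered_expression.tsv")
        return ["centered_expression.tsv"]

    # ---- decompose (with optional dimension scan) ------------------------
    X = compendium.values
    dim_holder = {}

    @stage("decompose")
    def _decompose():
        if config.dimension is not None:
            dim = config.dimension
        else:
            dim, diagnostics = select_dimension(
                X, dim_min=config.dim_min, dim_max=config.dim_max,
                step=config.dim_step, n_runs=config.n_runs,
                tolerance=config.tolerance, epsilon=config.epsilon,
                min_cluster_seed=config.min_cluster_seed,
                master_seed=config.master_seed,
            )
            diagnostics.to_csv(out / "dimension_scan.tsv", sep="\t", index=False)
        d = decompose(
            X, dim, n_runs=config.n_runs, tolerance=config.tolerance,
            epsilon=config.epsilon, min_cluster_seed=config.min_cluster_seed,
            master_seed=config.master_seed, max_iter=config.max_iter,
        )
        dim_holder["decomposition"] = d
        M = d.M.copy()
        M.index.name = "gene_id"
        M.to_csv(out / "M.tsv", sep="\t")
        d.A.to_csv(out / "A.tsv", sep="\t")
        files = ["M.tsv", "A.tsv"]
        if config.dimension is None:
            files.append("dimension_scan.tsv")
        return files

    # ---- define ----------------------------------------------------------
    @stage("define")
    def _define():
        d = dim_holder["decomposition"]
        ims = define_imodulons(d, X=X, k2_cutoff=config.k2_cutoff)
        dim_holder["imodulons"] = ims
        table = imodulon_table(ims)
        table["total_explained_variance"] = explained_variance(d, X)
        table.to_csv(out / "imodulons.csv", index=False)
        membership_table(ims).to_csv(out / "membership.csv", index=False)
        return ["imodulons.csv", "membership.csv"]

    # ---- enrich ----------------------------------------------------------
    trn = RegulonTable.from_csv(trn_path)

    @stage("enrich")
    def _enrich():
        result = enrich_regulons(
            dim_holder["imodulons"], trn, universe=set(compendium.genes)
        )
        result.to_csv(out / "enrichment.csv", index=False)
        return ["enrichment.csv"]

    # ---- differential activity -------------------------------------------
    A = dim_holder["decomposition"].A
    A_named = A.copy()
    A_named.index = [im.name for im in dim_holder["imodulons"]]
    meta = compendium.metadata

    @stage("diffact")
    def _diffact():
        g1 = _samples_for(meta, config.diff_group1_conditions)
        g2 = _samples_for(meta, config.diff_group2_conditions)
        result = diff_activity(
            A_named, g1, g2,
            activity_threshold=config.activity_threshold,
            fdr_level=config.fdr_level,
        )
        result.to_csv(out / "diff_activity.csv")
        return ["diff_activity.csv"]

    # ---- active TRN ------------------------------------------------------
    @stage("activetrn")
    def _activetrn():
        ref = _samples_for(meta, config.reference_conditions)
        tgt = _samples_for(meta, config.target_conditions)
        active = ks_active_imodulons(
            A_named, ref, tgt, alpha=config.ks_alpha, fdr=config.ks_fdr
        )
        net = build_active_trn(
            active, dim_holder["imodulons"], trn,
            condition_id="+".join(config.target_conditions),
        )
        net.write(out / "active_trn_edges.csv", out / "active_trn_nodes.csv")
        with open(out / "active_imodulons.json", "w") as fh:
            json.dump(sorted(active), fh)
        return ["active_trn_edges.csv", "active_trn_nodes.csv", "active_imodulons.json"]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
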