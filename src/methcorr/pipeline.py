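"""End-to-end workflow: partition -> impute -> discover -> score -> fit ->
gate -> infer (-> map), with a machine-readable run manifest.

The manifest records package/library versions, the seed, every scientific
threshold, a hash of the scientific configuration, and checksums of the
input files.  Each output file is stamped with the config hash in a leading
comment line, so artifacts from runs with different thresholds can never be
confused.  A run is deterministic: the same config and seed reproduce every
output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .dataio import (
    BetaMatrix,
    ExpressionMatrix,
    GeneModelTable,
    MCSMatrix,
    MethCorrMatrix,
    ValidationError,
    read_beta_matrix,
    read_expression_matrix,
    write_beta_matrix,
    write_gene_models,
    write_mcs_matrix,
    write_methcorr_matrix,
)
from .discovery import (
    SamplePartition,
    impute_missing,
    partition_cohort,
    select_correlated_cpgs,
    spearman_scan,
)
from .methmap import build_map, write_edge_list
from .modeling import IRnaMatrix, fit_gene_models, infer_expression
from .scoring import compute_mcs

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_pipeline_arrays"]


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the published method constants."""

    expr_path: str | None = None
    beta_path: str | None = None
    out_dir: str | None = None
    alpha: float = 0.01
    max_per_sign: int = 100
    r2_min: float = 0.16
    rmse_improvement: float = 0.05
    map_cutoff: float = 0.126
    cv_repeats: int = 10
    cv_folds: int = 10
    seed: int = 0
    strict: bool = True
    fractions: tuple[float, float, float] = (0.4, 0.4, 0.2)
    impute_k: int = 10
    exclude_probes: tuple[str, ...] = ()
    with_map: bool = True
    require_sign_concordance: bool = True
    rank_by_abs: bool = True

    def validate(self) -> None:
        for name in ("alpha", "r2_min", "rmse_improvement", "map_cutoff"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if self.cv_repeats < 1 or self.cv_folds < 2:
            raise ValidationError("cv_repeats >= 1 and cv_folds >= 2 required")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("partition fractions must sum to 1")
        if self.impute_k < 1:
            raise ValidationError("impute_k must be >= 1")

    def science_dict(self) -> dict:
        d = asdict(self)
        for key in ("expr_path", "beta_path", "out_dir"):
            d.pop(key)
        d["fractions"] = list(self.fractions)
        d["exclude_probes"] = sorted(self.exclude_probes)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.science_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    partition: SamplePartition
    matrix: MethCorrMatrix
    mcs: MCSMatrix
    models: GeneModelTable
    irna: IRnaMatrix
    graph: nx.Graph | None
    manifest: dict


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline_arrays(expr: ExpressionMatrix, beta: BetaMatrix,
                        config: RunConfig) -> PipelineResult:
    """Run the full workflow on in-memory matrices (no file output)."""
    config.validate()
    samples = [s for s in expr.sample_ids if s in set(beta.sample_ids)]
    if len(samples) < 10:
        raise ValidationError("need >= 10 samples shared by both matrices")
    expr = expr.subset_samples(samples)
    beta = beta.subset_samples(samples)

    if config.exclude_probes:
        keep = [p for p in beta.probe_ids if p not in set(config.exclude_probes)]
        beta = BetaMatrix(beta.data.loc[keep])
    if beta.has_missing():
        beta = impute_missing(beta, k=config.impute_k)

    partition = partition_cohort(samples, config.fractions, config.seed)
    rec1 = spearman_scan(expr, beta, partition.set("set1"), "set1")
    rec2 = spearman_scan(expr, beta, partition.set("set2"), "set2")
    matrix = select_correlated_cpgs(
        rec1, rec2, alpha=config.alpha, max_per_sign=config.max_per_sign,
        require_sign_concordance=config.require_sign_concordance,
        rank_by_abs=config.rank_by_abs)
    mcs = compute_mcs(beta, matrix, strict=config.strict)
    models = fit_gene_models(
        mcs, expr, partition, repeats=config.cv_repeats,
        folds=config.cv_folds, seed=config.seed,
        rmse_improvement=config.rmse_improvement, r2_min=config.r2_min)
    irna = infer_expression(models, mcs, accepted_only=True)
    graph = build_map(matrix, cutoff=config.map_cutoff) if config.with_map else None

    manifest = {
        "methcorr_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.science_dict(),
        "config_hash": config.config_hash(),
        "n_samples": len(samples),
        "n_probes": len(beta.probe_ids),
        "n_genes_input": len(expr.gene_ids),
        "n_genes_with_correlated_cpgs": len(matrix),
        "n_genes_accepted": int(models.data["accepted"].sum()),
        "inputs": {},
    }
    return PipelineResult(partition, matrix, mcs, models, irna, graph, manifest)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Read inputs from config paths, run the workflow, write all artifacts."""
    config.validate()
    if not (config.expr_path and config.beta_path and config.out_dir):
        raise ValidationError("expr_path, beta_path and out_dir are required")
    expr = read_expression_matrix(config.expr_path)
    beta = read_beta_matrix(config.beta_path)
    result = run_pipeline_arrays(expr, beta, config)
    result.manifest["inputs"] = {
        "expr": {"path": str(config.expr_path), "sha256": _sha256(config.expr_path)},
        "beta": {"path": str(config.beta_path), "sha256": _sha256(config.beta_path)},
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={config.config_hash()}"
    with open(out / "partition.tsv", "w") as fh:
        fh.write(f"# {stamp}\n")
        result.partition.to_frame().to_csv(fh, sep="\t", index=False)
    write_methcorr_matrix(result.matrix, out / "matrix.tsv", comment=stamp)
    write_mcs_matrix(result.mcs, out / "mcs.tsv", comment=stamp)
    write_gene_models(result.models, out / "models.tsv", comment=stamp)
    with open(out / "irna.tsv", "w") as fh:
        fh.write(f"# {stamp}\n")
        result.irna.data.to_csv(fh, sep="\t", index_label="gene_id",
                                float_format="%.10g")
    if result.graph is not None:
        write_edge_list(result.graph, out / "map_edges.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result
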