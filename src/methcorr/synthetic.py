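"""Synthetic cohorts with the statistical structure the method assumes.

Two coupling mechanisms between methylation and expression are emulated:

* **direct** genes — a latent promoter activity u drives the gene's
  expression linearly (RNA = B0 + B1*u) and is written into two dedicated
  driver CpGs, one hypomethylated with activity (beta = 1 - u, the
  negatively correlated driver) and one methylated with activity (beta = u,
  the positively correlated driver), so a MethCORR gene with both signs
  exists by construction;
* **celltype** genes — samples are mixtures of cell types (Dirichlet
  proportions); each cell type hypomethylates its own marker CpGs
  (delta-beta >= 0.3 vs. other types) and expresses its own genes, so
  expression and marker methylation co-vary only through the mixture —
  the indirect association the genome-wide scan exploits;
* **null** genes — expression independent of all methylation.

Beta noise is Gaussian truncated (clipped) to [0, 1]; expression noise is
Gaussian with floor 0 (log2(FPKM+1) scale).  A fraction of beta entries can
be masked missing to emulate failed probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import BetaMatrix, ExpressionMatrix, ValidationError

__all__ = ["CellTypeReference", "TruthSet", "simulate_reference",
           "simulate_cohort"]

#: Default expression noise sd: ~0.3x the direct-gene signal sd, which is
#: |B1| * sd(Uniform(0.1, 0.9)) = 4 * 0.231 = 0.92 under the defaults.
DEFAULT_NOISE_SD = 0.28


@dataclass
class CellTypeReference:
    """Per-cell-type methylation and expression profiles.

    ``beta_profiles``: types x probes, in [0, 1]; each type's marker probes
    are >= 0.3 less methylated in that type than in every other type.
    ``expr_profiles``: types x genes, non-negative.
    """

    type_names: list[str]
    probe_ids: list[str]
    beta_profiles: np.ndarray
    gene_ids: list[str]
    expr_profiles: np.ndarray
    marker_probes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.beta_profiles.shape != (len(self.type_names), len(self.probe_ids)):
            raise ValidationError("beta_profiles shape mismatch")
        if self.expr_profiles.shape != (len(self.type_names), len(self.gene_ids)):
            raise ValidationError("expr_profiles shape mismatch")
        if ((self.beta_profiles < 0) | (self.beta_profiles > 1)).any():
            raise ValidationError("reference beta profiles must lie in [0,1]")
        if (self.expr_profiles < 0).any():
            raise ValidationError("reference expression must be non-negative")

    @property
    def n_types(self) -> int:
        return len(self.type_names)


@dataclass
class TruthSet:
    """Ground truth per simulated gene.

    Columns: gene_id, mechanism (direct/celltype/null), driver_pos_probe,
    driver_neg_probe (NA for non-direct genes), b0, b1, noise_sd.
    """

    data: pd.DataFrame

    def mechanism(self, gene: str) -> str:
        return str(self.data.set_index("gene_id").loc[gene, "mechanism"])

    def genes(self, mechanism: str) -> list[str]:
        sub = self.data[self.data["mechanism"] == mechanism]
        return list(sub["gene_id"])

    def drivers(self, gene: str) -> dict[str, str]:
        """Driver probes keyed by expected correlation sign ('+', '-')."""
        row = self.data.set_index("gene_id").loc[gene]
        out = {}
        for sign, col in (("+", "driver_pos_probe"), ("-", "driver_neg_probe")):
            v = row[col]
            if isinstance(v, str) and v != "NA":
                out[sign] = v
        return out

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.10g",
                         na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "TruthSet":
        return cls(pd.read_csv(path, sep="\t", na_values=["NA"]))


def simulate_reference(n_types: int, n_probes: int,
                       n_marker_probes_per_type: int, seed: int,
                       n_genes: int = 100,
                       marker_low: float = 0.1,
                       marker_high: float = 0.8) -> CellTypeReference:
    """Build a cell-type reference with hypomethylated marker probes.

    Background probes share a Beta(2, 2)-distributed methylation level across
    all types; each type's marker probes sit at ``marker_low`` in that type
    and ``marker_high`` elsewhere, forcing a delta-beta of >= 0.3 by
    construction.  Each gene is assigned to one type in which it is highly
    expressed (~8 on the log2(FPKM+1) scale) and lowly expressed (~1-3)
    elsewhere.
    """
    if n_marker_probes_per_type * n_types > n_probes:
        raise ValidationError("marker probes exceed total probes")
    if marker_high - marker_low < 0.3:
        raise ValidationError("marker contrast must give delta-beta >= 0.3")
    rng = np.random.default_rng(seed)
    type_names = [f"type{t + 1}" for t in range(n_types)]
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    background = rng.beta(2.0, 2.0, size=n_probes)
    beta = np.tile(background, (n_types, 1))
    marker_probes: dict[str, list[str]] = {}
    cursor = 0
    for t, name in enumerate(type_names):
        idx = np.arange(cursor, cursor + n_marker_probes_per_type)
        cursor += n_marker_probes_per_type
        beta[:, idx] = marker_high
        beta[t, idx] = marker_low
        marker_probes[name] = [probe_ids[i] for i in idx]
    gene_ids = [f"ctgene{i:04d}" for i in range(n_genes)]
    owner = rng.integers(0, n_types, size=n_genes)
    expr = rng.uniform(1.0, 3.0, size=(n_types, n_genes))
    expr[owner, np.arange(n_genes)] = rng.uniform(7.0, 9.0, size=n_genes)
    return CellTypeReference(type_names, probe_ids, beta, gene_ids, expr,
                             marker_probes)


def simulate_cohort(ref: CellTypeReference, n_samples: int,
                    n_direct_genes: int, n_null_genes: int,
                    noise_sd: float = DEFAULT_NOISE_SD,
                    missing_frac: float = 0.0, seed: int = 0,
                    beta_noise_sd: float = 0.05,
                    dirichlet_alpha: float = 1.0,
                    direct_b1: float = 4.0
                    ) -> tuple[BetaMatrix, ExpressionMatrix, TruthSet]:
    """Simulate a matched methylation + expression cohort with ground truth.

    Sample cell-type mixtures are Dirichlet(alpha); beta is the
    mixture-weighted reference plus truncated Gaussian noise; cell-type gene
    expression is the mixture-weighted type profile plus noise.  Each direct
    gene draws a latent promoter activity u ~ Uniform(0.1, 0.9) per sample,
    overrides its two dedicated driver probes with beta = u (positive driver)
    and beta = 1 - u (negative driver) plus beta noise, and sets expression
    to B0 + B1 * u + noise.  Null genes are independent noise.
    ``missing_frac`` of beta entries are then masked missing.
    """
    if n_samples < 1 or noise_sd < 0:
        raise ValidationError("parameters must be positive")
    if not 0 <= missing_frac <= 0.05:
        raise ValidationError("missing_frac must be in [0, 0.05]")
    n_bg = len(ref.probe_ids) - sum(len(v) for v in ref.marker_probes.values())
    if 2 * n_direct_genes > n_bg:
        raise ValidationError("not enough background probes for driver CpGs")
    rng = np.random.default_rng(seed)
    n_probes = len(ref.probe_ids)
    W = rng.dirichlet(np.full(ref.n_types, dirichlet_alpha), size=n_samples)

    beta = W @ ref.beta_profiles  # samples x probes
    beta = np.clip(beta + rng.normal(0.0, beta_noise_sd,
                                     size=(n_samples, n_probes)), 0.0, 1.0)

    # driver probes for direct genes: last background probes (never markers)
    marker_ids = {p for v in ref.marker_probes.values() for p in v}
    bg_indices = [i for i, p in enumerate(ref.probe_ids) if p not in marker_ids]
    neg_idx = bg_indices[-n_direct_genes:] if n_direct_genes else []
    pos_idx = bg_indices[-2 * n_direct_genes:-n_direct_genes] if n_direct_genes else []
    u = np.empty((n_samples, 0))
    if n_direct_genes:
        u = rng.uniform(0.1, 0.9, size=(n_samples, n_direct_genes))
        pos_b = u.copy()
        neg_b = 1.0 - u
        if beta_noise_sd > 0:
            pos_b = np.clip(pos_b + rng.normal(0.0, beta_noise_sd, size=u.shape),
                            0.0, 1.0)
            neg_b = np.clip(neg_b + rng.normal(0.0, beta_noise_sd, size=u.shape),
                            0.0, 1.0)
        beta[:, pos_idx] = pos_b
        beta[:, neg_idx] = neg_b

    rows = []
    expr_rows = []
    # cell-type genes
    ct_expr = W @ ref.expr_profiles  # samples x genes
    ct_expr = np.maximum(ct_expr + rng.normal(0.0, noise_sd, size=ct_expr.shape),
                         0.0)
    for j, gene in enumerate(ref.gene_ids):
        expr_rows.append((gene, ct_expr[:, j]))
        rows.append((gene, "celltype", "NA", "NA", np.nan, np.nan, noise_sd))
    # direct genes
    b0 = rng.uniform(0.5, 2.0, size=n_direct_genes)
    for j in range(n_direct_genes):
        gene = f"dirgene{j:04d}"
        signal = b0[j] + direct_b1 * u[:, j]
        y = np.maximum(signal + rng.normal(0.0, noise_sd, size=n_samples), 0.0)
        expr_rows.append((gene, y))
        rows.append((gene, "direct", ref.probe_ids[pos_idx[j]],
                     ref.probe_ids[neg_idx[j]], b0[j], direct_b1, noise_sd))
    # null genes
    for j in range(n_null_genes):
        gene = f"nullgene{j:04d}"
        y = np.maximum(rng.normal(3.0, 1.0, size=n_samples), 0.0)
        expr_rows.append((gene, y))
        rows.append((gene, "null", "NA", "NA", np.nan, np.nan, 1.0))

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    beta = beta.T  # probes x samples
    if missing_frac > 0:
        mask = rng.random(beta.shape) < missing_frac
        # never blank out an entire probe row
        full = mask.all(axis=1)
        mask[full, 0] = False
        beta = np.where(mask, np.nan, beta)
    beta_m = BetaMatrix(pd.DataFrame(beta, index=ref.probe_ids,
                                     columns=sample_ids))
    expr_m = ExpressionMatrix(pd.DataFrame(
        np.vstack([v for _, v in expr_rows]),
        index=[g for g, _ in expr_rows], columns=sample_ids))
    truth = TruthSet(pd.DataFrame(
        rows, columns=["gene_id", "mechanism", "driver_pos_probe",
                       "driver_neg_probe", "b0", "b1", "noise_sd"]))
    return beta_m, expr_m, truth
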