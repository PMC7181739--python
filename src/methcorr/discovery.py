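"""Dual-discovery-set identification of expression-correlated CpG sites.

The cohort is split 40/40/20 into two discovery sets and a validation set.
Genome-wide Spearman correlations between every gene's expression
(log2(FPKM+1)) and every CpG's methylation beta-value are computed
independently in the two discovery sets.  Pairs significant (two-sided
p < 0.01) with a concordant correlation sign in both sets are ranked by
|rho| within each set, ordered by rank sum, and the top <=100 CpGs per sign
are kept per gene.  Genes lacking either sign are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import (
    BetaMatrix,
    ExpressionMatrix,
    GeneProbeSets,
    MethCorrMatrix,
    ProbeEntry,
    ValidationError,
)

__all__ = [
    "SamplePartition",
    "partition_cohort",
    "impute_missing",
    "qc_filter_probes",
    "spearman_matrix",
    "spearman_scan",
    "select_correlated_cpgs",
]


# ---------------------------------------------------------------------------
# Cohort partitioning
# ---------------------------------------------------------------------------

@dataclass
class SamplePartition:
    """Disjoint, exhaustive assignment of samples to set1/set2/set3."""

    assignments: dict[str, str]
    seed: int

    def set(self, label: str) -> list[str]:
        return [s for s, l in self.assignments.items() if l == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": list(self.assignments), "set": list(self.assignments.values())}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, seed: int = -1) -> "SamplePartition":
        return cls(dict(zip(df["sample"].astype(str), df["set"].astype(str))), seed)


def partition_cohort(sample_ids: Sequence[str],
                     fractions: tuple[float, float, float] = (0.4, 0.4, 0.2),
                     seed: int = 0) -> SamplePartition:
    """Randomly split samples into two discovery sets and one validation set.

    Set sizes are round(f*n) for set1 and set2; the remainder goes to set3.
    Deterministic given the seed; no stratification.
    """
    n = len(sample_ids)
    if n < 10:
        raise ValidationError(f"need >= 10 samples to partition, got {n}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError(f"fractions must sum to 1, got {fractions}")
    _check_dups = pd.Index(sample_ids)
    if _check_dups.has_duplicates:
        raise ValidationError("duplicate sample IDs in partition input")
    n1 = int(np.floor(fractions[0] * n + 0.5))
    n2 = int(np.floor(fractions[1] * n + 0.5))
    n3 = n - n1 - n2
    if min(n1, n2, n3) < 1:
        raise ValidationError("every partition set must receive >= 1 sample")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = ["set1"] * n1 + ["set2"] * n2 + ["set3"] * n3
    assignments = {str(sample_ids[i]): labels[k] for k, i in enumerate(order)}
    # keep original sample order in the mapping for readable output
    assignments = {str(s): assignments[str(s)] for s in sample_ids}
    return SamplePartition(assignments, seed)


# ---------------------------------------------------------------------------
# Missing-value imputation (row-wise KNN over probes)
# ---------------------------------------------------------------------------

def impute_missing(beta: BetaMatrix, k: int = 10) -> BetaMatrix:
    """KNN-impute missing beta-values over probe rows.

    For each missing cell (probe p, sample s) the k nearest probe rows by
    Euclidean distance on mutually observed samples — restricted to probes
    observed at sample s — contribute the mean of their beta at s.  Imputed
    values are clipped to [0, 1]; observed entries are never altered.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    X = beta.values.copy()
    miss = np.isnan(X)
    if not miss.any():
        return beta
    all_missing = miss.all(axis=1)
    if all_missing.any():
        bad = [beta.probe_ids[i] for i in np.where(all_missing)[0]]
        raise ValidationError(f"probes missing in all samples: {bad[:5]}")
    obs = ~miss
    target_rows = np.where(miss.any(axis=1))[0]
    for i in target_rows:
        # squared distance to every other probe over mutually observed samples
        shared = obs & obs[i]
        diff = np.where(shared, X - X[i], 0.0)
        d2 = np.einsum("ij,ij->i", diff, diff)
        n_shared = shared.sum(axis=1)
        d2 = np.where(n_shared > 0, d2, np.inf)
        d2[i] = np.inf
        for j in np.where(miss[i])[0]:
            cand = np.where(obs[:, j] & np.isfinite(d2))[0]
            if cand.size == 0:
                raise ValidationError(
                    f"cannot impute probe {beta.probe_ids[i]!r}: no donor probes "
                    f"observed at sample {beta.sample_ids[j]!r}")
            # k nearest donors; ties broken by row order for determinism
            order = cand[np.argsort(d2[cand], kind="stable")][:k]
            X[i, j] = float(np.clip(np.mean(X[order, j]), 0.0, 1.0))
    return BetaMatrix(pd.DataFrame(X, index=beta.probe_ids, columns=beta.sample_ids))


# ---------------------------------------------------------------------------
# Probe QC on detection p-values
# ---------------------------------------------------------------------------

def qc_filter_probes(beta_cohorts: Sequence[BetaMatrix],
                     detection_p: Sequence[pd.DataFrame],
                     p_max: float = 0.05,
                     frac_max: float = 0.05) -> list[str]:
    """Return probes failing detection QC in any cohort.

    A probe is excluded iff, in at least one cohort, the fraction of samples
    with detection p > p_max is >= frac_max (the >= is inclusive).
    """
    if len(beta_cohorts) != len(detection_p):
        raise ValidationError("one detection p-value table per cohort required")
    excluded: set[str] = set()
    for beta, pvals in zip(beta_cohorts, detection_p):
        if list(pvals.index) != beta.probe_ids or list(pvals.columns) != beta.sample_ids:
            raise ValidationError("detection p-values misaligned with beta matrix")
        frac_fail = (pvals.to_numpy() > p_max).mean(axis=1)
        excluded.update(np.asarray(beta.probe_ids)[frac_fail >= frac_max])
    return sorted(excluded)


# ---------------------------------------------------------------------------
# Genome-wide Spearman scan
# ---------------------------------------------------------------------------

def _rank_rows(X: np.ndarray) -> np.ndarray:
    return stats.rankdata(X, axis=1, method="average")


def spearman_matrix(expr: ExpressionMatrix, beta: BetaMatrix,
                    samples: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p for every (gene, probe) pair.

    Returns (rho, p), each genes x probes.  Rho is the Pearson correlation of
    average ranks (exact tie handling); p comes from the large-sample
    t approximation with n-2 degrees of freedom.  Zero-variance rows give
    NaN in both outputs.
    """
    samples = list(samples)
    if len(samples) < 10:
        raise ValidationError(f"need >= 10 samples for correlation, got {len(samples)}")
    E = expr.subset_samples(samples).values
    B = beta.subset_samples(samples).values
    if np.isnan(B).any():
        raise ValidationError("beta matrix has missing values; impute first")
    n = len(samples)
    RE = _rank_rows(E)
    RB = _rank_rows(B)
    RE = RE - RE.mean(axis=1, keepdims=True)
    RB = RB - RB.mean(axis=1, keepdims=True)
    se = np.sqrt(np.einsum("ij,ij->i", RE, RE))
    sb = np.sqrt(np.einsum("ij,ij->i", RB, RB))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (RE @ RB.T) / np.outer(se, sb)
    rho = np.clip(rho, -1.0, 1.0)
    rho[se == 0, :] = np.nan
    rho[:, sb == 0] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = np.nextafter(0.0, 1.0)  # |rho| == 1: p in (0,1] contract
    p[np.isnan(rho)] = np.nan
    return rho, p


def spearman_scan(expr: ExpressionMatrix, beta: BetaMatrix,
                  samples: Iterable[str], set_label: str = "") -> pd.DataFrame:
    """Long-format correlation records: gene_id, probe_id, rho, p, set_label.

    Zero-variance genes/probes yield NaN rho flagged for downstream exclusion.
    """
    samples = list(samples)
    rho, p = spearman_matrix(expr, beta, samples)
    genes = np.repeat(expr.gene_ids, len(beta.probe_ids))
    probes = np.tile(beta.probe_ids, len(expr.gene_ids))
    return pd.DataFrame({
        "gene_id": genes,
        "probe_id": probes,
        "rho": rho.ravel(),
        "p": p.ravel(),
        "set_label": set_label,
    })


# ---------------------------------------------------------------------------
# Selection of top expression-correlated CpGs
# ---------------------------------------------------------------------------

def select_correlated_cpgs(rec1: pd.DataFrame, rec2: pd.DataFrame,
                           alpha: float = 0.01, max_per_sign: int = 100,
                           require_sign_concordance: bool = True,
                           rank_by_abs: bool = True) -> MethCorrMatrix:
    """Select each gene's top expression-correlated CpGs from two discovery sets.

    A (gene, probe) pair qualifies when p < alpha in BOTH sets and (by default)
    the rho signs agree.  Within each gene and sign the pairs are ranked by
    correlation strength (|rho| by default) in each set, ordered by the sum of
    the two ranks, and truncated to max_per_sign.  Rank-sum ties break by
    larger mean |rho|, then lexicographic probe ID, making the output a total
    order independent of input record order.  Genes lacking either sign are
    dropped.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    df = rec1.merge(rec2, on=["gene_id", "probe_id"], suffixes=("_1", "_2"))
    keep = (df["p_1"] < alpha) & (df["p_2"] < alpha)
    keep &= df["rho_1"].notna() & df["rho_2"].notna()
    keep &= (df["rho_1"] != 0) & (df["rho_2"] != 0)
    if require_sign_concordance:
        keep &= np.sign(df["rho_1"]) == np.sign(df["rho_2"])
    df = df[keep].copy()
    if df.empty:
        return MethCorrMatrix({}, max_per_sign=max_per_sign)
    df["sign"] = np.where(df["rho_1"] + df["rho_2"] > 0, "+", "-")
    a1 = df["rho_1"].abs()
    a2 = df["rho_2"].abs()
    key1 = a1 if rank_by_abs else df["rho_1"]
    key2 = a2 if rank_by_abs else df["rho_2"]
    # rank within (gene, sign) per set: 1 = strongest
    df["_k1"] = key1.to_numpy()
    df["_k2"] = key2.to_numpy()
    r1 = df.groupby(["gene_id", "sign"], sort=False)["_k1"].rank(
        ascending=False, method="average")
    r2 = df.groupby(["gene_id", "sign"], sort=False)["_k2"].rank(
        ascending=False, method="average")
    df["rank_sum"] = (r1 + r2).to_numpy()
    df["_mean_abs"] = ((a1 + a2) / 2).to_numpy()
    df = df.sort_values(
        ["gene_id", "sign", "rank_sum", "_mean_abs", "probe_id"],
        ascending=[True, True, True, False, True], kind="stable")
    df = df.groupby(["gene_id", "sign"], sort=False).head(max_per_sign)

    genes: dict[str, GeneProbeSets] = {}
    for gene, sub in df.groupby("gene_id", sort=True):
        signs = set(sub["sign"])
        if signs != {"+", "-"}:
            continue  # MethCORR genes need both signs
        sets = GeneProbeSets(pos=[], neg=[])
        for sign, target in (("+", sets.pos), ("-", sets.neg)):
            for _, r in sub[sub["sign"] == sign].iterrows():
                target.append(ProbeEntry(str(r["probe_id"]),
                                         float(r["rho_1"]), float(r["rho_2"])))
        genes[str(gene)] = sets
    return MethCorrMatrix(genes, max_per_sign=max_per_sign)
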