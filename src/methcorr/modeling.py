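"""Per-gene regression of RNA expression on MethCORR scores.

Each gene's expression is modelled as a polynomial in its MCS,
RNA = B0 + B1*MCS + ... + Bn*MCS^n with n in 1..4.  Degrees are compared by
mean held-out RMSE over 10 repeats of 10-fold cross-validation; a polynomial
replaces the simple linear model only when it improves mean RMSE by >= 5%
(relative).  The selected degree is refit on the full discovery set and a
gene is accepted only when R^2 between predicted and observed expression
exceeds 0.16 in both the discovery and the independent validation set.
R^2 is the squared Pearson correlation between predictions and observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import (
    ExpressionMatrix,
    GeneModelTable,
    MCSMatrix,
    ValidationError,
)
from .discovery import SamplePartition

__all__ = [
    "CvResult",
    "IRnaMatrix",
    "fold_assignments",
    "cv_fit",
    "select_model",
    "fit_polynomial",
    "r_squared",
    "gate_gene",
    "fit_gene_models",
    "infer_expression",
]

_VAR_EPS = 1e-12


@dataclass(frozen=True)
class CvResult:
    """Mean held-out RMSE for one gene and polynomial degree."""

    gene_id: str
    degree: int
    mean_rmse: float
    seed: int


@dataclass
class IRnaMatrix:
    """Inferred RNA expression (accepted genes only), genes x samples."""

    data: pd.DataFrame
    omitted_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValidationError("inferred expression contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# Cross-validation machinery
# ---------------------------------------------------------------------------

def fold_assignments(n: int, folds: int, seed: int, repeat: int) -> np.ndarray:
    """Fold label per observation; depends only on (seed, repeat, n, folds)."""
    rng = np.random.default_rng([abs(int(seed)), int(repeat), int(n), int(folds)])
    return rng.permutation(np.arange(n) % folds)


def _design(m: np.ndarray, degree: int) -> np.ndarray:
    # raw powers: MCS lies in [0,1], so conditioning is acceptable at degree <= 4
    return m[..., None] ** np.arange(degree + 1)


def _batch_ols(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for a batch of small designs via pinv of the
    normal equations.  X: (G, n, p); Y: (G, n) -> (G, p)."""
    XtX = np.einsum("gni,gnj->gij", X, X)
    Xty = np.einsum("gni,gn->gi", X, Y)
    return np.einsum("gij,gj->gi", np.linalg.pinv(XtX), Xty)


def cv_rmse_batch(M: np.ndarray, Y: np.ndarray, degree: int,
                  repeats: int = 10, folds: int = 10, seed: int = 0) -> np.ndarray:
    """Mean held-out RMSE per gene over repeats x folds evaluations.

    M, Y: genes x samples arrays of MCS and observed expression.  Fold
    assignments are shared across genes (one global seed).
    """
    G, n = M.shape
    if n < 2 * folds:
        raise ValidationError(f"too few observations ({n}) for {folds}-fold CV")
    X = _design(M, degree)
    total = np.zeros(G)
    count = 0
    for r in range(repeats):
        lab = fold_assignments(n, folds, seed, r)
        for f in range(folds):
            test = lab == f
            train = ~test
            coef = _batch_ols(X[:, train, :], Y[:, train])
            pred = np.einsum("gni,gi->gn", X[:, test, :], coef)
            total += np.sqrt(((pred - Y[:, test]) ** 2).mean(axis=1))
            count += 1
    return total / count


def cv_fit(mcs: Sequence[float], rna: Sequence[float], degree: int,
           repeats: int = 10, folds: int = 10, seed: int = 0,
           gene_id: str = "") -> CvResult:
    """Cross-validated RMSE for a single gene at a given polynomial degree."""
    m = np.asarray(mcs, dtype=float)
    y = np.asarray(rna, dtype=float)
    if m.shape != y.shape or m.ndim != 1:
        raise ValidationError("mcs and rna must be equal-length vectors")
    if m.size < 30:
        raise ValidationError(f"need >= 30 paired observations, got {m.size}")
    if np.isnan(m).any() or np.isnan(y).any():
        raise ValidationError("missing values not allowed in cv_fit")
    if not 1 <= degree <= 4:
        raise ValidationError("degree must be in 1..4")
    if np.var(m) < _VAR_EPS:
        raise ValidationError(f"constant MCS for gene {gene_id!r}: design is "
                              "rank-deficient, gene rejected")
    rmse = cv_rmse_batch(m[None, :], y[None, :], degree, repeats, folds, seed)[0]
    return CvResult(gene_id, degree, float(rmse), seed)


def select_model(linear: CvResult, polys: Sequence[CvResult]) -> int:
    """Choose the polynomial degree only on a >= 5% relative RMSE improvement."""
    if any(p.gene_id != linear.gene_id for p in polys):
        raise ValidationError("CvResults mix genes")
    if not polys:
        return 1
    best = min(polys, key=lambda c: c.mean_rmse)
    if linear.mean_rmse <= 0:
        return 1
    if (linear.mean_rmse - best.mean_rmse) / linear.mean_rmse >= 0.05:
        return best.degree
    return 1


# ---------------------------------------------------------------------------
# Fitting, gating, inference
# ---------------------------------------------------------------------------

def fit_polynomial(mcs: Sequence[float], rna: Sequence[float],
                   degree: int) -> np.ndarray:
    """OLS coefficients (B0..Bdegree) of expression on MCS powers."""
    m = np.asarray(mcs, dtype=float)
    y = np.asarray(rna, dtype=float)
    if np.var(m) < _VAR_EPS:
        raise ValidationError("constant MCS: rank-deficient design")
    X = _design(m, degree)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def r_squared(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation between predictions and observations.

    NaN when either side has (near-)zero variance.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if np.var(pred) < _VAR_EPS or np.var(obs) < _VAR_EPS:
        return float("nan")
    r = np.corrcoef(pred, obs)[0, 1]
    return float(r * r)


def _polyval(coef: np.ndarray, m: np.ndarray) -> np.ndarray:
    return _design(np.asarray(m, dtype=float), len(coef) - 1) @ coef


def gate_gene(coef: np.ndarray,
              mcs_disc: np.ndarray, rna_disc: np.ndarray,
              mcs_val: np.ndarray, rna_val: np.ndarray,
              r2_min: float = 0.16) -> tuple[bool, float, float]:
    """Accept a gene model only when R^2 > r2_min strictly in BOTH the
    discovery and the validation set.  Returns (accepted, r2_disc, r2_val)."""
    r2_d = r_squared(_polyval(coef, mcs_disc), rna_disc)
    r2_v = r_squared(_polyval(coef, mcs_val), rna_val)
    accepted = bool(np.isfinite(r2_d) and np.isfinite(r2_v)
                    and r2_d > r2_min and r2_v > r2_min)
    return accepted, r2_d, r2_v


def fit_gene_models(mcs: MCSMatrix, expr: ExpressionMatrix,
                    partition: SamplePartition,
                    repeats: int = 10, folds: int = 10, seed: int = 0,
                    degrees: Sequence[int] = (1, 2, 3, 4),
                    rmse_improvement: float = 0.05,
                    r2_min: float = 0.16) -> GeneModelTable:
    """Fit, select, refit, and gate MCS -> expression models for all genes.

    CV model selection runs on the combined discovery samples (set1 + set2);
    the selected degree is refit on the full discovery set and gated on
    discovery and validation (set3) R^2.  Genes with constant MCS or constant
    observed expression are flagged (NaN metrics) and rejected.
    """
    genes = [g for g in mcs.gene_ids if g in set(expr.gene_ids)]
    disc = partition.set("set1") + partition.set("set2")
    val = partition.set("set3")
    M_disc = mcs.data.loc[genes, disc].to_numpy()
    Y_disc = expr.data.loc[genes, disc].to_numpy()
    M_val = mcs.data.loc[genes, val].to_numpy()
    Y_val = expr.data.loc[genes, val].to_numpy()
    G = len(genes)
    ok = (np.var(M_disc, axis=1) >= _VAR_EPS)

    rmse = {}
    for d in degrees:
        r = np.full(G, np.nan)
        if ok.any():
            r[ok] = cv_rmse_batch(M_disc[ok], Y_disc[ok], d, repeats, folds, seed)
        rmse[d] = r
    lin = rmse[degrees[0]]
    poly_degrees = [d for d in degrees if d > 1]
    chosen = np.ones(G, dtype=int)
    if poly_degrees:
        poly_stack = np.vstack([rmse[d] for d in poly_degrees])
        with np.errstate(invalid="ignore"):
            best_idx = np.nanargmin(np.where(np.isnan(poly_stack),
                                             np.inf, poly_stack), axis=0)
            best_rmse = poly_stack[best_idx, np.arange(G)]
            improve = np.where(lin > 0, (lin - best_rmse) / lin, 0.0)
        take_poly = ok & np.isfinite(best_rmse) & (improve >= rmse_improvement)
        chosen[take_poly] = np.asarray(poly_degrees)[best_idx[take_poly]]

    rows = []
    for i, gene in enumerate(genes):
        b = np.full(5, np.nan)
        if ok[i]:
            d = int(chosen[i])
            coef = fit_polynomial(M_disc[i], Y_disc[i], d)
            b[: d + 1] = coef
            accepted, r2_d, r2_v = gate_gene(coef, M_disc[i], Y_disc[i],
                                             M_val[i], Y_val[i], r2_min)
            cv = rmse[d][i]
        else:
            d, accepted, r2_d, r2_v, cv = 1, False, np.nan, np.nan, np.nan
            b[0], b[1] = float(np.mean(Y_disc[i])), 0.0
        rows.append((gene, d, *b, cv, r2_d, r2_v, accepted))
    df = pd.DataFrame(rows, columns=["gene", "degree", "b0", "b1", "b2", "b3",
                                     "b4", "cv_rmse", "r2_discovery",
                                     "r2_validation", "accepted"])
    return GeneModelTable(df)


def infer_expression(models: GeneModelTable, mcs: MCSMatrix,
                     accepted_only: bool = True) -> IRnaMatrix:
    """Evaluate each gene's polynomial at its MCS: iRNA = sum_k Bk * MCS^k.

    Genes present in the model table but absent from the MCS matrix are
    omitted and listed on the result.
    """
    table = models.accepted() if accepted_only else models
    present = set(mcs.gene_ids)
    omitted = tuple(g for g in table.gene_ids if g not in present)
    rows = []
    genes = []
    for _, r in table.data.iterrows():
        gene = r["gene"]
        if gene not in present:
            continue
        d = int(r["degree"])
        coef = r[[f"b{k}" for k in range(d + 1)]].to_numpy(dtype=float)
        rows.append(_polyval(coef, mcs.data.loc[gene].to_numpy()))
        genes.append(gene)
    data = pd.DataFrame(np.vstack(rows) if rows else
                        np.empty((0, len(mcs.sample_ids))),
                        index=genes, columns=mcs.sample_ids)
    return IRnaMatrix(data, omitted_genes=omitted)
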