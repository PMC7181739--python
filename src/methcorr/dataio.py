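"""Typed containers and TSV input/output for every artifact the pipeline touches.

All interchange formats are plain TSV with a mandatory header row, decimal
point only, and missing methylation values encoded as an empty field or "NA".
Matrices are stored with probes/genes as rows and samples as columns, the
convention of Illumina array exports.  Floats are written at 10 significant
digits so that write -> read round-trips are bitwise identical for values
representable at that precision.  Lines starting with ``#`` are treated as
comments (the pipeline stamps its config hash there) and skipped on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethcorrError",
    "ParseError",
    "ValidationError",
    "BetaMatrix",
    "ExpressionMatrix",
    "MCSMatrix",
    "ProbeEntry",
    "GeneProbeSets",
    "MethCorrMatrix",
    "GeneModelTable",
    "SegmentTable",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_mcs_matrix",
    "write_mcs_matrix",
    "read_methcorr_matrix",
    "write_methcorr_matrix",
    "read_gene_models",
    "write_gene_models",
    "read_segments",
    "write_segments",
]

FLOAT_FMT = "%.10g"


class MethcorrError(Exception):
    """Base class for all package errors."""


class ParseError(MethcorrError):
    """A file could not be parsed into the expected shape."""


class ValidationError(MethcorrError):
    """Parsed data violates a domain invariant."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {kind} IDs: {dups[:5]}")


def _read_table(path, delimiter: str = "\t") -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, header=0, index_col=0,
                         comment="#", na_values=["NA"])
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.index.isna().any() or df.columns.isna().any():
        raise ParseError(f"{path}: malformed header or row labels")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    df.columns.name = None
    return df


def _write_table(df: pd.DataFrame, path, index_label: str,
                 comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index_label=index_label,
                  float_format=FLOAT_FMT, na_rep="NA")


# ---------------------------------------------------------------------------
# Matrix containers
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """CpG methylation beta-values, probes x samples, entries in [0, 1].

    Missing values are NaN.  Beta = methylated / (methylated + unmethylated)
    signal at a CpG, so the closed unit interval is a hard contract.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "probe")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy()
        bad = (vals < 0) | (vals > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                "beta value outside [0,1]: "
                f"probe {self.data.index[i]!r}, sample {self.data.columns[j]!r} "
                f"= {vals[i, j]}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples absent from beta matrix: {missing[:5]}")
        return BetaMatrix(self.data[list(samples)])


@dataclass
class ExpressionMatrix:
    """Gene expression, genes x samples, log2(FPKM + 1) scale (finite, >= 0)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative expression: gene {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples absent from expression matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(samples)])


@dataclass
class MCSMatrix:
    """MethCORR scores, genes x samples, entries in [0, 1].

    ``dropped_probe_counts`` and ``omitted_genes`` are populated by tolerant
    scoring when target-platform probes were absent (e.g. 450K-derived probe
    sets applied to EPIC data).
    """

    data: pd.DataFrame
    dropped_probe_counts: dict[str, int] = field(default_factory=dict)
    omitted_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        vals = self.data.to_numpy()
        if ((vals < 0) | (vals > 1)).any() or not np.isfinite(vals).all():
            raise ValidationError("MCS values must lie in [0,1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, samples: Sequence[str]) -> "MCSMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples absent from MCS matrix: {missing[:5]}")
        return MCSMatrix(self.data[list(samples)])


# ---------------------------------------------------------------------------
# MethCORR matrix (per-gene expression-correlated CpG sets)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeEntry:
    """One selected CpG probe with its Spearman rho in each discovery set."""

    probe_id: str
    rho_set1: float
    rho_set2: float


@dataclass
class GeneProbeSets:
    """Ordered positive / negative expression-correlated CpG lists for a gene.

    Order is the rank-sum order from dual-set discovery (strongest first).
    """

    pos: list[ProbeEntry]
    neg: list[ProbeEntry]

    def probe_set(self, sign: str) -> set[str]:
        entries = self.pos if sign == "+" else self.neg
        return {e.probe_id for e in entries}


@dataclass
class MethCorrMatrix:
    """Per gene, the <=100 positively and <=100 negatively expression-correlated
    CpGs with their discovery-set correlations, in rank-sum order."""

    genes: dict[str, GeneProbeSets]
    max_per_sign: int = 100

    def __post_init__(self) -> None:
        for gene, sets in self.genes.items():
            if not sets.pos or not sets.neg:
                raise ValidationError(
                    f"gene {gene!r} lacks probes of one sign; MethCORR genes "
                    "require both positively and negatively correlated CpGs"
                )
            if len(sets.pos) > self.max_per_sign or len(sets.neg) > self.max_per_sign:
                raise ValidationError(
                    f"gene {gene!r} exceeds {self.max_per_sign} probes per sign")
            all_ids = [e.probe_id for e in sets.pos] + [e.probe_id for e in sets.neg]
            if len(all_ids) != len(set(all_ids)):
                raise ValidationError(f"gene {gene!r} has duplicated probes")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def all_probe_ids(self) -> set[str]:
        out: set[str] = set()
        for sets in self.genes.values():
            for e in sets.pos:
                out.add(e.probe_id)
            for e in sets.neg:
                out.add(e.probe_id)
        return out


# ---------------------------------------------------------------------------
# Gene model table
# ---------------------------------------------------------------------------

_MODEL_COLS = ["gene", "degree", "b0", "b1", "b2", "b3", "b4",
               "cv_rmse", "r2_discovery", "r2_validation", "accepted"]


@dataclass
class GeneModelTable:
    """Per-gene MCS -> expression regression models.

    Columns: degree (1-4), coefficients b0..b4 (unused higher-order terms NaN),
    cross-validated RMSE, discovery/validation R^2 and the acceptance flag
    (R^2 > 0.16 in both sets).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _MODEL_COLS if c not in self.data.columns]
        if missing:
            raise ParseError(f"gene model table missing columns: {missing}")
        self.data = self.data[_MODEL_COLS].copy()
        self.data["gene"] = self.data["gene"].astype(str)
        self.data["degree"] = self.data["degree"].astype(int)
        for c in _MODEL_COLS[2:-1]:
            self.data[c] = self.data[c].astype(float)
        self.data["accepted"] = self.data["accepted"].astype(bool)
        _check_unique(self.data["gene"], "gene")
        deg = self.data["degree"].to_numpy()
        if ((deg < 1) | (deg > 4)).any():
            raise ValidationError("model degree must be in 1..4")
        if (self.data["cv_rmse"].to_numpy() < 0).any():
            raise ValidationError("cv_rmse must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data["gene"])

    def accepted(self) -> "GeneModelTable":
        return GeneModelTable(self.data[self.data["accepted"]].reset_index(drop=True))

    def coefficients(self, gene: str) -> np.ndarray:
        row = self.data.set_index("gene").loc[gene]
        d = int(row["degree"])
        return row[[f"b{k}" for k in range(d + 1)]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Copy-number segment table
# ---------------------------------------------------------------------------

_SEG_COLS = ["sample", "chrom", "start", "end", "num.probes", "seg.mean"]


@dataclass
class SegmentTable:
    """Copy-number segments (SEG-like dialect), 1-based inclusive coordinates."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _SEG_COLS if c not in self.data.columns]
        if missing:
            raise ParseError(f"segment table missing columns: {missing}")
        self.data = self.data[_SEG_COLS].copy()
        self.data["start"] = self.data["start"].astype(int)
        self.data["end"] = self.data["end"].astype(int)
        self.data["num.probes"] = self.data["num.probes"].astype(int)
        self.data["seg.mean"] = self.data["seg.mean"].astype(float)
        if (self.data["num.probes"] < 1).to_numpy().any():
            raise ValidationError("num.probes must be >= 1")
        if (self.data["start"] > self.data["end"]).to_numpy().any():
            raise ValidationError("segment start must be <= end")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_beta_matrix(path, delimiter: str = "\t") -> BetaMatrix:
    """Read a probes x samples beta-value TSV (first column probe IDs)."""
    return BetaMatrix(_read_table(path, delimiter))


def write_beta_matrix(beta: BetaMatrix, path, comment: str | None = None) -> None:
    _write_table(beta.data, path, "probe_id", comment)


def read_expression_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    df = _read_table(path, delimiter)
    if df.isna().any().any():
        raise ValidationError("expression matrix contains missing values")
    return ExpressionMatrix(df)


def write_expression_matrix(expr: ExpressionMatrix, path,
                            comment: str | None = None) -> None:
    _write_table(expr.data, path, "gene_id", comment)


def read_mcs_matrix(path, delimiter: str = "\t") -> MCSMatrix:
    df = _read_table(path, delimiter)
    if df.isna().any().any():
        raise ValidationError("MCS matrix contains missing values")
    return MCSMatrix(df)


def write_mcs_matrix(mcs: MCSMatrix, path, comment: str | None = None) -> None:
    _write_table(mcs.data, path, "gene_id", comment)


def write_methcorr_matrix(m: MethCorrMatrix, path, comment: str | None = None) -> None:
    """Serialize to long format: gene, sign, rank, probe_id, rho_set1, rho_set2.

    Rank is 1-based within (gene, sign) and preserves the rank-sum order.
    """
    rows = []
    for gene, sets in m.genes.items():
        for sign, entries in (("+", sets.pos), ("-", sets.neg)):
            for rank, e in enumerate(entries, start=1):
                rows.append((gene, sign, rank, e.probe_id, e.rho_set1, e.rho_set2))
    df = pd.DataFrame(rows, columns=["gene", "sign", "rank", "probe_id",
                                     "rho_set1", "rho_set2"])
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_methcorr_matrix(path, delimiter: str = "\t",
                         max_per_sign: int = 100) -> MethCorrMatrix:
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#")
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    need = ["gene", "sign", "rank", "probe_id", "rho_set1", "rho_set2"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"MethCORR matrix file missing columns: {missing}")
    genes: dict[str, GeneProbeSets] = {}
    for gene, sub in df.groupby("gene", sort=False):
        sets = GeneProbeSets(pos=[], neg=[])
        for sign, target in (("+", sets.pos), ("-", sets.neg)):
            block = sub[sub["sign"] == sign].sort_values("rank")
            for _, r in block.iterrows():
                target.append(ProbeEntry(str(r["probe_id"]),
                                         float(r["rho_set1"]), float(r["rho_set2"])))
        genes[str(gene)] = sets
    return MethCorrMatrix(genes, max_per_sign=max_per_sign)


def write_gene_models(models: GeneModelTable, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        models.data.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT,
                           na_rep="NA")


def read_gene_models(path, delimiter: str = "\t") -> GeneModelTable:
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#", na_values=["NA"])
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if "accepted" in df.columns:
        df["accepted"] = df["accepted"].astype(bool)
    return GeneModelTable(df)


def read_segments(path, delimiter: str = "\t") -> SegmentTable:
    """Read a SEG-like table with columns sample, chrom, start, end,
    num.probes, seg.mean (champ.CNA-style output)."""
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#")
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    return SegmentTable(df)


def write_segments(segs: SegmentTable, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        segs.data.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)
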