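"""Auxiliary sample/gene scores and methylation-PCR classification rules.

Covers chromosomal-instability (CIN) scores from GISTIC-style gene-level
copy numbers or from copy-number segments, the 40th-percentile sample
methylation score, and the QMSP delta-CT decision rules for CRC1/CRC2
subtyping and relapse-risk stratification.

The QMSP assays use primers specific for UNmethylated template against an
AluC4A reference, so a low delta-CT means abundant unmethylated template
(low methylation) and a high delta-CT means high methylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import SegmentTable, ValidationError

__all__ = [
    "QmspSample",
    "gene_cin_scores",
    "sample_cin_score_gistic",
    "sample_cin_score_segments",
    "sample_methylation_score",
    "qmsp_subtype",
    "stratify_risk",
    "RISK_CUTOFFS",
]

#: Published delta-CT risk cutoffs (cycles) for the three biomarker assays.
RISK_CUTOFFS: dict[str, float] = {"cd3e": 19.5, "acta2": 15.55, "pdpn": 13.5}


@dataclass(frozen=True)
class QmspSample:
    """Delta-CT values (cycles vs. the AluC4A reference) for one sample.

    Any assay may be missing (None); rules that need it return "unclassified".
    """

    sample_id: str
    dct_hnf4a: float | None = None
    dct_cd3e: float | None = None
    dct_acta2: float | None = None
    dct_pdpn: float | None = None


# ---------------------------------------------------------------------------
# CIN scores
# ---------------------------------------------------------------------------

def gene_cin_scores(cn: pd.DataFrame) -> pd.Series:
    """Per-gene CIN score: sample sd (ddof=1) of copy numbers across samples."""
    if cn.shape[1] < 3:
        raise ValidationError("need >= 3 samples for gene CIN scores")
    if not np.isfinite(cn.to_numpy()).all():
        raise ValidationError("copy-number matrix must be finite")
    return cn.std(axis=1, ddof=1)


def sample_cin_score_gistic(cn: pd.DataFrame) -> pd.Series:
    """Per-sample CIN score: sd (ddof=1) of copy numbers across genes."""
    if cn.shape[0] < 3:
        raise ValidationError("need >= 3 genes for sample CIN scores")
    if not np.isfinite(cn.to_numpy()).all():
        raise ValidationError("copy-number matrix must be finite")
    return cn.std(axis=0, ddof=1)


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])  # linear interpolation
    return float(q75 - q25)


def sample_cin_score_segments(segs: SegmentTable, min_probes: int = 25,
                              min_segments: int = 4,
                              per_chromosome: bool = True) -> pd.Series:
    """Segment-based per-sample CIN score from methylation-array copy numbers.

    Segments covered by fewer than ``min_probes`` array probes are discarded.
    In the default per-chromosome mode the score is the mean, over
    chromosomes with >= ``min_segments`` qualifying segments, of the IQR of
    their seg.mean values (linear interpolation between order statistics).
    With ``per_chromosome=False`` a single IQR over all qualifying segments
    is used instead.  Samples with no qualifying chromosome get NaN.
    """
    df = segs.data[segs.data["num.probes"] >= min_probes]
    out: dict[str, float] = {}
    for sample, sub in df.groupby("sample", sort=True):
        if per_chromosome:
            iqrs = [
                _iqr(chrom_sub["seg.mean"].to_numpy())
                for _, chrom_sub in sub.groupby("chrom", sort=True)
                if len(chrom_sub) >= min_segments
            ]
            out[str(sample)] = float(np.mean(iqrs)) if iqrs else np.nan
        else:
            vals = sub["seg.mean"].to_numpy()
            out[str(sample)] = _iqr(vals) if len(vals) >= min_segments else np.nan
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# Sample methylation score
# ---------------------------------------------------------------------------

def sample_methylation_score(beta_sample: Sequence[float],
                             min_probes: int = 10) -> float:
    """40th percentile of a sample's beta-values over the shared CpG set
    (linear interpolation between order statistics)."""
    x = np.asarray(beta_sample, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < min_probes:
        raise ValidationError(f"need >= {min_probes} probes, got {x.size}")
    return float(np.percentile(x, 40))


# ---------------------------------------------------------------------------
# QMSP classification rules
# ---------------------------------------------------------------------------

def qmsp_subtype(q: QmspSample, ratio_cutoff: float = 0.85) -> str:
    """CRC1/CRC2 subtype from the HNF4A / mean(CD3E, ACTA2) delta-CT ratio.

    HNF4A marks CRC2 (its promoter is less methylated there); CD3E and ACTA2
    mark stromal/immune infiltration (CRC1).  A ratio strictly below the
    cutoff calls CRC2, otherwise CRC1.  Missing or non-positive delta-CT
    values give "unclassified".
    """
    vals = (q.dct_hnf4a, q.dct_cd3e, q.dct_acta2)
    if any(v is None or not np.isfinite(v) or v <= 0 for v in vals):
        return "unclassified"
    ratio = q.dct_hnf4a / ((q.dct_cd3e + q.dct_acta2) / 2.0)
    return "CRC2" if ratio < ratio_cutoff else "CRC1"


def stratify_risk(subtype: str, q: QmspSample,
                  cutoffs: Mapping[str, float] = RISK_CUTOFFS) -> str:
    """Subtype-specific relapse-risk group from QMSP delta-CT values.

    CRC1: high risk iff dCT_CD3E >= cutoff (high CD3E promoter methylation,
    i.e. T-cell depletion).  CRC2: high risk iff dCT_ACTA2 or dCT_PDPN falls
    strictly below its cutoff (low methylation, i.e. high CAF / EMT content).
    Missing required values give "unclassified".
    """
    if subtype == "CRC1":
        v = q.dct_cd3e
        if v is None or not np.isfinite(v):
            return "unclassified"
        return "high" if v >= cutoffs["cd3e"] else "low"
    if subtype == "CRC2":
        a, p = q.dct_acta2, q.dct_pdpn
        if a is None or p is None or not np.isfinite(a) or not np.isfinite(p):
            return "unclassified"
        return "high" if (a < cutoffs["acta2"] or p < cutoffs["pdpn"]) else "low"
    return "unclassified"
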