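"""The MethCORR map: a gene graph built from overlap of negatively
expression-correlated CpG sets, plus the overlay scores used to interpret it.

Edges connect genes whose negative CpG sets are similar under the combined
Jaccard + Overlap coefficient

    sim(A, B) = k * |A∩B|/min(|A|,|B|) + (1-k) * |A∩B|/|A∪B|,   k = 0.5

kept when sim >= cutoff (default 0.126, inclusive).  Only the negative sets
enter the similarity: genes whose expression responds in opposite directions
to the same methylation would otherwise cluster together.  Overlays:
per-gene MCS z-scores within a cohort, differences of median z-scores
between groups, correlation-to-median-MCS scores (cMCS) for gene sets,
their differences (delta-cMCS), and percent change of median MCS.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .dataio import MCSMatrix, MethCorrMatrix, ValidationError

__all__ = [
    "combined_similarity",
    "build_map",
    "write_edge_list",
    "write_graphml",
    "mcs_zscores",
    "delta_median_zscore",
    "cmcs",
    "delta_cmcs",
    "pct_change_median_mcs",
]


def combined_similarity(setA: Iterable[str], setB: Iterable[str],
                        k: float = 0.5) -> float:
    """Combined Jaccard + Overlap similarity of two probe sets, in [0, 1]."""
    A, B = set(setA), set(setB)
    if not A or not B:
        raise ValidationError("probe sets must be non-empty")
    inter = len(A & B)
    overlap = inter / min(len(A), len(B))
    jaccard = inter / len(A | B)
    return k * overlap + (1.0 - k) * jaccard


def build_map(m: MethCorrMatrix, cutoff: float = 0.126,
              k: float = 0.5) -> nx.Graph:
    """Build the MethCORR map from the negatively correlated CpG sets.

    Nodes are all genes of the matrix; an undirected edge (i, j) with
    attribute ``similarity`` is added iff the combined similarity of the two
    negative sets is >= cutoff (inclusive).  Isolated genes stay in the graph,
    marked with ``isolated=True`` (the published layout hides them only for
    visual simplicity).
    """
    genes = m.gene_ids
    neg_sets = [m.genes[g].probe_set("-") for g in genes]
    probe_ids = sorted(set().union(*neg_sets)) if neg_sets else []
    pidx = {p: i for i, p in enumerate(probe_ids)}
    rows, cols = [], []
    for gi, s in enumerate(neg_sets):
        for p in s:
            rows.append(gi)
            cols.append(pidx[p])
    M = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)),
                          shape=(len(genes), len(probe_ids)))
    inter = (M @ M.T).toarray()
    sizes = np.asarray([len(s) for s in neg_sets], dtype=float)
    mins = np.minimum.outer(sizes, sizes)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = k * inter / mins + (1.0 - k) * inter / union
    g = nx.Graph(cutoff=float(cutoff))
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = sim[iu, ju] >= cutoff
    for a, b, s in zip(iu[keep], ju[keep], sim[iu, ju][keep]):
        g.add_edge(genes[a], genes[b], similarity=float(s))
    for node in g.nodes:
        g.nodes[node]["isolated"] = g.degree(node) == 0
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    rows = sorted((min(a, b), max(a, b), d["similarity"])
                  for a, b, d in g.edges(data=True))
    pd.DataFrame(rows, columns=["gene_i", "gene_j", "similarity"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Overlay scores
# ---------------------------------------------------------------------------

def mcs_zscores(mcs: MCSMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scores of MCS within the cohort: (MCS - mean) / sd (ddof=1).

    Returns (z, flagged) where flagged lists zero-variance genes whose
    z-scores are undefined (NaN rows).
    """
    if len(mcs.sample_ids) < 3:
        raise ValidationError("need >= 3 samples for z-scores")
    vals = mcs.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - mean) / sd
    flagged = [g for g, s in zip(mcs.gene_ids, sd[:, 0]) if s == 0]
    z[sd[:, 0] == 0, :] = np.nan
    return pd.DataFrame(z, index=mcs.gene_ids, columns=mcs.sample_ids), flagged


def _check_groups(columns, groupA, groupB, disjoint: bool = True):
    groupA, groupB = list(groupA), list(groupB)
    if not groupA or not groupB:
        raise ValidationError("both groups must be non-empty")
    if disjoint and set(groupA) & set(groupB):
        raise ValidationError("groups must be disjoint")
    missing = [s for s in groupA + groupB if s not in columns]
    if missing:
        raise ValidationError(f"samples not in matrix: {missing[:5]}")
    return groupA, groupB


def delta_median_zscore(z: pd.DataFrame, groupA: Sequence[str],
                        groupB: Sequence[str]) -> pd.Series:
    """Per-gene median z in group A minus median z in group B."""
    groupA, groupB = _check_groups(z.columns, groupA, groupB)
    return z[groupA].median(axis=1) - z[groupB].median(axis=1)


def cmcs(mcs_by_cohort: Sequence[MCSMatrix],
         gene_set: Sequence[str]) -> pd.Series:
    """Correlation to median MCS, averaged over cohorts.

    Within each cohort the reference profile is the per-sample median MCS over
    ``gene_set``; a gene's cMCS is the Pearson correlation of its MCS with the
    reference, then averaged over cohorts.  Cohorts where a gene (or the
    reference) is constant are omitted from that gene's average.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValidationError("gene_set must be non-empty")
    if not mcs_by_cohort:
        raise ValidationError("at least one cohort required")
    common = set(mcs_by_cohort[0].gene_ids)
    for m in mcs_by_cohort[1:]:
        common &= set(m.gene_ids)
    genes = [g for g in mcs_by_cohort[0].gene_ids if g in common]
    sums = pd.Series(0.0, index=genes)
    counts = pd.Series(0, index=genes)
    for m in mcs_by_cohort:
        if len(m.sample_ids) < 3:
            raise ValidationError("cohorts need >= 3 samples for cMCS")
        missing = [g for g in gene_set if g not in set(m.gene_ids)]
        if missing:
            raise ValidationError(f"gene_set genes absent from a cohort: {missing[:5]}")
        ref = m.data.loc[gene_set].median(axis=0).to_numpy()
        X = m.data.loc[genes].to_numpy()
        ref_c = ref - ref.mean()
        ref_ss = np.sqrt((ref_c ** 2).sum())
        Xc = X - X.mean(axis=1, keepdims=True)
        xss = np.sqrt((Xc ** 2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc @ ref_c) / (xss * ref_ss)
        valid = np.isfinite(r)
        sums[valid] += r[valid]
        counts[valid] += 1
    with np.errstate(invalid="ignore"):
        out = sums / counts.replace(0, np.nan)
    return out


def delta_cmcs(mcs_by_cohort: Sequence[MCSMatrix], up_set: Sequence[str],
               down_set: Sequence[str]) -> pd.Series:
    """cMCS of the upregulated set minus cMCS of the downregulated set."""
    if not list(up_set) or not list(down_set):
        raise ValidationError("both gene sets must be non-empty")
    return cmcs(mcs_by_cohort, up_set) - cmcs(mcs_by_cohort, down_set)


def pct_change_median_mcs(mcs: MCSMatrix, groupA: Sequence[str],
                          groupB: Sequence[str]) -> pd.Series:
    """Percent change of per-gene median MCS from group A to group B:
    100 * (median_B - median_A) / median_A.  NaN where the baseline is 0."""
    groupA, groupB = _check_groups(mcs.sample_ids, groupA, groupB,
                                   disjoint=False)
    medA = mcs.data[groupA].median(axis=1)
    medB = mcs.data[groupB].median(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (medB - medA) / medA
    out[medA == 0] = np.nan
    return out
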