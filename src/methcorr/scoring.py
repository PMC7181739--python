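"""MethCORR score (MCS) computation.

For each gene the MCS is the mean "expression-supporting" methylation of its
selected CpGs:

    MCS = (1/N) * ( sum(beta over positively correlated CpGs)
                  + sum(1 - beta over negatively correlated CpGs) )

with N the total number of CpGs used.  Because beta lies in [0,1], so does
the MCS, and it rises when positively correlated sites gain methylation or
negatively correlated sites lose it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataio import BetaMatrix, MCSMatrix, MethCorrMatrix, ValidationError

__all__ = ["compute_mcs"]


def compute_mcs(beta: BetaMatrix, m: MethCorrMatrix,
                strict: bool = True) -> MCSMatrix:
    """Compute the genes x samples MCS matrix.

    In strict mode every probe of ``m`` must be present in ``beta`` (after
    imputation).  In tolerant mode absent probes are dropped with N reduced
    accordingly — needed when scoring e.g. EPIC cohorts with a 450K-derived
    probe matrix — and per-gene dropped-probe counts are reported on the
    result; genes left without at least one probe of each sign are omitted
    and listed in ``omitted_genes``.
    """
    if beta.has_missing():
        raise ValidationError("beta matrix has missing values; impute first")
    probe_index = {p: i for i, p in enumerate(beta.probe_ids)}
    missing_all = sorted(m.all_probe_ids() - probe_index.keys())
    if missing_all and strict:
        raise ValidationError(
            f"{len(missing_all)} matrix probes absent from beta matrix "
            f"(e.g. {missing_all[:5]}); use strict=False to drop them")

    B = beta.values
    n_samples = B.shape[1]
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    dropped: dict[str, int] = {}
    omitted: list[str] = []
    for gene, sets in m.genes.items():
        pos = [probe_index[e.probe_id] for e in sets.pos if e.probe_id in probe_index]
        neg = [probe_index[e.probe_id] for e in sets.neg if e.probe_id in probe_index]
        n_drop = (len(sets.pos) - len(pos)) + (len(sets.neg) - len(neg))
        if n_drop:
            dropped[gene] = n_drop
        if not pos or not neg:
            omitted.append(gene)
            continue
        total = B[pos].sum(axis=0) + (1.0 - B[neg]).sum(axis=0)
        rows.append(total / (len(pos) + len(neg)))
        gene_ids.append(gene)
    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_samples)),
        index=gene_ids, columns=beta.sample_ids)
    return MCSMatrix(data, dropped_probe_counts=dropped,
                     omitted_genes=tuple(omitted))
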