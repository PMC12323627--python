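"""Per-gene and per-pathway between-condition contrasts with FDR control.

Each gene (or pathway, after summing member-gene expression per sample) is
tested between cTPut-positive and cTPut-negative samples; p-values are
adjusted by the Benjamini-Hochberg step-up procedure and log2 fold changes
computed on pseudocounted means.  The default test is Mann-Whitney (count
data are rarely normal); Welch's t is available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, NormalizedMatrix, PathwayCatalog, SampleTable
from .ordination import mann_whitney_z

logger = logging.getLogger(__name__)

__all__ = ["bh_fdr", "per_gene_contrast", "pathway_aggregate"]


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j >= i}( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-D")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def per_gene_contrast(
    m: ExpressionMatrix,
    samples: SampleTable,
    test: str = "mann_whitney",
    pseudocount: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One row per gene: statistic, p, BH q, log2FC (positive vs negative).

    log2FC = log2((mean_pos + pc) / (mean_neg + pc)).  Genes that are
    all-zero in both conditions are excluded (logged).  Metadata records
    the test used.
    """
    if test not in ("mann_whitney", "t"):
        raise ValueError("test must be 'mann_whitney' or 't'")
    pos = [s for s in samples.ids_by_status(True) if s in m.sample_ids]
    neg = [s for s in samples.ids_by_status(False) if s in m.sample_ids]
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("both conditions need >= 3 samples")
    A = m.data.loc[:, pos].to_numpy(dtype=float)
    B = m.data.loc[:, neg].to_numpy(dtype=float)

    nonzero = (A.sum(axis=1) + B.sum(axis=1)) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("per_gene_contrast: excluded %d all-zero gene(s)", n_dropped)
    genes = [g for g, keep in zip(m.gene_ids, nonzero) if keep]
    A, B = A[nonzero], B[nonzero]

    stat = np.empty(len(genes))
    pval = np.empty(len(genes))
    for i in range(len(genes)):
        a, b = A[i], B[i]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat[i], pval[i] = 0.0, 1.0  # identical constants: no evidence
            continue
        if test == "mann_whitney":
            _, z, p = mann_whitney_z(a, b)
            stat[i], pval[i] = z, p
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            stat[i], pval[i] = t, p
    q = bh_fdr(pval)
    log2fc = np.log2((A.mean(axis=1) + pseudocount) / (B.mean(axis=1) + pseudocount))
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "statistic": stat,
            "p": pval,
            "q": q,
            "log2FC": log2fc,
            "significant": q < q_threshold,
        }
    )
    out.attrs["test"] = test
    out.attrs["pseudocount"] = pseudocount
    out.attrs["q_threshold"] = q_threshold
    return out


def pathway_aggregate(
    m: ExpressionMatrix,
    samples: SampleTable,
    catalog: PathwayCatalog,
    test: str = "mann_whitney",
    pseudocount: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pathway-level contrasts: sum member-gene expression per sample first.

    BH adjustment is across pathways.  Pathways with no member genes
    present in the matrix are skipped.
    """
    gene_set = set(m.gene_ids)
    rows = {}
    for pid in catalog.pathway_ids:
        members = sorted(catalog.members(pid) & gene_set)
        if not members:
            logger.warning("pathway %s has no genes in the matrix; skipped", pid)
            continue
        rows[pid] = m.data.loc[members].sum(axis=0)
    if not rows:
        raise ValueError("no pathway has member genes in the matrix")
    agg = pd.DataFrame(rows).T
    if isinstance(m, NormalizedMatrix):
        agg_m = NormalizedMatrix(m.compartment, agg, method=m.method)
    else:
        agg_m = ExpressionMatrix(m.compartment, agg)
    out = per_gene_contrast(
        agg_m, samples, test=test, pseudocount=pseudocount, q_threshold=q_threshold
    )
    out = out.rename(columns={"gene_id": "pathway_id"})
    out.attrs["level"] = "pathway"
    return out
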