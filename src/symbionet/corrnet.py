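"""Permutation-based Spearman correlation networks and hub-gene scoring.

Edges between two expression compartments are called by Spearman rank
correlation with a permutation p-value: p = (1 + #{|rho*| >= |rho|}) /
(1 + n_perm) for Monte Carlo permutations, or the exact proportion over
all n! rank permutations when the sample count is small (n <= 7).

Per-gene network scores follow the hub-table conventions of the
motivating study:

* ``N`` — number of distinct partner genes;
* ``S_type`` — signed sum (+1 positive / -1 negative) over counted edges;
* ``S_strength`` — summed edge strength.

In ``pathway_instance`` mode a gene that belongs to k pathways contributes
k counted edge instances per correlation (the convention behind network
views that draw one node per pathway membership), so S_strength is the
instance count; in ``abs_rho`` mode counted edges are distinct partners
and S_strength is the sum of |rho|.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .io import (
    EDGE_COLUMNS,
    ExpressionMatrix,
    PathwayCatalog,
    validate_edges,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CorrConfig",
    "spearman_perm",
    "spearman_perm_batch",
    "correlation_matrix",
    "gene_stats",
    "filter_hubs",
    "edge_count_table",
    "compare_edge_counts",
    "PairedTResult",
    "correlation_heatmap_matrix",
]

EXACT_N_MAX = 7  # n! <= 5040: enumerate instead of sampling


@dataclass
class CorrConfig:
    """Edge-calling parameters.

    Defaults mirror the full-network analysis (all edges with permutation
    p < 0.05); the hub analysis uses ``rho_min=0.75`` and
    ``min_strength=100`` with the |rho| window closed on both ends.
    """

    n_perm: int = 9999
    alpha: float = 0.05
    rho_min: float = 0.0
    rho_max: float = 1.0
    seed: int | None = None
    strength_mode: str = "pathway_instance"
    min_strength: float = 100.0
    bh_correct: bool = False  # optional extension; the study filters on raw p

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho_min <= self.rho_max <= 1.0):
            raise ValueError("require 0 <= rho_min <= rho_max <= 1")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.strength_mode not in ("pathway_instance", "abs_rho"):
            raise ValueError("strength_mode must be 'pathway_instance' or 'abs_rho'")


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis."""
    return stats.rankdata(x, axis=-1)


def _standardize_rows(r: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm; constant rows become NaN."""
    c = r - r.mean(axis=-1, keepdims=True)
    norm = np.sqrt((c**2).sum(axis=-1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        return c / norm


def spearman_perm(
    x, y, n_perm: int = 999, seed: int | None = None
) -> tuple[float, float]:
    """Spearman rho and its permutation p-value for two vectors.

    Exact enumeration over all n! permutations for n <= 7; Monte Carlo with
    the (1 + count)/(1 + n_perm) estimator otherwise.  Two-sided.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman rho is undefined")
    rx = _standardize_rows(_rank_rows(x))
    ry = _standardize_rows(_rank_rows(y))
    rho = float(rx @ ry)
    tol = 1e-12
    if n <= EXACT_N_MAX:
        perms = np.array(list(iter_permutations(range(n))))
        rho_star = (rx[perms] @ ry).ravel()
        p = float(np.mean(np.abs(rho_star) >= abs(rho) - tol))
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            rho_star = float(rx[rng.permutation(n)] @ ry)
            if abs(rho_star) >= abs(rho) - tol:
                count += 1
        p = (1 + count) / (1 + n_perm)
    return rho, p


def spearman_perm_batch(
    X: np.ndarray, Y: np.ndarray, n_perm: int = 999, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Row-paired Spearman rho and permutation p for many pairs at once.

    ``X`` and ``Y`` are (pairs x n) arrays; pair i is tested against its own
    row.  All pairs share one stream of sample permutations, which keeps the
    per-pair test valid while making large calibration runs cheap.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("X and Y must have the same shape")
    n = X.shape[1]
    if n < 4:
        raise ValueError("need at least 4 observations")
    rx = _standardize_rows(_rank_rows(X))
    ry = _standardize_rows(_rank_rows(Y))
    rho = (rx * ry).sum(axis=1)
    tol = 1e-12
    rng = np.random.default_rng(seed)
    count = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rho_star = (rx * ry[:, perm]).sum(axis=1)
        count += np.abs(rho_star) >= np.abs(rho) - tol
    p = (1 + count) / (1 + n_perm)
    return rho, p


def correlation_matrix(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    cfg: CorrConfig | None = None,
    sample_subset: list[str] | None = None,
    return_full: bool = False,
):
    """Test all cross-compartment gene pairs; return the significant edges.

    Samples are intersected (or restricted to ``sample_subset``) and
    identically ordered.  Zero-variance genes are skipped with a warning.
    Edges are retained where p_perm < alpha and rho_min <= |rho| <= rho_max.

    With ``return_full=True`` also returns the full (rho, p) matrices as
    DataFrames (genes of ``a`` x genes of ``b``) for heatmap export.
    """
    cfg = cfg or CorrConfig()
    shared = [s for s in a.sample_ids if s in set(b.sample_ids)]
    if sample_subset is not None:
        shared = [s for s in sample_subset if s in set(shared)]
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared samples, found {len(shared)}")
    A = a.subset_samples(shared).counts
    B = b.subset_samples(shared).counts
    n = len(shared)

    def _keep(M: np.ndarray, m: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
        var = M.var(axis=1)
        keep = var > 0
        dropped = [g for g, k in zip(m.gene_ids, keep) if not k]
        if dropped:
            logger.warning(
                "%s: skipped %d zero-variance gene(s), e.g. %s",
                m.compartment, len(dropped), dropped[:3],
            )
        return M[keep], [g for g, k in zip(m.gene_ids, keep) if k]

    A, genes_a = _keep(A, a)
    B, genes_b = _keep(B, b)

    ra = _standardize_rows(_rank_rows(A))
    rb = _standardize_rows(_rank_rows(B))
    rho = ra @ rb.T
    tol = 1e-12
    abs_rho = np.abs(rho)
    if math.factorial(n) <= max(cfg.n_perm, 5040) and n <= EXACT_N_MAX:
        perms = np.array(list(iter_permutations(range(n))))
        count = np.zeros(rho.shape, dtype=np.int64)
        for perm in perms:
            count += np.abs(ra @ rb[:, perm].T) >= abs_rho - tol
        p = count / len(perms)
        exact = True
    else:
        rng = np.random.default_rng(cfg.seed)
        count = np.zeros(rho.shape, dtype=np.int64)
        for _ in range(cfg.n_perm):
            perm = rng.permutation(n)
            count += np.abs(ra @ rb[:, perm].T) >= abs_rho - tol
        p = (1 + count) / (1 + cfg.n_perm)
        exact = False

    keep = (p < cfg.alpha) & (abs_rho >= cfg.rho_min - tol) & (abs_rho <= cfg.rho_max + tol)
    ii, jj = np.nonzero(keep)
    edges = pd.DataFrame(
        {
            "source_gene": [genes_a[i] for i in ii],
            "source_compartment": a.compartment,
            "target_gene": [genes_b[j] for j in jj],
            "target_compartment": b.compartment,
            "rho": rho[ii, jj],
            "p_perm": p[ii, jj],
            "sign": np.where(rho[ii, jj] > 0, 1, -1),
            "pathway_context": None,
        },
        columns=EDGE_COLUMNS,
    )
    edges.attrs["n_samples"] = n
    edges.attrs["n_perm"] = cfg.n_perm if not exact else math.factorial(n)
    edges.attrs["exact"] = exact
    edges.attrs["seed"] = cfg.seed
    validate_edges(edges)
    if return_full:
        rho_df = pd.DataFrame(rho, index=genes_a, columns=genes_b)
        p_df = pd.DataFrame(p, index=genes_a, columns=genes_b)
        return edges, rho_df, p_df
    return edges


# ---------------------------------------------------------------------------
# per-gene network statistics


def gene_stats(
    edges: pd.DataFrame,
    catalog: PathwayCatalog | None = None,
    mode: str = "pathway_instance",
    focal: str = "source",
) -> pd.DataFrame:
    """Per-gene N / S_type / S_strength for the focal edge side.

    ``focal`` selects which endpoint the statistics describe ("source" or
    "target").  In ``pathway_instance`` mode each edge is expanded into one
    counted instance per pathway membership of the catalog-covered
    endpoint (partner first, focal gene otherwise); genes covered by no
    pathway count once, with a warning.
    """
    validate_edges(edges)
    if mode not in ("pathway_instance", "abs_rho"):
        raise ValueError("mode must be 'pathway_instance' or 'abs_rho'")
    if mode == "pathway_instance" and catalog is None:
        raise ValueError("pathway_instance mode requires a PathwayCatalog")
    if focal not in ("source", "target"):
        raise ValueError("focal must be 'source' or 'target'")
    focal_col = f"{focal}_gene"
    partner_col = "target_gene" if focal == "source" else "source_gene"

    mult_cache: dict[str, int] = {}
    if catalog is not None:
        for members in catalog.sets.values():
            for g in members:
                mult_cache[g] = mult_cache.get(g, 0) + 1

    rows = []
    n_uncovered = 0
    for gene, sub in edges.groupby(focal_col, sort=True):
        partners = sub[partner_col]
        n_distinct = partners.nunique()
        if mode == "abs_rho":
            s_type = int(sub["sign"].sum())
            s_strength = float(np.abs(sub["rho"]).sum())
        else:
            mult_focal = mult_cache.get(gene, 0)
            mult = partners.map(lambda g: mult_cache.get(g, 0) or mult_focal or 1)
            n_uncovered += int(((mult == 1) & (mult_focal == 0)
                                & ~partners.isin(mult_cache)).sum())
            s_type = int((sub["sign"].to_numpy() * mult.to_numpy()).sum())
            s_strength = float(mult.sum())
        rows.append(
            {"gene_id": gene, "N": int(n_distinct), "S_type": s_type,
             "S_strength": s_strength}
        )
    if n_uncovered:
        logger.warning(
            "gene_stats: %d edge(s) with neither endpoint in the catalog; counted once",
            n_uncovered,
        )
    out = pd.DataFrame(rows, columns=["gene_id", "N", "S_type", "S_strength"])
    out.attrs["mode"] = mode
    out.attrs["focal"] = focal
    return out


def filter_hubs(stats_table: pd.DataFrame, cfg: CorrConfig | None = None) -> pd.DataFrame:
    """Retain genes whose total strength strictly exceeds ``min_strength``."""
    cfg = cfg or CorrConfig(rho_min=0.75, min_strength=100.0)
    return stats_table.loc[stats_table["S_strength"] > cfg.min_strength].reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# between-condition comparison of per-gene correlation counts


@dataclass
class PairedTResult:
    t: float
    p: float
    mean_a: float
    mean_b: float
    n_pairs: int
    degenerate: bool = False  # zero-variance nonzero differences


def edge_count_table(edges: pd.DataFrame, focal: str = "source") -> pd.DataFrame:
    """Per-focal-gene counts of positive and negative correlations."""
    validate_edges(edges)
    focal_col = f"{focal}_gene"
    if len(edges) == 0:
        return pd.DataFrame(columns=["n_pos", "n_neg"])
    pos = edges.loc[edges["sign"] > 0].groupby(focal_col).size()
    neg = edges.loc[edges["sign"] < 0].groupby(focal_col).size()
    out = pd.DataFrame({"n_pos": pos, "n_neg": neg}).fillna(0).astype(int)
    out.index.name = "gene_id"
    return out


def _paired_t(a: np.ndarray, b: np.ndarray) -> PairedTResult:
    d = a - b
    k = len(d)
    if k < 2:
        raise ValueError("need >= 2 paired genes")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedTResult(0.0, 1.0, float(a.mean()), float(b.mean()), k)
        t = math.inf if d[0] > 0 else -math.inf
        return PairedTResult(t, 0.0, float(a.mean()), float(b.mean()), k, degenerate=True)
    t = float(d.mean() / (sd / math.sqrt(k)))
    p = float(2 * stats.t.sf(abs(t), df=k - 1))
    return PairedTResult(t, p, float(a.mean()), float(b.mean()), k)


def compare_edge_counts(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame
) -> dict[str, PairedTResult]:
    """Paired t-tests of per-gene correlation counts between two conditions.

    ``counts_a``/``counts_b`` are edge_count_table outputs indexed by gene;
    genes missing from one condition are excluded (count logged).  Returns
    results separately for positive and negative correlation counts.
    """
    common = counts_a.index.intersection(counts_b.index)
    dropped = len(counts_a.index.union(counts_b.index)) - len(common)
    if dropped:
        logger.info("compare_edge_counts: excluded %d unpaired gene(s)", dropped)
    if len(common) < 2:
        raise ValueError("fewer than 2 genes present in both conditions")
    out = {}
    for key, col in (("positive", "n_pos"), ("negative", "n_neg")):
        a = counts_a.loc[common, col].to_numpy(dtype=float)
        b = counts_b.loc[common, col].to_numpy(dtype=float)
        out[key] = _paired_t(a, b)
    return out


# ---------------------------------------------------------------------------
# heatmap ordering


def correlation_heatmap_matrix(
    rho: pd.DataFrame, method: str = "ward"
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Order a correlation matrix by Ward hierarchical clustering.

    Rows and columns are clustered separately on the Euclidean distance of
    their rho profiles; values are unchanged, only the ordering is
    returned (reordered matrix, row order, column order).
    """
    values = rho.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("rho matrix contains NaN entries")

    def _order(profiles: np.ndarray) -> np.ndarray:
        if profiles.shape[0] < 3:
            return np.arange(profiles.shape[0])
        z = linkage(profiles, method=method)
        return np.asarray(leaves_list(z))

    row_order = _order(values)
    col_order = _order(values.T)
    ordered = rho.iloc[row_order, col_order]
    return ordered, row_order, col_order
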