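"""Distance construction, dbRDA, forward selection, ANOSIM, pathway ledger.

Distance-based redundancy analysis (dbRDA) fits predictor variables to the
principal coordinates of an arbitrary sample dissimilarity matrix:

* Gower-center the squared distances, G = -1/2 J (D o D) J;
* eigendecompose G; real (positive-eigenvalue) axes carry the ordination;
* project onto the predictor hat matrix; R = constrained / total positive
  inertia; pseudo-F from the trace partition of G (the PERMANOVA identity,
  so F agrees exactly with the classical one-factor pseudo-F); p by
  permuting sample rows, with exact enumeration when n! is small.

Two distances are first-class: Bray-Curtis (semi-metric, abundance data)
and the robust Aitchison distance — Euclidean distance on robust-clr
transformed compositions, where the geometric mean is taken over the
nonzero parts of each sample and zeros stay zero after centering.

ANOSIM, the tie-corrected normal-approximation Mann-Whitney test, and the
per-pathway dR model-comparison ledger (R_with - R_without across the two
symbiont-status conditions) live here as well.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations, permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .io import (
    DistanceMatrix,
    ExpressionMatrix,
    OrdinationResult,
    PathwayCatalog,
    SampleTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "bray_curtis",
    "robust_aitchison",
    "rclr",
    "gower_center",
    "dbrda",
    "forward_select",
    "anosim",
    "mann_whitney_z",
    "pathway_ledger",
    "PathwayLedgerRow",
]

EXACT_N_MAX = 7


# ---------------------------------------------------------------------------
# distances


def bray_curtis(m: ExpressionMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples: sum|x-y| / sum(x+y)."""
    X = m.counts.T  # samples x genes
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        bad = [s for s, t in zip(m.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(m.sample_ids, d)


def rclr(m: ExpressionMatrix) -> pd.DataFrame:
    """Robust centered log-ratio transform, samples x genes.

    Per sample: rclr(x)_i = ln(x_i) - mean(ln over positive entries) for
    x_i > 0, and 0 for x_i = 0 (zeros excluded from the geometric mean and
    left at zero after centering — a deliberate simplification of
    matrix-completion-based robust Aitchison).
    """
    X = m.counts.T
    if np.any(X.sum(axis=1) == 0):
        bad = [s for s, t in zip(m.sample_ids, X.sum(axis=1)) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    pos = X > 0
    logs = np.zeros_like(X)
    np.log(X, where=pos, out=logs)
    means = logs.sum(axis=1) / pos.sum(axis=1)
    out = np.where(pos, logs - means[:, None], 0.0)
    return pd.DataFrame(out, index=m.sample_ids, columns=m.gene_ids)


def robust_aitchison(m: ExpressionMatrix) -> DistanceMatrix:
    """Euclidean distance on rclr-transformed samples."""
    t = rclr(m).to_numpy()
    d = squareform(pdist(t, metric="euclidean"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(m.sample_ids, d)


def gower_center(d: DistanceMatrix) -> np.ndarray:
    """Doubly centered Gower matrix G = -1/2 J (D o D) J."""
    D2 = d.values**2
    n = d.n
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    return (G + G.T) / 2.0


# ---------------------------------------------------------------------------
# dbRDA


def _drop_aliased(X: np.ndarray, names: list[str], tol: float = 1e-10):
    """Drop columns that add no rank (after centering), keeping input order."""
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, [j]]
        if basis.shape[1]:
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) > tol * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.hstack([basis, col])
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.warning("dropping aliased predictor column(s): %s", dropped)
    return X[:, keep], [names[j] for j in keep]


def _hat(Xc: np.ndarray) -> np.ndarray:
    return Xc @ np.linalg.pinv(Xc)


def _permutation_indices(n: int, n_perm: int, seed) -> tuple[np.ndarray, bool]:
    """Permutations of range(n): exact enumeration for tiny n, else Monte Carlo."""
    if n <= EXACT_N_MAX or math.factorial(n) <= n_perm:
        return np.array(list(iter_permutations(range(n)))), True
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)]), False


def dbrda(
    response: DistanceMatrix,
    predictors: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | None = None,
    n_axes: int | None = None,
) -> OrdinationResult:
    """Distance-based redundancy analysis with a Monte Carlo permutation test.

    ``predictors`` rows must align with the distance matrix sample order
    (reindexed by sample id when the index matches).  Aliased predictor
    columns are dropped with a warning.  R is the constrained fraction of
    positive inertia; F and its permutation test follow the trace
    partition of the Gower-centered matrix, so with a single factor and
    any distance the pseudo-F equals the classical PERMANOVA statistic.
    """
    n = response.n
    if isinstance(predictors, pd.Series):
        predictors = predictors.to_frame()
    if set(predictors.index) == set(response.sample_ids):
        predictors = predictors.loc[response.sample_ids]
    elif len(predictors) != n:
        raise ValueError("predictor rows do not align with distance samples")
    X = predictors.to_numpy(dtype=float)
    names = [str(c) for c in predictors.columns]
    Xc = X - X.mean(axis=0)
    Xc, kept = _drop_aliased(Xc, names)
    df_model = Xc.shape[1]
    if df_model == 0:
        raise ValueError("no non-constant predictors remain")
    if n <= df_model:
        raise ValueError(
            f"need n_samples > n_predictors (n={n}, predictors={df_model})"
        )
    df_residual = n - 1 - df_model  # 0 for a saturated model (F undefined)

    G = gower_center(response)
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    pos = evals > tol
    neg = evals < -tol
    pos_evals = evals[pos]
    Y = evecs[:, pos] * np.sqrt(pos_evals)  # classical PCoA coordinates
    total_positive = float(pos_evals.sum())

    H = _hat(Xc)
    fitted = H @ Y
    constrained = float((fitted**2).sum())
    R = constrained / total_positive if total_positive > 0 else 0.0
    R = min(max(R, 0.0), 1.0)

    # trace partition of G (includes negative-eigenvalue contributions):
    # this is the PERMANOVA sums-of-squares decomposition
    ss_total = float(np.trace(G))
    ss_model = float(np.sum(H * G))  # trace(HG), H symmetric
    ss_resid = ss_total - ss_model
    if df_residual >= 1 and ss_resid > 1e-12 * max(abs(ss_total), 1.0):
        F = (ss_model / df_model) / (ss_resid / df_residual)
        perms, exact = _permutation_indices(n, n_perm, seed)
        # permuting predictor rows == permuting G rows+cols; F* shares df,
        # and ss_total is permutation invariant, so comparing ss_model suffices
        f_obs = ss_model
        count = 0
        eps = 1e-12
        for perm in perms:
            Gp = G[np.ix_(perm, perm)]
            if float(np.sum(H * Gp)) >= f_obs - eps:
                count += 1
        p = count / len(perms) if exact else (1 + count) / (1 + len(perms))
    else:
        # saturated (or perfectly fitting) model: F undefined, no test
        F = math.inf
        p = 1.0
        perms, exact = np.empty((0, n), dtype=int), False

    # CAP site scores: principal axes of the fitted values
    k_axes = min(df_model, Y.shape[1]) if n_axes is None else n_axes
    U, S, _ = np.linalg.svd(fitted, full_matrices=False)
    scores = (U * S)[:, :k_axes]
    site_scores = pd.DataFrame(
        scores,
        index=response.sample_ids,
        columns=[f"CAP{i + 1}" for i in range(scores.shape[1])],
    )

    return OrdinationResult(
        R=R,
        F=float(F),
        df_model=df_model,
        df_residual=df_residual,
        p_perm=float(p),
        eigenvalues=pos_evals,
        negative_eigenvalues=evals[neg],
        site_scores=site_scores,
        n_perm_used=len(perms),
        exact=exact,
        metadata={"predictors": kept, "seed": seed},
    )


# ---------------------------------------------------------------------------
# forward selection


def _trace_stats(G: np.ndarray, H: np.ndarray, perm_G: np.ndarray) -> np.ndarray:
    """trace(H Gp) for a stack of permuted G matrices (B x n x n)."""
    return np.einsum("ij,bij->b", H, perm_G)


def forward_select(
    response: DistanceMatrix,
    candidates: pd.DataFrame,
    alpha_enter: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    correction: str = "sidak",
) -> tuple[list[str], list[float]]:
    """Greedy forward selection of predictors for a dbRDA model.

    At each step the candidate with the smallest permutation p enters
    (partial-F test, permuting sample rows); ties break toward the larger
    marginal R, then input order.  Duplicate (aliased) candidates never
    enter.  Returns the ordered selected names and their entry p-values;
    the set may be empty.

    ``correction`` controls the entry threshold.  The default "sidak"
    requires the best candidate's p to clear a Sidak-corrected level
    1 - (1 - alpha_enter)**(1/k) for the k candidates screened that step,
    keeping the familywise entry error at ``alpha_enter`` per step —
    uncorrected per-candidate entry ("none") selects noise predictors
    with probability ~1-(1-alpha)^k per step and badly overfits small-n
    models.  ``n_perm`` must be large enough that 1/(n_perm+1) is below
    the corrected level, otherwise nothing can enter (warned).
    """
    if correction not in ("sidak", "none"):
        raise ValueError("correction must be 'sidak' or 'none'")
    n = response.n
    if len(candidates.columns) < 1:
        raise ValueError("need at least one candidate")
    if set(candidates.index) == set(response.sample_ids):
        candidates = candidates.loc[response.sample_ids]
    G = gower_center(response)
    ss_total = float(np.trace(G))
    evals = np.linalg.eigvalsh(G)
    total_positive = float(evals[evals > max(abs(evals).max(), 1.0) * 1e-12].sum())

    perms, exact = _permutation_indices(n, n_perm, seed)
    perm_G = G[perms[:, :, None], perms[:, None, :]]  # B x n x n

    X = candidates.to_numpy(dtype=float)
    names = [str(c) for c in candidates.columns]
    Xc = X - X.mean(axis=0)

    selected: list[int] = []
    entry_p: list[float] = []
    basis = np.empty((n, 0))
    H_sel = np.zeros((n, n))
    ss_sel = 0.0
    ss_sel_perm = np.zeros(len(perms))
    eps = 1e-12

    while True:
        k_next = len(selected) + 1
        if n - 1 - k_next < 1:
            break
        best = None  # (p, -marginal_ss, order, j, H_with, ss_with, ss_with_perm)
        n_screened = 0
        for j in range(Xc.shape[1]):
            if j in selected:
                continue
            col = Xc[:, [j]]
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0] \
                if basis.shape[1] else col
            if np.linalg.norm(resid) <= 1e-10 * max(1.0, np.linalg.norm(col)):
                continue  # aliased with current model
            n_screened += 1
            Xw = np.hstack([basis, col])
            Hw = _hat(Xw)
            ss_with = float(np.sum(Hw * G))
            denom = (ss_total - ss_with) / (n - 1 - k_next)
            if denom <= eps:
                continue
            f_obs = (ss_with - ss_sel) / 1.0 / denom
            ss_with_perm = _trace_stats(G, Hw, perm_G)
            denom_perm = (ss_total - ss_with_perm) / (n - 1 - k_next)
            with np.errstate(divide="ignore", invalid="ignore"):
                f_perm = (ss_with_perm - ss_sel_perm) / denom_perm
            exceed = int(np.sum(f_perm >= f_obs - eps))
            if exact:
                p = exceed / len(perms)
            else:
                p = (1 + exceed) / (1 + len(perms))
            key = (p, -(ss_with - ss_sel), j)
            if best is None or key < best[0]:
                best = (key, j, col, Hw, ss_with, ss_with_perm, p)
        if best is None:
            break
        if correction == "sidak" and n_screened > 0:
            alpha_local = 1.0 - (1.0 - alpha_enter) ** (1.0 / n_screened)
            if not exact and 1.0 / (1 + len(perms)) >= alpha_local:
                logger.warning(
                    "forward_select: n_perm=%d cannot resolve the Sidak-corrected "
                    "entry level %.2g for %d candidates; nothing can enter",
                    len(perms), alpha_local, n_screened,
                )
        else:
            alpha_local = alpha_enter
        _, j, col, Hw, ss_with, ss_with_perm, p = best
        if p >= alpha_local:
            break
        selected.append(j)
        entry_p.append(p)
        basis = np.hstack([basis, col])
        H_sel = Hw
        ss_sel = ss_with
        ss_sel_perm = ss_with_perm
    return [names[j] for j in selected], entry_p


# ---------------------------------------------------------------------------
# ANOSIM


def anosim(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Analysis of similarities: rank-based R and a one-sided permutation p.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances ranked with average ties.  Exact
    enumeration of distinct labelings for n <= 7 samples.
    """
    labels = np.asarray(list(groups))
    n = d.n
    if len(labels) != n:
        raise ValueError("group labels do not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        small = [str(u) for u, c in zip(uniq, counts) if c < 2]
        raise ValueError(f"group(s) of size 1: {small}")

    condensed = squareform(d.values, checks=False)
    ranks = stats.rankdata(condensed)
    M = len(condensed)
    pairs = np.array(list(combinations(range(n), 2)))

    def _r(lab: np.ndarray) -> float:
        within = lab[pairs[:, 0]] == lab[pairs[:, 1]]
        rb = ranks[~within].mean()
        rw = ranks[within].mean()
        return float((rb - rw) / (M / 2.0))

    r_obs = _r(labels)
    eps = 1e-12
    if n <= EXACT_N_MAX:
        seen = set()
        r_stars = []
        for perm in iter_permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            r_stars.append(_r(np.asarray(perm)))
        r_stars = np.asarray(r_stars)
        p = float(np.mean(r_stars >= r_obs - eps))
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            count += _r(labels[rng.permutation(n)]) >= r_obs - eps
        p = (1 + count) / (1 + n_perm)
    return r_obs, p


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney_z(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U with tie-corrected z and two-sided p.

    U = min(U1, U2); z uses the tie-corrected variance and a 0.5
    continuity correction.  For n1 + n2 <= 12 the two-sided p is exact,
    by enumerating all C(n1+n2, n1) group assignments of the pooled
    values; otherwise the normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        z = 0.0
    else:
        z = max(abs(u1 - mu) - 0.5, 0.0) / math.sqrt(var)

    if n <= 12:
        # exact two-sided p: U1 is symmetric about mu under exchangeability
        lo = 0
        hi = 0
        u_lo = min(u1, u2)
        u_hi = max(u1, u2)
        total = 0
        for idx in combinations(range(n), n1):
            total += 1
            r = ranks[list(idx)].sum()
            u1s = r - n1 * (n1 + 1) / 2.0
            if u1s <= u_lo + 1e-12:
                lo += 1
            if u1s >= u_hi - 1e-12:
                hi += 1
        p = (lo + hi) / total
    else:
        p = float(2 * stats.norm.sf(z))
    return float(u), float(z), min(float(p), 1.0)


# ---------------------------------------------------------------------------
# pathway ledger


@dataclass
class PathwayLedgerRow:
    pathway_id: str
    df_with: tuple[int, int]
    R_with: float
    F_with: float
    df_without: tuple[int, int]
    R_without: float
    F_without: float

    @property
    def dR(self) -> float:
        return self.R_with - self.R_without


def _pathway_distance(
    host: ExpressionMatrix,
    sample_ids: list[str],
    genes: list[str],
    distance: str,
    rclr_frame: pd.DataFrame | None,
) -> DistanceMatrix:
    """Sample distances on a pathway's genes.

    For the robust Aitchison distance the rclr transform is taken over the
    *full* host composition (precomputed in ``rclr_frame``) and then
    restricted to the pathway's genes: transforming the pathway submatrix
    alone would re-center each sample by the pathway mean and cancel any
    coordinated (same-direction) pathway response.
    """
    if distance == "braycurtis":
        sub = ExpressionMatrix(host.compartment, host.data.loc[genes, sample_ids])
        return bray_curtis(sub)
    if distance == "rclr":
        t = rclr_frame.loc[sample_ids, genes].to_numpy()
        d = squareform(pdist(t, metric="euclidean"))
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(list(sample_ids), d)
    raise ValueError("distance must be 'braycurtis' or 'rclr'")


def _fit_condition(
    host: ExpressionMatrix,
    sol: ExpressionMatrix,
    sample_ids: list[str],
    genes: list[str],
    candidate_pool: list[str],
    distance: str,
    alpha_enter: float,
    n_perm: int,
    seed: int | None,
    rclr_frame: pd.DataFrame | None = None,
):
    dm = _pathway_distance(host, sample_ids, genes, distance, rclr_frame)
    cand = sol.data.loc[candidate_pool, sample_ids].T
    cand = cand.loc[:, cand.std(axis=0) > 0]
    chosen, _ = forward_select(dm, cand, alpha_enter=alpha_enter,
                               n_perm=n_perm, seed=seed)
    n = len(sample_ids)
    if not chosen:
        return (0, n - 1), 0.0, float("nan")
    res = dbrda(dm, cand.loc[:, chosen], n_perm=n_perm, seed=seed)
    return (res.df_model, res.df_residual), res.R, res.F


def pathway_ledger(
    host: ExpressionMatrix,
    sol: ExpressionMatrix,
    catalog: PathwayCatalog,
    samples: SampleTable,
    distance: str = "rclr",
    candidate_pool: list[str] | None = None,
    alpha_enter: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-pathway dbRDA ledger: R/F/df per condition and dR.

    For each pathway the host genes in the pathway form the response
    (distance on their expression) and forward-selected symbiont genes the
    predictors, fitted separately for cTPut-positive and cTPut-negative
    samples.  dR = R_with - R_without; rows sorted by dR descending.
    ``candidate_pool`` restricts the symbiont genes entering selection
    (defaults to all).
    """
    pos = [s for s in samples.ids_by_status(True) if s in host.sample_ids]
    neg = [s for s in samples.ids_by_status(False) if s in host.sample_ids]
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("both condition subsets need >= 3 samples")
    pool = candidate_pool if candidate_pool is not None else sol.gene_ids
    host_genes = set(host.gene_ids)
    rclr_frames = {"pos": None, "neg": None}
    if distance == "rclr":
        rclr_frames["pos"] = rclr(host.subset_samples(pos))
        rclr_frames["neg"] = rclr(host.subset_samples(neg))
    rows = []
    for pid in catalog.pathway_ids:
        genes = sorted(catalog.members(pid) & host_genes)
        if len(genes) < 2:
            logger.warning("pathway %s has < 2 genes present; skipped", pid)
            continue
        try:
            df_w, r_w, f_w = _fit_condition(
                host, sol, pos, genes, pool, distance, alpha_enter, n_perm, seed,
                rclr_frames["pos"],
            )
            df_wo, r_wo, f_wo = _fit_condition(
                host, sol, neg, genes, pool, distance, alpha_enter, n_perm, seed,
                rclr_frames["neg"],
            )
        except ValueError as exc:
            logger.warning("pathway %s skipped: %s", pid, exc)
            continue
        rows.append(
            {
                "pathway_id": pid,
                "df_model_with": df_w[0],
                "df_residual_with": df_w[1],
                "R_with": r_w,
                "F_with": f_w,
                "df_model_without": df_wo[0],
                "df_residual_without": df_wo[1],
                "R_without": r_wo,
                "F_without": f_wo,
                "dR": r_w - r_wo,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("dR", ascending=False).reset_index(drop=True)
    return out
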