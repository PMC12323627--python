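"""Expression standardization, relative abundance, diversity and transforms.

Symbiont expression is standardized to a fixed per-sample read total
(3,000 reads for SOL, 5,000 for cTPut in the motivating study) before
correlation and ordination.  Two readings of "standardized to N reads"
are provided: deterministic proportional scaling (default; preserves
within-sample proportions exactly, hence leaves Spearman correlations
unchanged) and multinomial downsampling (rarefaction; seeded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, NormalizedMatrix

__all__ = [
    "standardize_counts",
    "relative_abundance",
    "shannon_diversity",
    "log_transform",
    "qpcr_preprocess",
]


def standardize_counts(
    m: ExpressionMatrix,
    target_total: float,
    mode: str = "scale",
    seed: int | None = None,
) -> NormalizedMatrix:
    """Standardize every sample to ``target_total`` reads.

    ``scale`` multiplies each column by target/total (real-valued output);
    ``downsample`` draws a multinomial subsample of exactly ``target_total``
    reads (requires integer target and per-sample totals >= target).
    """
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    totals = m.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    if mode == "scale":
        scaled = m.data * (target_total / totals)
        return NormalizedMatrix(m.compartment, scaled, method=f"scale:{target_total:g}")
    if mode == "downsample":
        target = int(target_total)
        if target != target_total:
            raise ValueError("downsample mode requires an integer target")
        short = totals[totals < target]
        if len(short):
            raise ValueError(
                f"sample(s) with fewer than {target} reads: {list(short.index)}"
            )
        rng = np.random.default_rng(seed)
        out = np.empty(m.shape, dtype=float)
        counts = m.counts
        for j, total in enumerate(totals.to_numpy()):
            p = counts[:, j] / total
            out[:, j] = rng.multinomial(target, p)
        df = pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids)
        return NormalizedMatrix(
            m.compartment, df, method=f"downsample:{target}:seed={seed}"
        )
    raise ValueError(f"unknown mode {mode!r}; expected 'scale' or 'downsample'")


def relative_abundance(sym_reads, host_reads):
    """Per-sample symbiont/host mapped-read proportion.

    Accepts scalars or aligned array-likes; host totals must be positive.
    """
    sym = np.asarray(sym_reads, dtype=float)
    host = np.asarray(host_reads, dtype=float)
    if np.any(host <= 0):
        raise ValueError("host read totals must be positive")
    out = sym / host
    if np.ndim(sym_reads) == 0 and np.ndim(host_reads) == 0:
        return float(out)
    if isinstance(sym_reads, pd.Series):
        return pd.Series(out, index=sym_reads.index)
    return out


def shannon_diversity(m: ExpressionMatrix, base: str = "e") -> pd.Series:
    """Shannon diversity H per sample, over genes with positive counts.

    H = -sum p_i log p_i; ``base`` is 'e' (nats, default) or '2' (bits).
    """
    if base not in ("e", "2", 2):
        raise ValueError("base must be 'e' or '2'")
    counts = m.counts
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        bad = [s for s, t in zip(m.sample_ids, totals) if t == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    p = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=0)
    if base in ("2", 2):
        h = h / np.log(2.0)
    return pd.Series(h, index=m.sample_ids, name="shannon")


def log_transform(
    m: ExpressionMatrix, base: int = 2, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Elementwise log_base(x + pseudocount)."""
    if base not in (2, 10):
        raise ValueError("base must be 2 or 10")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values = m.counts
    if pseudocount == 0 and (values == 0).any():
        raise ValueError("zeros present: a positive pseudocount is required")
    out = np.log(values + pseudocount) / np.log(base)
    df = pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids)
    return NormalizedMatrix(m.compartment, df, method=f"log{base}:pc={pseudocount:g}")


def qpcr_preprocess(values, detection_limit: float = 10.0):
    """qPCR copy-number preprocessing: censor below the detection limit, log10.

    Values below ``detection_limit`` (10 copies in the motivating assay) are
    replaced with zero before the log10(x + 1) transform.
    """
    if detection_limit <= 0:
        raise ValueError("detection_limit must be positive")
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("copy numbers must be non-negative")
    censored = np.where(x < detection_limit, 0.0, x)
    out = np.log10(censored + 1.0)
    if np.ndim(values) == 0:
        return float(out)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index)
    return out
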