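"""Synthetic tripartite meta-transcriptome generator.

Emulates the study design the pipeline is built for: four mite cultures,
two carrying the intracellular symbiont cTPut ("5L", "5S") and two without
it ("5Pi", "5Tk"), seven replicates each (28 samples).  Three count
compartments are produced — host KEGG genes, SOL (the Solitalea-like gut
symbiont) genes, and cTPut genes — with planted cross-compartment
correlation blocks and a condition effect that lowers SOL relative
abundance in cTPut-positive samples.

Counts follow a latent-factor Gaussian copula with negative-binomial
marginals: per sample a vector of latent factors is drawn; genes inside a
planted block load on a shared factor with the block's sign and loading,
and their latent Gaussian values are pushed through the NB quantile
function.  This makes planted *rank* correlations controllable (two genes
with loadings a and b on the same factor have latent correlation a*b),
which is the right handle for a Spearman-based pipeline.

cTPut columns exist only for cTPut-positive samples: absence in negative
cultures is structural (missing columns), not zero counts, matching the
study design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PathwayCatalog, SampleTable, SimTruth

__all__ = ["Block", "SimConfig", "simulate", "default_blocks"]

POS_CULTURES = ("5L", "5S")
NEG_CULTURES = ("5Pi", "5Tk")


@dataclass(frozen=True)
class Block:
    """A planted cross-compartment correlation block.

    Genes are given as (compartment, start, stop) index ranges; every gene
    in side A is correlated with every gene in side B with latent
    correlation ``loading**2`` and the given sign.  ``condition`` restricts
    the coupling to a sample subset ("all" or "ctput_positive").
    """

    a_compartment: str
    a_range: tuple[int, int]
    b_compartment: str
    b_range: tuple[int, int]
    sign: int = 1
    loading: float = 0.9
    condition: str = "all"

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError("block sign must be +1 or -1")
        if not (0 < self.loading <= 1):
            raise ValueError("block loading must lie in (0, 1]")
        if self.condition not in ("all", "ctput_positive"):
            raise ValueError("block condition must be 'all' or 'ctput_positive'")


def default_blocks() -> list[Block]:
    """Default planted structure (see docs/methods.md for the sizing logic)."""
    return [
        Block("host", (0, 80), "SOL", (0, 10), sign=1, loading=0.9),
        Block("host", (80, 160), "SOL", (10, 20), sign=-1, loading=0.9),
        Block("host", (160, 200), "cTPut", (0, 10), sign=1, loading=0.9),
        Block("host", (200, 260), "SOL", (20, 28), sign=1, loading=0.9,
              condition="ctput_positive"),
    ]


@dataclass
class SimConfig:
    n_reps: int = 7
    n_genes: dict = field(
        default_factory=lambda: {"host": 500, "SOL": 200, "cTPut": 150}
    )
    blocks: list[Block] = field(default_factory=default_blocks)
    nb_dispersion: float = 0.5      # NB size parameter r (smaller = noisier)
    baseline_mean: float = 50.0     # mean counts per gene before library effects
    libsize_sigma: float = 0.3      # log-normal spread of library sizes
    sol_multiplier: float = 0.6     # SOL library scale in cTPut-positive samples
    pathway_size: int = 25
    extra_memberships: int = 2      # extra umbrella-pathway memberships per host gene
    n_umbrella: int = 4             # large umbrella pathways absorbing the overlap
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        for comp, n in self.n_genes.items():
            if n < 1:
                raise ValueError(f"n_genes[{comp}] must be >= 1")
        if self.sol_multiplier <= 0:
            raise ValueError("sol_multiplier must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for blk in self.blocks:
            for comp, (lo, hi) in ((blk.a_compartment, blk.a_range),
                                   (blk.b_compartment, blk.b_range)):
                if comp not in self.n_genes:
                    raise ValueError(f"block references unknown compartment {comp!r}")
                if not (0 <= lo < hi <= self.n_genes[comp]):
                    raise ValueError(
                        f"block gene range {lo}:{hi} outside compartment "
                        f"{comp!r} of size {self.n_genes[comp]}"
                    )


def _gene_ids(comp: str, n: int) -> list[str]:
    prefix = {"host": "K", "SOL": "LOCUS_", "cTPut": "CTP_"}[comp]
    return [f"{prefix}{i:05d}" for i in range(n)]


def _nb_quantile(u: np.ndarray, mean: np.ndarray, r: float) -> np.ndarray:
    """NB quantile transform: u in (0,1), per-cell mean, shared dispersion r."""
    p = r / (r + mean)
    return stats.nbinom.ppf(u, r, p)


def simulate(config: SimConfig):
    """Generate (matrices, samples, catalog, truth) for one seed.

    Returns a dict of ExpressionMatrix keyed by compartment (``cTPut``
    restricted to positive samples), a SampleTable, a PathwayCatalog over
    host genes, and the SimTruth record.
    """
    rng = np.random.default_rng(config.seed)

    cultures = list(POS_CULTURES) + list(NEG_CULTURES)
    rows = []
    for culture in cultures:
        positive = culture in POS_CULTURES
        for rep in range(1, config.n_reps + 1):
            rows.append(
                {
                    "sample_id": f"{culture}_r{rep}",
                    "culture": culture,
                    "ctput_status": positive,
                    "replicate": rep,
                }
            )
    samples = SampleTable(pd.DataFrame(rows))
    sample_ids = samples.sample_ids
    n_samples = len(sample_ids)
    positive_mask = np.array([samples.status_of(s) for s in sample_ids])

    # one latent factor per planted block, drawn independently per sample
    n_factors = len(config.blocks)
    factors = rng.standard_normal((n_samples, n_factors))

    # latent Gaussian per (sample, gene); block genes mix factor + noise
    gene_ids = {c: _gene_ids(c, n) for c, n in config.n_genes.items()}
    latent = {
        c: rng.standard_normal((n_samples, n)) for c, n in config.n_genes.items()
    }
    loading_of: dict[str, dict[int, tuple[int, float, int, str]]] = {
        c: {} for c in config.n_genes
    }
    for k, blk in enumerate(config.blocks):
        for comp, (lo, hi), sgn in (
            (blk.a_compartment, blk.a_range, 1),
            (blk.b_compartment, blk.b_range, blk.sign),
        ):
            for g in range(lo, hi):
                if g in loading_of[comp]:
                    raise ValueError(
                        f"gene index {g} of {comp!r} appears in two blocks"
                    )
                loading_of[comp][g] = (k, blk.loading, sgn, blk.condition)
    for comp, assignments in loading_of.items():
        for g, (k, lam, sgn, condition) in assignments.items():
            active = (
                np.ones(n_samples, dtype=bool)
                if condition == "all"
                else positive_mask
            )
            noise = latent[comp][:, g]
            mixed = sgn * lam * factors[:, k] + np.sqrt(1 - lam**2) * noise
            latent[comp][:, g] = np.where(active, mixed, noise)

    # library sizes: log-normal per sample, SOL suppressed in positive samples
    libsize = {
        c: np.exp(rng.normal(0.0, config.libsize_sigma, size=n_samples))
        for c in config.n_genes
    }
    libsize["SOL"] = libsize["SOL"] * np.where(
        positive_mask, config.sol_multiplier, 1.0
    )

    matrices: dict[str, ExpressionMatrix] = {}
    for comp, n in config.n_genes.items():
        u = stats.norm.cdf(latent[comp])
        # clip away exact 0/1 so the NB quantile stays finite
        u = np.clip(u, 1e-12, 1 - 1e-12)
        mean = config.baseline_mean * libsize[comp][:, None]
        counts = _nb_quantile(u, np.broadcast_to(mean, u.shape), config.nb_dispersion)
        df = pd.DataFrame(counts.T, index=gene_ids[comp], columns=sample_ids)
        if comp == "cTPut":
            keep = [s for s, pos in zip(sample_ids, positive_mask) if pos]
            df = df.loc[:, keep]
        matrices[comp] = ExpressionMatrix(comp, df)

    catalog, condition_pathway = _host_pathways(config, gene_ids["host"], rng)

    planted_pairs = []
    planted_genes: dict[str, set[str]] = {c: set() for c in config.n_genes}
    for blk in config.blocks:
        a_ids = gene_ids[blk.a_compartment][blk.a_range[0] : blk.a_range[1]]
        b_ids = gene_ids[blk.b_compartment][blk.b_range[0] : blk.b_range[1]]
        planted_genes[blk.a_compartment].update(a_ids)
        planted_genes[blk.b_compartment].update(b_ids)
        for ga in a_ids:
            for gb in b_ids:
                planted_pairs.append(
                    (
                        ga,
                        blk.a_compartment,
                        gb,
                        blk.b_compartment,
                        blk.sign,
                        blk.loading,
                        blk.condition,
                    )
                )

    truth = SimTruth(
        planted_pairs=planted_pairs,
        planted_genes={c: sorted(g) for c, g in planted_genes.items()},
        condition_pathway=condition_pathway,
        sol_abundance_multiplier=config.sol_multiplier,
        seed=config.seed,
        params={
            "n_reps": config.n_reps,
            "n_genes": dict(config.n_genes),
            "nb_dispersion": config.nb_dispersion,
            "baseline_mean": config.baseline_mean,
            "libsize_sigma": config.libsize_sigma,
            "pathway_size": config.pathway_size,
            "extra_memberships": config.extra_memberships,
            "n_blocks": len(config.blocks),
        },
    )
    return matrices, samples, catalog, truth


def _host_pathways(config: SimConfig, host_genes: list[str], rng):
    """Partition host genes into base pathways plus umbrella pathways.

    Base pathways are clean contiguous chunks of ``pathway_size`` genes;
    every gene additionally joins ``extra_memberships`` of ``n_umbrella``
    large umbrella pathways at random, so typical multiplicity is
    1 + extra_memberships.  This mimics the shape of KEGG catalogs, where
    a gene sits in one specific pathway and several broad signalling
    umbrellas.  Returns the catalog and the id of the base pathway
    containing the first gene of the first condition-specific block (the
    "planted pathway" for recovery checks), or None.
    """
    n = len(host_genes)
    size = config.pathway_size
    n_pathways = max(1, (n + size - 1) // size)
    sets: dict[str, set[str]] = {}
    for p in range(n_pathways):
        pid = f"pw{p:03d}"
        members = set(host_genes[p * size : (p + 1) * size])
        if members:
            sets[pid] = members
    umbrellas = [f"umbrella{u:02d}" for u in range(config.n_umbrella)]
    if umbrellas and config.extra_memberships > 0:
        for pid in umbrellas:
            sets[pid] = set()
        k = min(config.extra_memberships, len(umbrellas))
        for gene in host_genes:
            for pid in rng.choice(umbrellas, size=k, replace=False):
                sets[pid].add(gene)
        sets = {pid: members for pid, members in sets.items() if members}
    catalog = PathwayCatalog(
        sets=sets, names={pid: f"synthetic pathway {pid}" for pid in sets}
    )
    condition_pathway = None
    for blk in config.blocks:
        if blk.condition == "ctput_positive" and blk.a_compartment == "host":
            condition_pathway = f"pw{blk.a_range[0] // size:03d}"
            break
    return catalog, condition_pathway
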