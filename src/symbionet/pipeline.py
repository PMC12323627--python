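"""One-shot pipeline: simulate (or load), normalize, correlate, ordinate.

``full_run`` chains the analysis stages in study order and writes every
result table plus a machine-readable manifest.  All randomness is funneled
through named child seeds derived deterministically from the global seed,
so two runs with the same configuration are identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corrnet import (
    CorrConfig,
    compare_edge_counts,
    correlation_heatmap_matrix,
    correlation_matrix,
    edge_count_table,
    filter_hubs,
    gene_stats,
)
from .diffexpr import pathway_aggregate, per_gene_contrast
from .io import (
    read_counts,
    read_pathways,
    read_samples,
    write_counts,
    write_edges,
    write_pathways,
    write_samples,
)
from .normalize import relative_abundance, shannon_diversity, standardize_counts
from .ordination import anosim, bray_curtis, dbrda, mann_whitney_z, pathway_ledger, robust_aitchison
from .simulate import SimConfig, simulate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "child_seed", "full_run"]


def child_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    outdir: str = "symbionet_run"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig | None = None
    counts: dict = field(default_factory=dict)   # compartment -> path
    samples_path: str | None = None
    pathways_path: str | None = None
    sol_target: float = 3000.0
    ctput_target: float = 5000.0
    standardize_mode: str = "scale"
    n_perm_edges: int = 999
    n_perm_ordination: int = 999
    alpha: float = 0.05
    hub_rho_min: float = 0.75
    hub_min_strength: float = 100.0
    ledger_distance: str = "rclr"
    ledger_candidates: int = 40  # symbiont genes entering forward selection
    ledger_max_pathways: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim_payload = payload.pop("sim", None)
        cfg = cls(**payload)
        if sim_payload:
            cfg.sim = SimConfig(**sim_payload)
        return cfg


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", **kwargs)


def full_run(config: RunConfig) -> Path:
    """Run every stage; returns the report directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "sol_target": config.sol_target,
            "ctput_target": config.ctput_target,
            "standardize_mode": config.standardize_mode,
            "n_perm_edges": config.n_perm_edges,
            "n_perm_ordination": config.n_perm_ordination,
            "alpha": config.alpha,
            "hub_rho_min": config.hub_rho_min,
            "hub_min_strength": config.hub_min_strength,
            "ledger_distance": config.ledger_distance,
        },
        "stage_seeds": {},
        "results": {},
    }

    def seed_for(stage: str) -> int:
        s = child_seed(config.seed, stage)
        manifest["stage_seeds"][stage] = s
        return s

    # --- inputs ----------------------------------------------------------
    if config.simulate:
        sim = config.sim or SimConfig()
        sim.seed = seed_for("simulate")
        matrices, samples, catalog, truth = simulate(sim)
        for comp, m in matrices.items():
            write_counts(m, out / f"counts_{comp}.tsv")
        write_samples(samples, out / "samples.tsv")
        write_pathways(catalog, out / "pathways.gmt")
        truth.to_json(out / "truth.json")
    else:
        if not config.samples_path or not Path(config.samples_path).exists():
            raise FileNotFoundError(
                f"sample sheet not found: {config.samples_path!r}"
            )
        samples = read_samples(config.samples_path)
        matrices = {}
        for comp, path in config.counts.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"count table not found: {path!r}")
            matrices[comp] = read_counts(path, comp)
        catalog = read_pathways(config.pathways_path) if config.pathways_path else None
        truth = None

    host, sol = matrices["host"], matrices["SOL"]
    ctput = matrices.get("cTPut")
    pos_ids = [s for s in samples.ids_by_status(True) if s in sol.sample_ids]
    neg_ids = [s for s in samples.ids_by_status(False) if s in sol.sample_ids]

    # --- normalization ---------------------------------------------------
    sol_std = standardize_counts(
        sol, config.sol_target, mode=config.standardize_mode,
        seed=seed_for("standardize_sol"),
    )
    write_counts(sol_std, out / "sol_standardized.tsv")
    ctput_std = None
    if ctput is not None:
        ctput_std = standardize_counts(
            ctput, config.ctput_target, mode=config.standardize_mode,
            seed=seed_for("standardize_ctput"),
        )
        write_counts(ctput_std, out / "ctput_standardized.tsv")

    # --- relative abundance & diversity (study's Fig 2 shape) -------------
    rel = relative_abundance(
        sol.sample_totals(), host.sample_totals().loc[sol.sample_ids]
    )
    u_rel, z_rel, p_rel = mann_whitney_z(rel.loc[neg_ids], rel.loc[pos_ids])
    div = shannon_diversity(sol_std)
    u_div, z_div, p_div = mann_whitney_z(div.loc[neg_ids], div.loc[pos_ids])
    abundance = pd.DataFrame(
        {"sample_id": rel.index, "sol_host_ratio": rel.values,
         "shannon": div.loc[rel.index].values}
    )
    _write_tsv(abundance, out / "abundance_diversity.tsv", index=False)
    manifest["results"]["relative_abundance_test"] = {
        "U": u_rel, "z": z_rel, "p": p_rel}
    manifest["results"]["shannon_test"] = {"U": u_div, "z": z_div, "p": p_div}

    # --- condition ordination (dbRDA + ANOSIM on SOL expression) ----------
    dm_sol = bray_curtis(sol_std)
    status = pd.DataFrame(
        {"ctput": [float(samples.status_of(s)) for s in dm_sol.sample_ids]},
        index=dm_sol.sample_ids,
    )
    res_cond = dbrda(dm_sol, status, n_perm=config.n_perm_ordination,
                     seed=seed_for("dbrda_condition"))
    manifest["results"]["dbrda_condition"] = {
        "R": res_cond.R, "F": res_cond.F, "df_model": res_cond.df_model,
        "df_residual": res_cond.df_residual, "p": res_cond.p_perm,
    }
    _write_tsv(res_cond.site_scores, out / "dbrda_condition_site_scores.tsv")
    groups = [samples.culture_of(s) for s in dm_sol.sample_ids]
    r_anosim, p_anosim = anosim(dm_sol, groups, n_perm=config.n_perm_ordination,
                                seed=seed_for("anosim"))
    manifest["results"]["anosim_culture"] = {"R": r_anosim, "p": p_anosim}

    # --- symbiont-symbiont network (positive samples only) ----------------
    edge_cfg = CorrConfig(n_perm=config.n_perm_edges, alpha=config.alpha,
                          seed=seed_for("edges_sol_ctput"))
    if ctput_std is not None:
        edges_sc, rho_sc, _ = correlation_matrix(
            sol_std, ctput_std, edge_cfg, sample_subset=pos_ids, return_full=True
        )
        write_edges(edges_sc, out / "edges_sol_ctput.tsv", format="tsv")
        write_edges(edges_sc, out / "edges_sol_ctput.sif", format="sif")
        ordered, _, _ = correlation_heatmap_matrix(rho_sc)
        _write_tsv(ordered, out / "rho_sol_ctput_ward_ordered.tsv")
        manifest["results"]["edges_sol_ctput"] = {
            "n_edges": int(len(edges_sc)),
            "n_positive": int((edges_sc["sign"] > 0).sum()),
            "n_negative": int((edges_sc["sign"] < 0).sum()),
        }

    # --- host-symbiont networks per condition ------------------------------
    stats_tables = {}
    count_tables = {}
    for label, subset in (("with_ctput", pos_ids), ("without_ctput", neg_ids)):
        cfg = CorrConfig(n_perm=config.n_perm_edges, alpha=config.alpha,
                         seed=seed_for(f"edges_host_sol_{label}"))
        edges = correlation_matrix(host, sol_std, cfg, sample_subset=subset)
        write_edges(edges, out / f"edges_host_sol_{label}.tsv", format="tsv")
        manifest["results"][f"edges_host_sol_{label}"] = {
            "n_edges": int(len(edges)),
            "n_positive": int((edges["sign"] > 0).sum()),
            "n_negative": int((edges["sign"] < 0).sum()),
        }
        count_tables[label] = edge_count_table(edges, focal="target")
        # hub scoring under the hub window
        hub_cfg = CorrConfig(
            n_perm=config.n_perm_edges, alpha=config.alpha,
            rho_min=config.hub_rho_min, min_strength=config.hub_min_strength,
            seed=cfg.seed,
        )
        hub_edges = edges.loc[np.abs(edges["rho"]) >= config.hub_rho_min]
        st = gene_stats(hub_edges, catalog, mode="pathway_instance",
                        focal="target") if catalog is not None else None
        if st is not None:
            hubs = filter_hubs(st, hub_cfg)
            _write_tsv(st, out / f"genestats_sol_{label}.tsv", index=False)
            _write_tsv(hubs, out / f"hubs_sol_{label}.tsv", index=False)
            stats_tables[label] = st
            manifest["results"][f"hubs_sol_{label}"] = {"n_hubs": int(len(hubs))}

    paired = compare_edge_counts(count_tables["with_ctput"],
                                 count_tables["without_ctput"])
    manifest["results"]["edge_count_paired_t"] = {
        k: {"t": v.t, "p": v.p, "mean_with": v.mean_a, "mean_without": v.mean_b,
            "n_pairs": v.n_pairs}
        for k, v in paired.items()
    }

    # --- pathway ledger ----------------------------------------------------
    if catalog is not None:
        pool = sol_std.gene_ids[: config.ledger_candidates]
        led_catalog = catalog
        if config.ledger_max_pathways is not None:
            keep = catalog.pathway_ids[: config.ledger_max_pathways]
            from .io import PathwayCatalog

            led_catalog = PathwayCatalog(
                sets={pid: catalog.members(pid) for pid in keep},
                names={pid: catalog.names[pid] for pid in keep},
            )
        ledger = pathway_ledger(
            host, sol_std, led_catalog, samples,
            distance=config.ledger_distance, candidate_pool=pool,
            n_perm=config.n_perm_ordination, seed=seed_for("ledger"),
        )
        _write_tsv(ledger, out / "pathway_ledger.tsv", index=False)
        manifest["results"]["pathway_ledger"] = {
            "n_pathways": int(len(ledger)),
            "max_dR": float(ledger["dR"].max()) if len(ledger) else None,
        }

    # --- differential expression -------------------------------------------
    contrasts = per_gene_contrast(sol_std, samples)
    _write_tsv(contrasts, out / "contrasts_sol.tsv", index=False)
    manifest["results"]["contrasts_sol"] = {
        "n_genes": int(len(contrasts)),
        "n_significant": int(contrasts["significant"].sum()),
    }
    if catalog is not None:
        pw = pathway_aggregate(host, samples, catalog)
        _write_tsv(pw, out / "contrasts_host_pathways.tsv", index=False)
        manifest["results"]["contrasts_host_pathways"] = {
            "n_pathways": int(len(pw)),
            "n_significant": int(pw["significant"].sum()),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("full run complete: %s", out)
    return out
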