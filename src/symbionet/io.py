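"""Core data model and readers/writers.

The pipeline moves gene-by-sample count tables for three expression
compartments (the mite host's KEGG-annotated genes and the two bacterial
symbionts), a sample sheet mapping samples to cultures and symbiont status,
GMT pathway gene sets, and derived tables (edge lists, per-gene network
statistics, distance matrices, ordination results).

All on-disk formats are plain text: TSV with a header row for tables, GMT
for gene sets, SIF or TSV for edge lists.  Gene identifiers are opaque
strings (KEGG K-numbers and locus tags both occur).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("host", "SOL", "cTPut")

__all__ = [
    "COMPARTMENTS",
    "ExpressionMatrix",
    "NormalizedMatrix",
    "SampleTable",
    "PathwayCatalog",
    "DistanceMatrix",
    "OrdinationResult",
    "SimTruth",
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_pathways",
    "write_pathways",
    "read_edges",
    "write_edges",
    "EDGE_COLUMNS",
    "validate_edges",
]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_duplicates(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} identifier: {lab!r}")
        seen.add(lab)


@dataclass
class ExpressionMatrix:
    """Non-negative counts for one compartment, genes x samples.

    ``data`` is a DataFrame indexed by gene id with sample ids as columns.
    """

    compartment: str
    data: pd.DataFrame

    # log-like transforms may legitimately produce negatives; see NormalizedMatrix
    _allow_negative = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )
        _check_duplicates(list(self.data.index), "gene")
        _check_duplicates(list(self.data.columns), "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("count table contains non-numeric entries")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at gene {self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        if not self._allow_negative and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        sub = self.data.loc[:, list(sample_ids)]
        if isinstance(self, NormalizedMatrix):
            return NormalizedMatrix(self.compartment, sub, method=self.method)
        return ExpressionMatrix(self.compartment, sub)

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)


@dataclass
class NormalizedMatrix(ExpressionMatrix):
    """An ExpressionMatrix after standardization or transformation.

    ``method`` records how the values were produced (e.g. ``scale:3000``,
    ``downsample:5000:seed=7``, ``log2:pc=1``); downstream results carry it
    into their audit trail.  Transformed values may be negative.
    """

    method: str = "identity"
    _allow_negative = True


@dataclass
class SampleTable:
    """Sample sheet: the single source of truth for culture -> condition.

    Columns: sample_id, culture, ctput_status (bool), replicate (>=1).
    """

    data: pd.DataFrame

    REQUIRED = ("sample_id", "culture", "ctput_status", "replicate")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValidationError(f"sample sheet missing column {col!r}")
        _check_duplicates(list(self.data["sample_id"]), "sample")
        status = self.data["ctput_status"]
        if status.dtype != bool:
            coerced = status.map(
                {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
            )
            if coerced.isna().any():
                raise ValidationError("ctput_status must be boolean")
            self.data = self.data.assign(ctput_status=coerced.astype(bool))
        if (self.data["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be >= 1")
        # each culture maps to exactly one condition
        per_culture = self.data.groupby("culture")["ctput_status"].nunique()
        bad = per_culture[per_culture > 1]
        if len(bad):
            raise ValidationError(
                f"culture(s) with inconsistent ctput_status: {list(bad.index)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def status_of(self, sample_id: str) -> bool:
        row = self.data.loc[self.data["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in sample sheet")
        return bool(row["ctput_status"].iloc[0])

    def ids_by_status(self, ctput_positive: bool) -> list[str]:
        mask = self.data["ctput_status"] == ctput_positive
        return list(self.data.loc[mask, "sample_id"])

    def culture_of(self, sample_id: str) -> str:
        row = self.data.loc[self.data["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in sample sheet")
        return str(row["culture"].iloc[0])

    def cultures(self) -> list[str]:
        return list(dict.fromkeys(self.data["culture"]))

    def check_covers(self, m: ExpressionMatrix) -> None:
        missing = [s for s in m.sample_ids if s not in set(self.sample_ids)]
        if missing:
            raise ValidationError(f"matrix samples absent from sample sheet: {missing}")


@dataclass
class PathwayCatalog:
    """Pathway -> member gene sets; a gene may belong to several pathways.

    Multiplicity across pathways is meaningful downstream: hub strength
    counts one edge instance per (gene, pathway) membership.
    """

    sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.sets.items():
            if not members:
                raise ValidationError(f"pathway {pid!r} has no member genes")
        for pid in self.sets:
            self.names.setdefault(pid, pid)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.sets)

    def members(self, pathway_id: str) -> set[str]:
        return self.sets[pathway_id]

    def pathways_of(self, gene_id: str) -> list[str]:
        return [pid for pid, members in self.sets.items() if gene_id in members]

    def multiplicity(self, gene_id: str) -> int:
        return sum(1 for members in self.sets.values() if gene_id in members)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, gene_id: str) -> bool:
        return any(gene_id in members for members in self.sets.values())


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample-by-sample distances, zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValidationError("distance matrix is not symmetric (tol 1e-12)")
        if np.any(np.diag(v) != 0.0):
            raise ValidationError("distance matrix diagonal must be exactly zero")
        if (v < 0).any():
            raise ValidationError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class OrdinationResult:
    """Constrained-ordination (dbRDA) or related permutation-test output.

    R is the fraction of positive inertia explained by the constraints;
    F the pseudo-F of the permutation test; eigenvalues are reported with
    negative (imaginary-axis) ones kept separate.
    """

    R: float
    F: float
    df_model: int
    df_residual: int
    p_perm: float
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    site_scores: pd.DataFrame | None = None
    n_perm_used: int = 0
    exact: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.R <= 1 + 1e-9):
            raise ValidationError(f"R must lie in [0, 1], got {self.R}")
        if self.df_model < 0 or self.df_residual < 0:
            raise ValidationError("degrees of freedom must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted by the synthetic generator.

    planted_pairs: (gene_a, compartment_a, gene_b, compartment_b, sign,
    loading, condition) — condition is "all" or "ctput_positive".
    """

    planted_pairs: list[tuple]
    planted_genes: dict[str, list[str]]
    condition_pathway: str | None
    sol_abundance_multiplier: float
    seed: int
    params: dict

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "planted_genes": self.planted_genes,
            "condition_pathway": self.condition_pathway,
            "sol_abundance_multiplier": self.sol_abundance_multiplier,
            "seed": self.seed,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_pairs=[tuple(p) for p in payload["planted_pairs"]],
            planted_genes=payload["planted_genes"],
            condition_pathway=payload["condition_pathway"],
            sol_abundance_multiplier=payload["sol_abundance_multiplier"],
            seed=payload["seed"],
            params=payload["params"],
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_counts(path: str | Path, compartment: str) -> ExpressionMatrix:
    """Read a TSV count table: first column gene ids, header row sample ids."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_duplicates(header[1:], "sample")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None  # the first-column header is cosmetic
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(compartment, df)


def write_counts(m: ExpressionMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene_id")


def read_samples(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "culture": str})
    return SampleTable(df)


def write_samples(t: SampleTable, path: str | Path) -> None:
    t.data.to_csv(path, sep="\t", index=False)


def read_pathways(path: str | Path) -> PathwayCatalog:
    """Read a GMT file: pathway_id <TAB> description <TAB> member genes..."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs id, description and >=1 member gene"
                )
            pid, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
            if not members:
                raise ValidationError(f"{path}:{lineno}: pathway {pid!r} has no members")
            if pid in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            sets[pid] = set(members)
            names[pid] = desc
    return PathwayCatalog(sets=sets, names=names)


def write_pathways(catalog: PathwayCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in catalog.pathway_ids:
            members = sorted(catalog.members(pid))
            fh.write("\t".join([pid, catalog.names[pid], *members]) + "\n")


# --- edge tables -----------------------------------------------------------

EDGE_COLUMNS = [
    "source_gene",
    "source_compartment",
    "target_gene",
    "target_compartment",
    "rho",
    "p_perm",
    "sign",
    "pathway_context",
]


def empty_edge_table() -> pd.DataFrame:
    return pd.DataFrame(columns=EDGE_COLUMNS)


def validate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Validate an edge table's invariants; returns the frame unchanged."""
    for col in EDGE_COLUMNS:
        if col not in edges.columns:
            raise ValidationError(f"edge table missing column {col!r}")
    if len(edges) == 0:
        return edges
    rho = edges["rho"].to_numpy(dtype=float)
    if (np.abs(rho) > 1 + 1e-12).any():
        raise ValidationError("|rho| must be <= 1")
    sign = edges["sign"].to_numpy(dtype=int)
    expected = np.where(rho > 0, 1, -1)
    if (sign != expected).any():
        raise ValidationError("sign must be +1 iff rho > 0, else -1")
    p = edges["p_perm"].to_numpy(dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("p_perm must lie in (0, 1]")
    self_edges = edges["source_gene"] == edges["target_gene"]
    same_comp = edges["source_compartment"] == edges["target_compartment"]
    if (self_edges & same_comp).any():
        raise ValidationError("self-edges are not allowed")
    key = edges[["source_gene", "target_gene", "pathway_context"]].astype(str)
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValidationError(f"duplicate edge (source, target, pathway): {tuple(dup)}")
    return edges


def write_edges(edges: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write an edge table as TSV (full columns) or SIF (``pos``/``neg`` labels)."""
    validate_edges(edges)
    path = Path(path)
    if format == "tsv":
        edges.to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with open(path, "w") as fh:
            for _, row in edges.iterrows():
                label = "pos" if row["sign"] > 0 else "neg"
                fh.write(f"{row['source_gene']}\t{label}\t{row['target_gene']}\n")
    else:
        raise ValueError(f"unknown edge format {format!r}; expected 'sif' or 'tsv'")


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"source_gene": str, "target_gene": str})
    if len(df) and "pathway_context" in df.columns:
        df["pathway_context"] = df["pathway_context"].where(
            ~df["pathway_context"].isna(), None
        )
    else:
        df["pathway_context"] = pd.Series([None] * len(df), dtype=object)
    return validate_edges(df)
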