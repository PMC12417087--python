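"""Core in-memory containers shared by all pipeline stages.

All identifiers are case-sensitive exact strings; no symbol aliasing is
performed anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {kind} identifier: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of real expression values.

    Parameters
    ----------
    gene_ids
        Ordered unique gene symbols (length N, N >= 2).
    sample_ids
        Ordered unique sample identifiers (length M, M >= 2).
    values
        N x M array; ``values[n, m]`` is the expression of gene ``n`` in
        sample ``m``. All entries must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise ValidationError("expression matrix needs at least 2 genes and 2 samples")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value for gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` (kept in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), self.sample_ids, self.values[rows, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class StagePartition:
    """Assignment of samples to ordered disease stages.

    ``stage_labels`` fixes the temporal order; every sample maps to exactly
    one stage and every stage holds at least two samples (differential
    statistics and per-stage averaging are undefined otherwise).
    """

    stage_labels: list[str]
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        self.stage_labels = list(self.stage_labels)
        _check_unique(self.stage_labels, "stage")
        if len(self.stage_labels) < 2:
            raise ValidationError("need at least 2 stages")
        known = set(self.stage_labels)
        for sample, stage in self.assignment.items():
            if stage not in known:
                raise ValidationError(f"sample {sample!r} assigned to unknown stage {stage!r}")
        for stage, count in self.counts.items():
            if count < 2:
                raise ValidationError(f"stage {stage!r} has {count} sample(s); need >= 2")

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    @property
    def counts(self) -> dict[str, int]:
        c = {s: 0 for s in self.stage_labels}
        for stage in self.assignment.values():
            c[stage] += 1
        return c

    def samples_in(self, stage: str) -> list[str]:
        return [s for s, st in self.assignment.items() if st == stage]

    def sample_indices(self, expr: ExpressionMatrix) -> dict[str, np.ndarray]:
        """Column indices of each stage's samples in ``expr``."""
        col = {s: i for i, s in enumerate(expr.sample_ids)}
        out = {}
        for stage in self.stage_labels:
            out[stage] = np.array([col[s] for s in self.samples_in(stage) if s in col], dtype=int)
        return out


@dataclass
class BackgroundNetwork:
    """Static weighted undirected interaction network (adjacency B).

    The adjacency is symmetric, non-negative with zero diagonal, and weights
    lie in [0, 1] (confidence scores). Isolated nodes are allowed; they are
    handled downstream by the dangling-column teleportation policy.
    """

    gene_ids: list[str]
    adjacency: sp.spmatrix

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        _check_unique(self.gene_ids, "gene")
        A = sp.csr_matrix(self.adjacency, dtype=float)
        n = len(self.gene_ids)
        if A.shape != (n, n):
            raise ValidationError(f"adjacency shape {A.shape} does not match {n} genes")
        if A.nnz and (A.data < 0).any():
            raise ValidationError("negative edge weight in background network")
        if A.nnz and (A.data > 1 + 1e-12).any():
            raise ValidationError("edge weight above 1 in background network")
        if np.abs(A.diagonal()).max(initial=0.0) > 0:
            raise ValidationError("background adjacency must have a zero diagonal")
        asym = abs(A - A.T)
        if asym.nnz and asym.max() > 1e-9:
            raise ValidationError("background adjacency must be symmetric")
        self.adjacency = A

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset_genes(self, genes: list[str]) -> "BackgroundNetwork":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = np.array([index[g] for g in genes], dtype=int)
        sub = self.adjacency[rows, :][:, rows]
        return BackgroundNetwork(list(genes), sub)


@dataclass
class GeneAnnotation:
    """Genomic coordinates per gene (chromosome, start, end in base pairs)."""

    table: pd.DataFrame  # index: gene symbol; columns: chrom, start, end

    def __post_init__(self) -> None:
        t = self.table
        missing = {"chrom", "start", "end"} - set(t.columns)
        if missing:
            raise ValidationError(f"gene annotation missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate gene in annotation: {dup!r}")
        if (t["start"] < 0).any() or (t["end"] < 0).any():
            raise ValidationError("negative genomic coordinate")
        bad = t.index[t["start"] > t["end"]]
        if len(bad):
            raise ValidationError(f"start > end for gene {bad[0]!r}")
        self.table = t

    def midpoints(self) -> pd.Series:
        return (self.table["start"] + self.table["end"]) / 2.0

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index


@dataclass
class GeneSet:
    """Named set of gene symbols (test sets, exclusion lists, modules)."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))


def align_universe(
    expr: ExpressionMatrix, network: BackgroundNetwork
) -> tuple[ExpressionMatrix, BackgroundNetwork]:
    """Restrict both inputs to their common gene set.

    Every network node needs an activity probability, so the working
    universe is the intersection of the expression and network gene sets,
    ordered by the network's node order. Dropped genes are counted and
    logged.
    """
    expr_genes = set(expr.gene_ids)
    common = [g for g in network.gene_ids if g in expr_genes]
    if len(common) < 2:
        raise ValidationError(
            f"gene universes barely overlap: only {len(common)} shared gene(s)"
        )
    dropped = (len(expr.gene_ids) - len(common)) + (len(network.gene_ids) - len(common))
    if dropped:
        logger.info(
            "gene-universe alignment: %d shared genes; dropped %d expression-only, "
            "%d network-only",
            len(common),
            len(expr.gene_ids) - len(common),
            len(network.gene_ids) - len(common),
        )
    return expr.subset_genes(common), network.subset_genes(common)
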