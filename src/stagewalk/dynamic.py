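"""Stage-wise dynamic network construction via the k-sigma activity model.

Each gene gets per-gene activity thresholds

    Th_k = mean + k * sigma * (1 - 1/(1 + sigma^2)),   k = 1, 2, 3,

where mean and sigma are the across-sample mean and unbiased standard
deviation of its expression. The damping factor ``1 - 1/(1 + sigma^2)``
shrinks the thresholds of low-variance genes so that stably expressed genes
are not declared inactive by noise alone. Per sample, expression is mapped
to an active probability in {0, 0.68, 0.95, 0.99} by which threshold band it
falls in; the static adjacency is reweighted per sample by the activity of
both endpoints and averaged within each stage to give the stage network
A[s].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import BackgroundNetwork, ExpressionMatrix, StagePartition, ValidationError

#: band constants of the k-sigma activity model (exact decimal literals)
ACTIVITY_LEVELS = (0.0, 0.68, 0.95, 0.99)


@dataclass
class GeneActivityStats:
    """Per-gene mean, unbiased sd and the three activity thresholds."""

    gene_ids: list[str]
    mean: np.ndarray
    sigma: np.ndarray
    thresholds: np.ndarray  # shape (3, N): rows are Th1, Th2, Th3

    def __post_init__(self) -> None:
        if (self.sigma < 0).any():
            raise ValidationError("sigma must be non-negative")
        if self.thresholds.shape != (3, len(self.gene_ids)):
            raise ValidationError("thresholds must have shape (3, N)")


@dataclass
class SampleNetwork:
    """One patient sample's reweighted interaction network Am'."""

    sample_id: str
    adjacency: sp.spmatrix


@dataclass
class StageNetwork:
    """Dynamic network A[s] of one disease stage (mean of its sample networks)."""

    stage: str
    adjacency: sp.spmatrix


def gene_stats(expr: ExpressionMatrix) -> GeneActivityStats:
    """Compute per-gene activity statistics over all M samples jointly.

    The mean and the unbiased (denominator M-1) standard deviation are taken
    over the full sample set, not per stage, so thresholds are comparable
    across stages. For a constant gene (sigma = 0) all three thresholds
    collapse to the mean.
    """
    if expr.n_samples < 2:
        raise ValidationError("need at least 2 samples for an unbiased variance")
    mean = expr.values.mean(axis=1)
    sigma = expr.values.std(axis=1, ddof=1)
    damp = 1.0 - 1.0 / (1.0 + sigma**2)
    ks = np.arange(1, 4)[:, None]
    thresholds = mean[None, :] + ks * sigma[None, :] * damp[None, :]
    return GeneActivityStats(list(expr.gene_ids), mean, sigma, thresholds)


def active_probabilities(expr: ExpressionMatrix, stats: GeneActivityStats) -> np.ndarray:
    """Map expression values to the four activity bands.

    Bands are half-open with ``>=`` on the lower edge:
    value >= Th3 -> 0.99; [Th2, Th3) -> 0.95; [Th1, Th2) -> 0.68; < Th1 -> 0.

    Returns an N x M matrix whose entries are drawn from
    :data:`ACTIVITY_LEVELS`.
    """
    if stats.gene_ids != expr.gene_ids:
        raise ValidationError("stats were computed for a different gene set")
    th1, th2, th3 = (stats.thresholds[k][:, None] for k in range(3))
    v = expr.values
    ap = np.zeros_like(v)
    ap[v >= th1] = ACTIVITY_LEVELS[1]
    ap[v >= th2] = ACTIVITY_LEVELS[2]
    ap[v >= th3] = ACTIVITY_LEVELS[3]
    return ap


def reweight_sample(
    background: BackgroundNetwork, ap_m: np.ndarray, sample_id: str = ""
) -> SampleNetwork:
    """Reweight the static adjacency by endpoint activities.

    ``Am'[i, j] = ap_m[i] * Am[i, j] * ap_m[j]`` (two-sided broadcasting
    product), which preserves symmetry and never increases an edge weight.
    """
    ap_m = np.asarray(ap_m, dtype=float)
    if ap_m.shape != (background.n_genes,):
        raise ValidationError(
            f"activity vector length {ap_m.shape} does not match {background.n_genes} genes"
        )
    d = sp.diags(ap_m)
    return SampleNetwork(sample_id, (d @ background.adjacency @ d).tocsr())


def stage_adjacency(sample_networks: list[SampleNetwork], stage: str = "") -> StageNetwork:
    """Entrywise mean of a stage's reweighted sample adjacencies."""
    if not sample_networks:
        raise ValidationError("stage has no sample networks")
    total = sample_networks[0].adjacency.copy()
    for net in sample_networks[1:]:
        total = total + net.adjacency
    return StageNetwork(stage, (total / len(sample_networks)).tocsr())


def build_dynamic_networks(
    expr: ExpressionMatrix,
    stages: StagePartition,
    background: BackgroundNetwork,
) -> list[StageNetwork]:
    """Build the S stage networks in temporal order.

    Expression and network must already share the same gene universe in the
    same order (see :func:`stagewalk.containers.align_universe`). Activity
    statistics are computed once over all samples; each sample's network is
    the activity-reweighted background and each stage network is the mean of
    its samples' networks.
    """
    if expr.gene_ids != background.gene_ids:
        raise ValidationError(
            "expression and background gene universes differ; align them first"
        )
    stats = gene_stats(expr)
    ap = active_probabilities(expr, stats)
    indices = stages.sample_indices(expr)
    out = []
    for stage in stages.stage_labels:
        cols = indices[stage]
        if cols.size == 0:
            raise ValidationError(f"stage {stage!r} has no samples in the expression matrix")
        nets = [
            reweight_sample(background, ap[:, m], expr.sample_ids[m]) for m in cols
        ]
        out.append(stage_adjacency(nets, stage))
    return out


def write_stage_network(stage_net: StageNetwork, gene_ids: list[str], path) -> None:
    """Dump one stage adjacency as a TSV weighted edge list for inspection."""
    coo = sp.triu(stage_net.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write(f"# stage: {stage_net.stage}\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{gene_ids[i]}\t{gene_ids[j]}\t{float(w)!r}\n")
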