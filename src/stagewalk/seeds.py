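"""Restart-vector construction from stage-wise differential expression.

For each stage the samples of that stage are compared against all remaining
samples with a two-sample statistic (Welch's t by default); the absolute
statistic per gene is the stage's seed score. The background layer is
seeded with Smean, the arithmetic mean of the S stage score vectors. The
stacked vector (Smean, stage 1, ..., stage S) is divided by its grand total
so the restart distribution PRS sums to 1; the walk consumes only relative
magnitudes, so any positively scaled statistic yields the same PRS.

The score function is pluggable: pass ``stat=callable`` with signature
``(in_group: ndarray, out_group: ndarray) -> ndarray`` returning one signed
statistic per gene (rows), e.g. to drop in moderated-t scores computed
externally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, StagePartition, ValidationError


def welch_t(in_group: np.ndarray, out_group: np.ndarray) -> np.ndarray:
    """Welch's two-sample t-statistic per gene (rows), unequal variances.

    Genes whose pooled variance term is zero get statistic 0 rather than
    inf/NaN: with no within-group variability the comparison carries no
    usable evidence for a relative-magnitude seed.
    """
    n1, n2 = in_group.shape[1], out_group.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 samples for a t-statistic")
    m1 = in_group.mean(axis=1)
    m2 = out_group.mean(axis=1)
    v1 = in_group.var(axis=1, ddof=1)
    v2 = out_group.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = np.zeros_like(m1)
    ok = se2 > 0
    t[ok] = (m1[ok] - m2[ok]) / np.sqrt(se2[ok])
    return t


def stage_differential_scores(
    expr: ExpressionMatrix,
    stages: StagePartition,
    stat: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_t,
) -> pd.DataFrame:
    """Absolute one-vs-rest differential statistic per gene and stage.

    Returns a genes x stages DataFrame of |statistic| values, columns in
    temporal stage order.
    """
    indices = stages.sample_indices(expr)
    all_cols = np.arange(expr.n_samples)
    out = {}
    for stage in stages.stage_labels:
        cols = indices[stage]
        rest = np.setdiff1d(all_cols, cols)
        if cols.size < 2 or rest.size < 2:
            raise ValidationError(
                f"stage {stage!r} or its complement has < 2 samples; "
                "differential scores undefined"
            )
        out[stage] = np.abs(stat(expr.values[:, cols], expr.values[:, rest]))
    return pd.DataFrame(out, index=expr.gene_ids)


def background_seed(stage_scores: pd.DataFrame) -> pd.Series:
    """Smean: entrywise arithmetic mean of the stage score vectors."""
    if stage_scores.shape[1] < 1:
        raise ValidationError("need at least one stage score vector")
    return stage_scores.mean(axis=1)


@dataclass
class RestartVector:
    """Normalized restart distribution over the multilayer node set.

    ``vector`` follows the multilayer layout: background block first (in
    ``full`` mode), then stage blocks in temporal order.
    """

    vector: np.ndarray
    gene_ids: list[str]
    mode: str
    n_stages: int
    stage_scores: pd.DataFrame | None = None
    smean: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.vector < 0).any():
            raise ValidationError("restart vector must be non-negative")
        if abs(self.vector.sum() - 1.0) > 1e-12:
            raise ValidationError("restart vector must sum to 1")


def assemble_restart(
    stage_scores: pd.DataFrame,
    smean: pd.Series | None = None,
    mode: str = "full",
) -> RestartVector:
    """Stack and normalize seed scores into the restart distribution PRS.

    ``full``: (Smean, stage 1..S) stacked then divided by the grand total;
    ``static_only``: normalized Smean alone; ``dynamic_only``: stage vectors
    only. All-zero scores are an error: there is no seed information to
    restart to.
    """
    if smean is None:
        smean = background_seed(stage_scores)
    genes = list(stage_scores.index)
    if list(smean.index) != genes:
        raise ValidationError("smean index does not match stage score index")
    S = stage_scores.shape[1]
    if mode == "full":
        parts = [smean.to_numpy()] + [stage_scores[c].to_numpy() for c in stage_scores.columns]
    elif mode == "static_only":
        parts = [smean.to_numpy()]
    elif mode == "dynamic_only":
        parts = [stage_scores[c].to_numpy() for c in stage_scores.columns]
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    stacked = np.concatenate(parts)
    if (stacked < 0).any():
        raise ValidationError("seed scores must be non-negative (use absolute statistics)")
    total = stacked.sum()
    if total <= 0:
        raise ValidationError("all seed scores are zero; no restart information")
    return RestartVector(
        vector=stacked / total,
        gene_ids=genes,
        mode=mode,
        n_stages=S,
        stage_scores=stage_scores,
        smean=smean,
        meta={"stage_labels": list(stage_scores.columns)},
    )
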