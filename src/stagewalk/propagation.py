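"""Random walk with restart on the (multilayer) transition matrix.

Iterates ``P_{t+1} = (1 - gamma) * TLc @ P_t + gamma * PRS`` from
``P_0 = PRS`` until the L1 difference between successive iterates drops
below ``tol``. With a column-stochastic TLc and a normalized PRS every
iterate is a probability vector, and the iteration converges geometrically
at rate ``1 - gamma`` to the unique fixed point
``gamma * (I - (1 - gamma) TLc)^{-1} PRS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .containers import GeneSet, ValidationError
from .multilayer import MultilayerNetwork


class ConvergenceError(RuntimeError):
    """Propagation did not reach the tolerance within ``max_iter`` steps."""


@dataclass
class PropagationState:
    """Converged walk state and bookkeeping."""

    steady_state: np.ndarray
    restart: np.ndarray
    gamma: float
    n_iter: int
    residual: float
    tol: float


@dataclass
class RankedGeneList:
    """Genes ordered by descending score; ties broken by ascending symbol."""

    genes: list[str]
    scores: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != self.scores.size:
            raise ValidationError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranking contains duplicate genes")
        if self.scores.size > 1 and (np.diff(self.scores) > 1e-15).any():
            raise ValidationError("ranking scores must be non-increasing")

    def top(self, k: int) -> list[str]:
        return self.genes[:k]

    def __len__(self) -> int:
        return len(self.genes)


def propagate(
    tlc: sp.spmatrix,
    prs: np.ndarray,
    gamma: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PropagationState:
    """Run the restart walk to convergence.

    ``gamma`` is the restart probability in (0, 1]; at ``gamma = 1`` the
    fixed point is PRS itself and the walk stops after one step.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValidationError(f"gamma must be in (0, 1], got {gamma}")
    prs = np.asarray(prs, dtype=float).ravel()
    if tlc.shape[0] != tlc.shape[1] or tlc.shape[0] != prs.size:
        raise ValidationError(
            f"transition shape {tlc.shape} incompatible with restart length {prs.size}"
        )
    if abs(prs.sum() - 1.0) > 1e-9:
        raise ValidationError("restart vector must sum to 1")
    tlc = sp.csr_matrix(tlc)
    p = prs.copy()
    for t in range(1, max_iter + 1):
        p_next = (1.0 - gamma) * (tlc @ p) + gamma * prs
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return PropagationState(
                steady_state=p, restart=prs, gamma=gamma, n_iter=t, residual=residual, tol=tol
            )
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations (final L1 residual {residual:.3e})"
    )


def background_scores(
    state: PropagationState,
    network: MultilayerNetwork,
    aggregate_stages: bool = False,
) -> np.ndarray:
    """Extract the per-gene score vector from the steady state.

    In ``full`` and ``static_only`` modes this is the background block (the
    first N entries). ``dynamic_only`` has no background layer; with
    ``aggregate_stages=True`` the per-gene mean over the S stage layers is
    returned instead, otherwise it is an error.
    """
    n = network.n_genes
    if state.steady_state.size != network.n_nodes:
        raise ValidationError("propagation state does not match network layout")
    if network.has_background:
        return state.steady_state[:n]
    if not aggregate_stages:
        raise ValidationError(
            "dynamic_only mode has no background layer; "
            "pass aggregate_stages=True for the per-gene mean over stage layers"
        )
    return state.steady_state.reshape(network.n_stages, n).mean(axis=0)


def rank_genes(
    scores: np.ndarray,
    gene_ids: list[str],
    exclusions: list[GeneSet] | None = None,
    meta: dict | None = None,
) -> RankedGeneList:
    """Sort genes by descending score with a deterministic tie rule.

    Genes in any exclusion list (known disease genes, housekeeping genes)
    are removed first; ties are broken by ascending gene symbol so repeated
    runs are byte-identical.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size != len(gene_ids):
        raise ValidationError("scores and gene_ids length mismatch")
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    excluded: set[str] = set()
    for gs in exclusions or []:
        excluded |= set(gs.members)
    pairs = [(g, s) for g, s in zip(gene_ids, scores) if g not in excluded]
    if not pairs:
        raise ValidationError("no genes left to rank after exclusions")
    pairs.sort(key=lambda gs: (-gs[1], gs[0]))
    return RankedGeneList(
        genes=[g for g, _ in pairs],
        scores=np.array([s for _, s in pairs]),
        meta=dict(meta or {}),
    )
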