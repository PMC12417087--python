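"""Background-temporal multilayer network assembly.

The multilayer graph has L = S + 1 layers over the same N genes: one static
background layer B and S stage layers A[1..S]. The temporal part couples
only adjacent stages (block-tridiagonal):

    TS = blocktridiag( (1-mu) * A[s]  on the diagonal,
                        mu * I        between adjacent stages )

and the full transition matrix couples the background layer to every stage
layer through each gene's counterpart nodes:

    TL = [ (1-delta) * B     delta * J^T ]
         [ delta * J         TS          ]      with J = (1/S) * e (x) I,

where e is the all-ones S-vector, so the background column spreads weight
1/S to each stage counterpart. The walk operates on the column-normalized
TLc; all-zero (dangling) columns are replaced by the restart distribution,
the standard teleportation fix, so probability is conserved.

Vector layout: background block first, then stages in temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .containers import BackgroundNetwork, ValidationError
from .dynamic import StageNetwork

MODES = ("full", "static_only", "dynamic_only")


@dataclass
class MultilayerNetwork:
    """Assembled multilayer transition structure.

    ``transition`` is the un-normalized transition matrix for the chosen
    mode: the full NL x NL matrix TL (``full``), the background adjacency B
    (``static_only``), or the temporal block TS alone (``dynamic_only``).
    """

    gene_ids: list[str]
    n_stages: int
    delta: float
    mu: float
    mode: str
    transition: sp.spmatrix
    meta: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_layers(self) -> int:
        return {"full": self.n_stages + 1, "static_only": 1, "dynamic_only": self.n_stages}[
            self.mode
        ]

    @property
    def n_nodes(self) -> int:
        return self.n_layers * self.n_genes

    @property
    def has_background(self) -> bool:
        return self.mode in ("full", "static_only")


def temporal_transition(stage_networks: list[StageNetwork], mu: float) -> sp.spmatrix:
    """Block-tridiagonal transition matrix of the S-layer temporal network.

    Diagonal blocks are ``(1 - mu) * A[s]``; the blocks between temporally
    adjacent stages are ``mu * I``; all other blocks are zero, so a walker
    can only hop one stage forward or backward per step.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValidationError(f"mu must be in [0, 1], got {mu}")
    if not stage_networks:
        raise ValidationError("need at least one stage network")
    S = len(stage_networks)
    n = stage_networks[0].adjacency.shape[0]
    eye = sp.identity(n, format="csr") * mu
    blocks = [[None] * S for _ in range(S)]
    for s, net in enumerate(stage_networks):
        if net.adjacency.shape != (n, n):
            raise ValidationError("stage networks have inconsistent sizes")
        blocks[s][s] = (1.0 - mu) * net.adjacency
        if s + 1 < S:
            blocks[s][s + 1] = eye
            blocks[s + 1][s] = eye
    return sp.bmat(blocks, format="csr")


def full_transition(
    background: BackgroundNetwork,
    ts: sp.spmatrix,
    delta: float,
    n_stages: int,
    scale_dynamic_block: bool = False,
) -> sp.spmatrix:
    """Assemble the full multilayer transition matrix TL.

    Layout ``[[(1-delta) B, delta J^T], [delta J, TS]]`` with
    ``J = (1/S) e (x) I``. By default the TS block enters as-is and column
    normalization absorbs the resulting non-uniform column sums;
    ``scale_dynamic_block=True`` scales it by ``(1 - delta)`` instead
    (off-by-default variant).
    """
    if not 0.0 <= delta <= 1.0:
        raise ValidationError(f"delta must be in [0, 1], got {delta}")
    n = background.n_genes
    if ts.shape != (n * n_stages, n * n_stages):
        raise ValidationError(
            f"temporal block shape {ts.shape} incompatible with N={n}, S={n_stages}"
        )
    eye = sp.identity(n, format="csr")
    j_blocks = sp.vstack([eye] * n_stages, format="csr") * (delta / n_stages)
    ts_block = (1.0 - delta) * ts if scale_dynamic_block else ts
    return sp.bmat(
        [
            [(1.0 - delta) * background.adjacency, j_blocks.T],
            [j_blocks, ts_block],
        ],
        format="csr",
    )


def column_normalize(matrix: sp.spmatrix, restart: np.ndarray | None = None) -> sp.spmatrix:
    """Column-normalize a non-negative matrix into a column-stochastic one.

    Zero-sum (dangling) columns are replaced by ``restart`` (the restart
    distribution; uniform if not given), so every column sums to exactly 1
    and the walk conserves probability.
    """
    A = sp.csc_matrix(matrix, dtype=float)
    if A.nnz and A.data.min() < 0:
        raise ValidationError("transition matrix must be non-negative")
    n = A.shape[0]
    colsum = np.asarray(A.sum(axis=0)).ravel()
    dangling = colsum <= 0
    scale = np.ones_like(colsum)
    scale[~dangling] = 1.0 / colsum[~dangling]
    A = A @ sp.diags(scale)
    if dangling.any():
        if restart is None:
            restart = np.full(n, 1.0 / n)
        restart = np.asarray(restart, dtype=float).ravel()
        if restart.shape != (n,):
            raise ValidationError("restart vector length does not match matrix size")
        cols = np.flatnonzero(dangling)
        # dangling columns are all-zero, so adding the restart column there
        # sets them exactly
        patch = sp.coo_matrix(
            (
                np.tile(restart, cols.size),
                (np.tile(np.arange(n), cols.size), np.repeat(cols, n)),
            ),
            shape=A.shape,
        )
        A = (A + patch.tocsc()).tocsc()
    A.eliminate_zeros()
    return A


def assemble(
    background: BackgroundNetwork,
    stage_networks: list[StageNetwork],
    delta: float = 0.5,
    mu: float = 0.5,
    mode: str = "full",
    scale_dynamic_block: bool = False,
) -> MultilayerNetwork:
    """Build the multilayer network for the requested mode.

    ``full`` couples background and stage layers; ``static_only`` is the
    classical single-network random-walk substrate over B; ``dynamic_only``
    uses the temporal block TS alone (the two ablation modes).
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    S = len(stage_networks)
    if mode == "static_only":
        transition = background.adjacency.copy()
    elif mode == "dynamic_only":
        if S == 0:
            raise ValidationError("dynamic_only mode requires at least one stage network")
        transition = temporal_transition(stage_networks, mu)
    else:
        if S == 0:
            raise ValidationError("full mode requires at least one stage network")
        ts = temporal_transition(stage_networks, mu)
        transition = full_transition(background, ts, delta, S, scale_dynamic_block)
    return MultilayerNetwork(
        gene_ids=list(background.gene_ids),
        n_stages=S,
        delta=delta,
        mu=mu,
        mode=mode,
        transition=transition,
        meta={"stage_labels": [net.stage for net in stage_networks]},
    )
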