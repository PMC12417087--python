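"""End-to-end orchestration: inputs -> dynamic networks -> multilayer walk -> ranking.

``rank_genes_pipeline`` is the in-memory pipeline used by tests and the
acceptance script; ``run_rank`` / ``run_evaluate`` are the file-level
entry points behind the command-line interface.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .containers import (
    BackgroundNetwork,
    ExpressionMatrix,
    GeneSet,
    StagePartition,
    align_universe,
)
from .dynamic import build_dynamic_networks
from .evaluation import DEFAULT_KS, EvaluationReport, evaluate_ranking, write_report
from .io import (
    read_edge_list,
    read_expression,
    read_gene_coordinates,
    read_gene_list,
    read_ranking,
    read_stage_annotation,
    write_ranking,
)
from .multilayer import assemble, column_normalize
from .propagation import RankedGeneList, background_scores, propagate, rank_genes
from .seeds import assemble_restart, stage_differential_scores

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File paths and parameters for one ranking/evaluation run."""

    expr: str | None = None
    stages: str | None = None
    network: str | None = None
    score_divisor: float = 1.0
    delta: float = 0.5
    mu: float = 0.5
    gamma: float = 0.1
    tol: float = 1e-6
    max_iter: int = 1000
    mode: str = "full"
    exclude: list[str] = field(default_factory=list)
    # evaluation
    ranking: str | None = None
    disease_genes: str | None = None
    scheme: str = "WG"
    coords: str | None = None
    n_controls: int = 99
    seed: int | None = None
    ks: tuple[int, ...] = DEFAULT_KS
    out: str | None = None


def rank_genes_pipeline(
    expr: ExpressionMatrix,
    stages: StagePartition,
    network: BackgroundNetwork,
    delta: float = 0.5,
    mu: float = 0.5,
    gamma: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 1000,
    mode: str = "full",
    exclusions: list[GeneSet] | None = None,
) -> RankedGeneList:
    """Run the full scoring pipeline on in-memory inputs.

    Aligns gene universes, builds the stage networks and the multilayer
    transition matrix for ``mode``, seeds the restart walk with absolute
    stage-wise differential statistics, and ranks genes by their
    steady-state background-layer score.
    """
    expr, network = align_universe(expr, network)
    stage_scores = stage_differential_scores(expr, stages)
    restart = assemble_restart(stage_scores, mode=mode)
    if mode == "static_only":
        net = assemble(network, [], delta=delta, mu=mu, mode=mode)
    else:
        stage_nets = build_dynamic_networks(expr, stages, network)
        net = assemble(network, stage_nets, delta=delta, mu=mu, mode=mode)
    tlc = column_normalize(net.transition, restart.vector)
    state = propagate(tlc, restart.vector, gamma=gamma, tol=tol, max_iter=max_iter)
    scores = background_scores(state, net, aggregate_stages=(mode == "dynamic_only"))
    meta = {
        "mode": mode,
        "delta": delta,
        "mu": mu,
        "gamma": gamma,
        "tol": tol,
        "n_genes": network.n_genes,
        "n_stages": stages.n_stages,
        "n_iter": state.n_iter,
        "residual": state.residual,
    }
    return rank_genes(scores, network.gene_ids, exclusions=exclusions, meta=meta)


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_rank(config: RunConfig) -> Path:
    """File-level ranking run; writes the ranking with a provenance header."""
    for name in ("expr", "stages", "network", "out"):
        if getattr(config, name) is None:
            raise ValueError(f"rank: config field {name!r} is required")
    try:
        expr = read_expression(config.expr)
        stages = read_stage_annotation(config.stages, expr)
        network = read_edge_list(config.network, score_divisor=config.score_divisor)
    except Exception as exc:
        raise RuntimeError(f"[io] {exc}") from exc
    exclusions = [read_gene_list(p) for p in config.exclude]
    ranking = rank_genes_pipeline(
        expr,
        stages,
        network,
        delta=config.delta,
        mu=config.mu,
        gamma=config.gamma,
        tol=config.tol,
        max_iter=config.max_iter,
        mode=config.mode,
        exclusions=exclusions,
    )
    header = {
        "stagewalk_version": __version__,
        **{k: v for k, v in sorted(ranking.meta.items())},
        "expr_sha256": _checksum(config.expr),
        "stages_sha256": _checksum(config.stages),
        "network_sha256": _checksum(config.network),
    }
    write_ranking(ranking, config.out, header=header)
    logger.info("wrote ranking of %d genes to %s", len(ranking), config.out)
    return Path(config.out)


def run_evaluate(config: RunConfig) -> EvaluationReport:
    """File-level evaluation run; writes the metric report as TSV."""
    for name in ("ranking", "disease_genes", "out"):
        if getattr(config, name) is None:
            raise ValueError(f"evaluate: config field {name!r} is required")
    if config.scheme == "ALI" and config.coords is None:
        raise ValueError("evaluate: ALI scheme requires a coordinate table (coords)")
    ranking = read_ranking(config.ranking)
    test = read_gene_list(config.disease_genes)
    annotation = read_gene_coordinates(config.coords) if config.coords else None
    report = evaluate_ranking(
        ranking,
        test,
        scheme=config.scheme,
        annotation=annotation,
        n_controls=config.n_controls,
        seed=config.seed,
        ks=config.ks,
    )
    write_report(report, config.out)
    logger.info("wrote %s-scheme report to %s", config.scheme, config.out)
    return report
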