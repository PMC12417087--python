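"""Synthetic staged-expression benchmark generator.

Emulates the data regime the method assumes: a sparse, roughly scale-free
interaction network; a small planted disease module whose genes sit close
together in the network; and a staged expression matrix where module genes
shift progressively upward across disease stages while all other genes
fluctuate around their baseline. Expression is on a log-like additive scale
with Gaussian noise, so the activity-band structure of the k-sigma model is
analytically controllable.

Default configuration: 500 genes (preferential attachment, 3 edges/node),
a 20-gene connected module, 3 stages with 8 samples each, per-stage mean
shifts (0.5, 1.5, 3.0) in units of the noise standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    BackgroundNetwork,
    ExpressionMatrix,
    GeneAnnotation,
    GeneSet,
    StagePartition,
    ValidationError,
)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic benchmark.

    ``effect_schedule`` gives the per-stage mean shift of module genes in
    units of ``noise_sd``; it must be non-decreasing (disease progression).
    ``module_adjacency`` is the fraction of module genes grown as a
    connected network neighborhood; the rest are sampled at random.
    """

    n_genes: int = 500
    network_model: str = "preferential-attachment"  # or "two-cluster"
    edges_per_node: int = 3
    module_size: int = 20
    module_adjacency: float = 1.0
    n_stages: int = 3
    samples_per_stage: int = 8
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    effect_schedule: tuple[float, ...] = (0.5, 1.5, 3.0)
    noise_sd: float = 1.0
    inter_cluster_edges: int = 1
    inter_cluster_weight: float = 1e-3
    seed: int = 0
    stage_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.module_size >= self.n_genes:
            raise ValidationError("module_size must be smaller than n_genes")
        if self.baseline_sd <= 0 or self.noise_sd <= 0:
            raise ValidationError("standard deviations must be positive")
        if len(self.effect_schedule) != self.n_stages:
            raise ValidationError("effect_schedule length must equal n_stages")
        if any(b < a for a, b in zip(self.effect_schedule, self.effect_schedule[1:])):
            raise ValidationError("effect_schedule must be non-decreasing")
        if not 0.0 <= self.module_adjacency <= 1.0:
            raise ValidationError("module_adjacency must be in [0, 1]")
        if self.samples_per_stage < 2:
            raise ValidationError("need >= 2 samples per stage")

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def stage_labels(self) -> list[str]:
        return [f"{self.stage_prefix}{s + 1}" for s in range(self.n_stages)]


def _graph(cfg: SyntheticConfig, rng: np.random.Generator) -> nx.Graph:
    gseed = int(rng.integers(2**31 - 1))
    if cfg.network_model == "preferential-attachment":
        g = nx.barabasi_albert_graph(cfg.n_genes, cfg.edges_per_node, seed=gseed)
    elif cfg.network_model == "two-cluster":
        half = cfg.n_genes // 2
        g1 = nx.barabasi_albert_graph(half, cfg.edges_per_node, seed=gseed)
        g2 = nx.barabasi_albert_graph(cfg.n_genes - half, cfg.edges_per_node, seed=gseed + 1)
        g = nx.disjoint_union(g1, g2)
        for _ in range(cfg.inter_cluster_edges):
            u = int(rng.integers(half))
            v = half + int(rng.integers(cfg.n_genes - half))
            g.add_edge(u, v, bridge=True)
    else:
        raise ValidationError(f"unknown network model {cfg.network_model!r}")
    if g.number_of_edges() == 0:
        raise ValidationError("network model produced no edges")
    return g


def generate_background(cfg: SyntheticConfig) -> tuple[BackgroundNetwork, GeneAnnotation]:
    """Sample the background network and synthetic gene coordinates.

    Edge weights are uniform in (0, 1] (bridge edges in the two-cluster
    model get ``inter_cluster_weight``). Coordinates place genes
    sequentially on two synthetic chromosomes so the ALI scheme has
    non-trivial neighborhoods.
    """
    rng = np.random.default_rng(cfg.seed)
    g = _graph(cfg, rng)
    genes = cfg.gene_ids
    rows, cols, data = [], [], []
    for u, v, attrs in sorted(g.edges(data=True)):
        w = cfg.inter_cluster_weight if attrs.get("bridge") else float(1.0 - rng.random())
        rows += [u, v]
        cols += [v, u]
        data += [w, w]
    adjacency = sp.coo_matrix((data, (rows, cols)), shape=(cfg.n_genes, cfg.n_genes)).tocsr()
    network = BackgroundNetwork(genes, adjacency)

    per_chrom = (cfg.n_genes + 1) // 2
    chrom = ["chr1" if i < per_chrom else "chr2" for i in range(cfg.n_genes)]
    start = [(i % per_chrom) * 10_000 + 1 for i in range(cfg.n_genes)]
    table = pd.DataFrame(
        {"chrom": chrom, "start": start, "end": [s + 999 for s in start]},
        index=pd.Index(genes, name="gene"),
    )
    return network, GeneAnnotation(table)


def plant_module(cfg: SyntheticConfig, network: BackgroundNetwork) -> GeneSet:
    """Choose the disease module, preferentially as a connected neighborhood.

    Grows a connected region from a uniformly chosen start node to cover
    ``module_adjacency * module_size`` genes; any remainder is drawn
    uniformly from the rest of the network, so the module's network
    coherence is tunable.

    Growth samples the next member from the current frontier with
    probability proportional to 1/degree. A frontier node is reached
    through a number of edges proportional to its degree (the friendship
    paradox), so plain breadth-first growth yields hub-enriched modules;
    random-walk-with-restart scores carry a known degree bias, and a
    hub-enriched module would be partially recoverable even with no
    expression signal. The inverse-degree weight cancels the reach bias so
    the planted module is connected but degree-typical.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n_adj = int(round(cfg.module_adjacency * cfg.module_size))
    g = nx.from_scipy_sparse_array(network.adjacency)
    degree = dict(g.degree())
    start = int(rng.integers(cfg.n_genes))
    picked: list[int] = []
    if n_adj:
        picked.append(start)
        frontier = set(g.neighbors(start))
        while frontier and len(picked) < n_adj:
            cand = sorted(frontier)
            w = np.array([1.0 / degree[c] for c in cand])
            node = int(rng.choice(cand, p=w / w.sum()))
            picked.append(node)
            frontier.discard(node)
            frontier |= set(g.neighbors(node)) - set(picked)
        if len(picked) < n_adj:  # disconnected component smaller than module
            rest = [i for i in range(cfg.n_genes) if i not in set(picked)]
            picked += list(rng.choice(rest, size=n_adj - len(picked), replace=False))
    remaining = [i for i in range(cfg.n_genes) if i not in set(picked)]
    extra = cfg.module_size - len(picked)
    if extra > 0:
        picked += list(rng.choice(remaining, size=extra, replace=False))
    genes = network.gene_ids
    return GeneSet("planted_module", frozenset(genes[i] for i in picked))


def generate_expression(
    cfg: SyntheticConfig, network: BackgroundNetwork, module: GeneSet
) -> tuple[ExpressionMatrix, StagePartition]:
    """Simulate the staged expression matrix with the planted signal.

    Each gene gets a fixed baseline ~ Normal(baseline_mean, baseline_sd);
    every measurement adds Normal(0, noise_sd) noise; module genes in stage
    s are additionally shifted by ``effect_schedule[s] * noise_sd``.
    """
    if not set(module.members) <= set(network.gene_ids):
        raise ValidationError("module genes must be network genes")
    rng = np.random.default_rng(cfg.seed + 2)
    genes = network.gene_ids
    n = len(genes)
    m_total = cfg.n_stages * cfg.samples_per_stage
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n, m_total))
    in_module = np.array([g in module for g in genes])
    sample_ids, assignment = [], {}
    for s, label in enumerate(cfg.stage_labels):
        shift = cfg.effect_schedule[s] * cfg.noise_sd
        for r in range(cfg.samples_per_stage):
            col = s * cfg.samples_per_stage + r
            values[in_module, col] += shift
            sid = f"{label}_r{r + 1}"
            sample_ids.append(sid)
            assignment[sid] = label
    expr = ExpressionMatrix(genes, sample_ids, values)
    stages = StagePartition(cfg.stage_labels, assignment)
    return expr, stages


def write_dataset(cfg: SyntheticConfig, out_dir) -> dict[str, Path]:
    """Generate a full dataset and write it as plain-text files.

    Writes ``expr.tsv``, ``stages.tsv``, ``network.tsv``, ``coords.tsv``
    and ``truth.txt`` (the planted module) into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    network, annotation = generate_background(cfg)
    module = plant_module(cfg, network)
    expr, stages = generate_expression(cfg, network, module)

    paths = {name: out / fname for name, fname in [
        ("expr", "expr.tsv"),
        ("stages", "stages.tsv"),
        ("network", "network.tsv"),
        ("coords", "coords.tsv"),
        ("truth", "truth.txt"),
    ]}
    expr.to_frame().to_csv(paths["expr"], sep="\t")
    with open(paths["stages"], "w") as fh:
        for sid in expr.sample_ids:
            fh.write(f"{sid}\t{stages.assignment[sid]}\n")
    coo = sp.triu(network.adjacency, k=1).tocoo()
    with open(paths["network"], "w") as fh:
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{network.gene_ids[i]}\t{network.gene_ids[j]}\t{float(w)!r}\n")
    annotation.table.to_csv(paths["coords"], sep="\t", header=False)
    with open(paths["truth"], "w") as fh:
        for g in sorted(module.members):
            fh.write(g + "\n")
    return paths
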