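# stagewalk

Disease-gene prioritization for progressive diseases by network propagation
on a **background–temporal multilayer network**.

Most network-propagation methods rank candidate disease genes on a single
static protein–protein interaction (PPI) network, discarding how the
interactome changes as a disease progresses. For staged diseases such as the
leukemias — where expression cohorts are sampled at ordered clinical stages —
`stagewalk` builds one *dynamic* network per stage from the expression data,
couples the stage networks to the static background network in a multilayer
graph, and ranks genes by a random walk with restart seeded from stage-wise
differential expression. It is aimed at computational biologists who have a
gene × sample expression matrix with an ordered stage annotation, a weighted
PPI network (e.g. STRING), and a list of known disease genes to benchmark
against.

## Model

**Stage networks (k-sigma activity model).** For gene *g* with across-sample
mean x̄(g) and unbiased standard deviation σ(g), the activity thresholds are

    Th_k(g) = x̄(g) + k·σ(g)·(1 − 1/(1 + σ²(g))),   k = 1, 2, 3.

Per sample *m*, expression maps to an active probability AP_m(g) ∈
{0, 0.68, 0.95, 0.99} by threshold band (≥ Th₃ → 0.99, [Th₂, Th₃) → 0.95,
[Th₁, Th₂) → 0.68, < Th₁ → 0). Each sample's network reweights the static
adjacency A by both endpoints, A′_m[i,j] = AP_m(i)·A[i,j]·AP_m(j), and the
stage-s network A[s] is the mean of A′_m over the M_s samples of that stage.

**Multilayer coupling.** With S stages, the temporal block is
block-tridiagonal, TS = [(1−μ)·A[s] on the diagonal, μ·I between adjacent
stages], and the full transition matrix couples the background adjacency B
to every stage layer through each gene's counterpart nodes:

    TL = [ (1−δ)·B   δ·Jᵀ ]        J = (1/S)·e ⊗ I.
         [  δ·J      TS   ]

TL is column-normalized to TLc; all-zero columns teleport to the restart
distribution.

**Seeded walk.** Per stage, a one-vs-rest Welch t-statistic is computed per
gene; the restart vector PRS stacks the mean absolute statistic S_mean
(background layer) and the per-stage absolute statistics, normalized to
sum 1. The walk iterates P_{t+1} = (1−γ)·TLc·P_t + γ·PRS until the L1
change falls below 10⁻⁶, and genes are ranked by the background block P∞B
of the steady state. Defaults: δ = 0.5, μ = 0.5, γ = 0.1.

**Evaluation.** Rankings are scored against known disease genes under three
control-set schemes — ALI (99 nearest same-chromosome genes per test gene),
RC (99 random genes per test gene), WG (all non-test genes) — with
Top-k precision/recall (k ∈ {5, 10, 50, 100, 200}), AUROC and AUPRC.

## Worked example

Generate a synthetic benchmark (500 genes on a scale-free network, a
20-gene connected disease module whose expression shifts by 0.5/1.5/3.0
noise-sd across 3 stages of 8 samples), rank, and evaluate:

```bash
stagewalk simulate --seed 7 --out-dir demo
stagewalk rank --expr demo/expr.tsv --stages demo/stages.tsv \
    --network demo/network.tsv --out demo/ranking.tsv
stagewalk evaluate --ranking demo/ranking.tsv --disease-genes demo/truth.txt \
    --scheme WG --out demo/report.tsv
cat demo/report.tsv
```

```
scheme	WG
n_test	20
n_controls	480
top5_precision	0.0
top5_recall	0.0
top10_precision	0.0
top10_recall	0.0
top50_precision	0.12
top50_recall	0.3
top100_precision	0.17
top100_recall	0.85
top200_precision	0.1
top200_recall	1.0
auroc	0.8855208333333333
auprc	0.15689108733774312
```

AUROC 0.89 means a planted-module gene outranks a random background gene
89% of the time; top100 recall 0.85 means 17 of the 20 module genes appear
in the first 100 of the 500 ranked genes. The same data scored with
`--mode static_only` (classical single-network RWR on B seeded with S_mean)
gives AUROC 0.73 — the dynamic stage layers add signal.

The same pipeline is available as a library:

```python
from stagewalk import SyntheticConfig, generate_background, plant_module, \
    generate_expression, evaluate_ranking
from stagewalk.pipeline import rank_genes_pipeline

cfg = SyntheticConfig(seed=7)
network, coords = generate_background(cfg)
module = plant_module(cfg, network)
expr, stages = generate_expression(cfg, network, module)
ranking = rank_genes_pipeline(expr, stages, network)   # mode="full"
report = evaluate_ranking(ranking, module, scheme="WG")
print(report.auroc)
```

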