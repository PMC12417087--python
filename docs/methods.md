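# Methods

## Model and assumptions

`stagewalk` scores gene–disease association for a staged, progressive
disease by a random walk with restart (RWR) on a multilayer graph that
combines one static background PPI layer with S expression-derived stage
layers. The underlying assumptions are the usual ones of network
propagation — disease genes cluster in interaction neighborhoods, and edge
weights are (noisy) interaction confidences — plus two specific to the
staged design:

1. **Stage-wise interactome rewiring is informative.** An interaction can
   only carry flux in a given patient sample if both partners are actively
   expressed in that sample; averaging the activity-reweighted networks over
   a stage's samples gives that stage's effective interactome.
2. **Stage-specific differential expression marks disease-relevant genes.**
   The walk restarts preferentially at genes whose expression separates one
   stage from the rest, so genes that both carry differential signal and sit
   in well-connected (stage-active) neighborhoods accumulate score.

The final ranking uses only the background-layer block of the stationary
vector: the stage layers act as signal conduits, while the background layer
aggregates evidence over the whole course of the disease.

### Activity model

Activity thresholds use the damped k-sigma rule
`Th_k = mean + k·σ·(1 − 1/(1+σ²))` with the mean and the unbiased
(denominator M−1) standard deviation computed **once over all M samples**,
not per stage — the thresholds must be comparable across stages for the
stage networks to be comparable. Band boundaries are half-open with `≥` on
the lower edge of each band; the band constants 0.99/0.95/0.68/0 are stored
as exact decimal literals. A constant gene (σ = 0) has all three thresholds
equal to its mean, so all of its values land in the top band: stably
expressed genes are treated as constitutively active rather than inactive.

### Multilayer transition matrix

The temporal block TS is block-tridiagonal: interlayer identity links
connect **adjacent stages only**, so a walker moves through disease stages
in order rather than jumping arbitrarily. The background layer connects to
every stage layer with uniform weight 1/S per counterpart. The TS block
enters the full matrix unscaled (column normalization absorbs the
non-uniform column sums); the alternative of scaling it by (1−δ) is exposed
as `scale_dynamic_block=True` but is off by default. Column layout and the
restart/score vectors all order the background block first, then stages in
temporal order.

**Dangling columns** (a gene inactive in every sample of a stage, or an
isolated background gene) are replaced by the restart distribution — the
standard PageRank teleportation fix — so the transition matrix is exactly
column-stochastic and every iterate remains a probability vector.

### Seeds

The per-stage differential score is Welch's two-sample t-statistic (one
stage vs. all other samples), taken in absolute value. Variance moderation
(e.g. an empirical-Bayes moderated t) is deliberately not built in: the walk
consumes only relative score magnitudes, and the score function is pluggable
(`stage_differential_scores(..., stat=...)`) so an externally computed score
table can be dropped in unchanged. Genes with zero pooled variance score 0
rather than ±inf. The stacked vector (S_mean, stage 1…S) is normalized by
its grand total — no per-layer reweighting — which keeps S_mean on the same
scale as the stage scores.

## Parameters

| parameter | default | meaning |
|---|---|---|
| δ (delta) | 0.5 | probability of jumping between background and stage layers |
| μ (mu) | 0.5 | probability of moving between adjacent stage layers |
| γ (gamma) | 0.1 | restart probability; lower = more network smoothing |
| tol | 1e-6 | L1 convergence threshold of the walk |
| max_iter | 1000 | iteration cap (convergence failure is an error, not a warning) |
| score_divisor | 1 (CLI), 1000 for STRING | rescales raw edge scores into [0, 1] |
| n_controls | 99 | controls per test gene in the ALI/RC schemes |
| k grid | 5, 10, 50, 100, 200 | top-k evaluation depths |

The walk iterates from P₀ = PRS and stops when the **L1** difference
between successive iterates falls below `tol`; with γ = 0.1 this typically
takes 50–80 iterations. Ranking ties are broken by ascending gene symbol so
repeated runs are byte-identical. The ALI scheme measures gene distance
between interval midpoints (`(start+end)/2`), with the same symbol tie rule.

## Synthetic benchmark

The generator emulates a staged case-series design: a sparse scale-free
background network (Barabási–Albert, 3 edges/node, weights uniform in
(0, 1]) or a two-cluster variant with near-zero bridge weights; a planted
disease module of 20 genes; and 3 stages × 8 samples of expression on a
log-like additive scale — per-gene baseline ~ N(6, 1), per-measurement
noise ~ N(0, 1), and a progressive module shift of (0.5, 1.5, 3.0)·sd per
stage. These sizes keep a full multilayer instance at 2000 nodes, small
enough that the complete 10-replicate benchmark runs in seconds on one CPU.
Synthetic gene coordinates tile two chromosomes so the ALI scheme is
exercised.

**Degree-typical module placement.** The module is grown as a connected
region from a random start node, sampling each next member from the current
frontier with probability ∝ 1/degree. Plain breadth-first growth in a
scale-free graph yields hub-enriched modules (a frontier node is reached
through a number of edges proportional to its degree), and RWR scores carry
a well-known degree bias — a hub-enriched module would be partially
recoverable even with no expression signal at all, which would corrupt both
the null calibration and the interpretation of recovery results. The
inverse-degree weight cancels the reach bias exactly: with a zero effect
schedule the module's whole-genome AUROC is centred on 0.5.

**What the generator does not emulate:** microarray/RNA-seq noise models
(mean–variance coupling, batch effects), correlated co-expression outside
the module, incomplete and biased PPI coverage, module genes with mixed
up/down regulation, and copy-number or cell-composition confounding.
Passing the recovery benchmark therefore demonstrates that the machinery
propagates staged differential signal correctly — not that any particular
AUROC will be attained on real cohorts.

## Numerical and design choices

- Sparse (CSR/CSC) matrices throughout; the dense closed-form solve
  `γ(I − (1−γ)TLc)⁻¹PRS` is used only as a test oracle on small instances.
- Duplicate undirected edges collapse by maximum weight (order-independent);
  self-edges are dropped with a warning.
- The gene universe is the intersection of the expression and network gene
  sets (every network node needs an activity probability); dropped genes are
  logged. Identifiers are case-sensitive exact strings — no aliasing.
- Ranking files store scores via `repr`, so write → read round trips are
  bit-identical.
- AUROC/AUPRC are computed with scikit-learn (`roc_auc_score`,
  `average_precision_score`); the test suite cross-checks AUROC against a
  brute-force Mann–Whitney count, including ties.
- `dynamic_only` mode has no background layer; requesting background scores
  is an error unless the per-gene mean over stage layers is explicitly
  requested (`aggregate_stages=True`).

## Known limitations

- The one-vs-rest Welch t needs ≥ 2 samples per stage and ≥ 2 in the
  complement; designs with singleton stages are rejected rather than
  imputed.
- Interlayer coupling is uniform (single δ, single μ); stage-specific
  coupling strengths are out of scope.
- The walk is dense in memory per column of dangling fix: a network where
  most genes are inactive in some stage produces many teleportation columns,
  which is handled correctly but can densify TLc for very large N.
- Evaluation assumes the test set is a subset of the ranked universe; test
  genes missing from the network are silently ignored in the candidate set
  (they cannot be ranked).
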