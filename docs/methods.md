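# Methods

This note records the model, the parameter choices, the numerical
conventions, and the limits of what the synthetic benchmark can show.

## Differential-expression statistics

`compute_de_stats` uses the classical pooled-variance two-sample *t*
(tumour minus normal) on log2-scale intensities, with two-sided
p-values from the t distribution on `n1 + n2 − 2` degrees of freedom
and Benjamini–Hochberg adjustment across all genes. A moderated
(empirical-Bayes) *t* would shrink per-gene variances toward a prior;
we deliberately use the unmoderated form because the downstream node
weight only needs a dys-regulation score, and the pooled *t* has a
closed form that the tests can verify exactly. Degenerate genes:
identical values in both groups give `t = 0, p = 1`; zero within-group
variance with a mean shift gives a signed-infinity sentinel, a
`zero_variance` flag, and exclusion from network construction (their
weight is undefined).

Inputs are assumed already log2-transformed (the convention of
normalised microarray matrices). `filter_de_genes` keeps genes with
`adj_p < cut` and `|logFC| ≥ cut`, defaults 0.01 and 1.0; a relaxed
fold-change cut of 0.5 is appropriate when the strict list is too small
to seed a network. `merge_de_lists` combines two cohorts as
(intersection of the lists) ∪ (genes with `|logFC| >` a strict cut,
default 1.5, in either cohort).

## Network integration

**Scale harmonisation.** `|t|` is unbounded while eigenvector
centrality lives in [0, 1], so the default mode min–max normalises
`|t|` and `|logFC|` across genes before summing them into the node
weight; the two terms of `w_i = c1·g_w + c2·eigen` are then
commensurate and reported gene weights live on a bounded, comparable
scale. A `raw` mode applies the literal sum for users who want
unnormalised statistics.

**Differential correlation** is computed per group on that group's
samples only, with the sign retained; the absolute value enters only
the edge weight. A gene constant within a group has no defined
correlation there; it contributes 0 and a warning rather than NaN.

**Gene-layer edge weight.** Correlation rewiring and interaction
confidence are combined as the equal-weight average of `|Diff_corr|/2`
and the association score, i.e. both mapped to [0, 1] first. No
canonical combination exists for these two evidence types; equal
weighting mirrors the 0.5/0.5 philosophy used everywhere else in the
integration and keeps the edge weight interpretable as a [0, 1]
confidence.

**Eigenvector centrality** is the principal eigenvector of the
score-weighted adjacency, computed per connected component (the
Perron–Frobenius vector is only defined component-wise), then globally
rescaled to max 1. Isolated nodes score 0.

**PPI conventions.** Association scores are accepted in [0, 1] or the
0–1000 STRING convention (auto-detected; anything else is an explicit
error). Edges below a configurable confidence cut (default 0.4,
"medium confidence") are dropped. Duplicate/reciprocal rows collapse to
the maximum score; graphs are undirected throughout. Gene and protein
identifiers must share one namespace; mapping between probe, gene and
protein id spaces is out of scope.

## The SDA optimiser

Agents run sequentially in id order over a shared smell state:

- node smell `s = c1·x + c2·y` (differential × topological weight) —
  with matching coefficients this equals the fused node weight;
- link smell initialised to the edge weight and reinforced on each
  traversal by `δ·p`, where `p` is the sum of node weights along the
  agent's path up to and including the current node (the "accumulated
  weight"), and δ defaults to 0.5;
- movement: the unvisited neighbour with maximal link smell, ties
  broken by higher node smell, then smaller node id — the run is fully
  deterministic given (network, parameters, seed);
- territory: visited marks are global, so agent paths are node-disjoint
  and later agents feel earlier agents' reinforcement. A per-agent
  visited mode exists behind a flag for experimentation;
- dead ends: the agent backtracks along its own path to the most recent
  node with an unvisited neighbour; if none remains the walk ends early.

**Scoring.** The objective `F = mean node weight + mean induced edge
weight` is evaluated on the *induced subgraph* of a node set (a module
of 30 genes routinely has hundreds of induced edges, far more than a
path's m − 1), with the edge term defined as 0 when no induced edge
exists. F is evaluated at every locally maximal state of every walk —
each dead end and the completed path — and the best state over all
agents and restarts is returned, ties going to the larger state. Scoring
dead-end states matters: a walk forced to backtrack may dilute a
high-mean prefix, and the prefix is itself a legitimate connected
candidate.

**Restarts.** Defaults: 8 agents, 10 restarts, module size as
requested (60 is a typical choice for disease-module work). Each
restart rebuilds the smell state. The first agent's start node cycles
deterministically through the sorted node list across restarts while
the remaining starts are drawn randomly without replacement; with at
least as many restarts as nodes this guarantees every node leads one
restart on a fresh smell field, which makes coverage systematic instead
of hoping the sampler hits good seeds. A consequence worth knowing: the
returned module can be smaller than m when a dead-end state strictly
beats every full-size state; in practice this occurs on sparse graphs
where greedy walks get trapped.

**Complexity.** One agent step scans the current node's neighbours, so
a restart costs O(n_agents · m · d̄ + n + e) with mean degree d̄; for
fixed agent count and module size the runtime grows near-linearly in
network size, which the scaling test confirms empirically (best-of-reps
runtime ratio well below 2 per doubling at constant mean degree;
timings use a warm-up run and the minimum over repetitions, as `timeit`
does, to suppress scheduler noise).

## Module evaluation

**Local modularity.** For module S with boundary B (members adjacent to
the outside), `R` = crossing boundary-incident edges / all
boundary-incident edges; low R means a sharp boundary, and a module
with no external edge scores R = 0 (maximally sharp) by convention.
The complementary convention from the local-community literature
(internal fraction, high = good) is available via
`convention="internal"`; the default was chosen so that "lower is
better" holds, consistent with how boundary sharpness is reported for
disease modules.

**Oracles.** `brute_force_best_module` enumerates all connected subsets
of size m (guarded to ≤ 15 nodes) and is the ground truth for
near-optimality tests. `greedy_baseline` is the classic single-start
greedy: always take the heaviest incident edge, no smell, no
backtracking; it stops early at dead ends, which is exactly the failure
mode the agent search's backtracking and restarts address.

## Synthetic benchmark

The generator plants a module that carries all three signals the method
assumes:

| parameter | default | meaning |
|---|---|---|
| n_genes / planted_size | 300 / 30 | background size, module size |
| n_normal / n_tumour | 20 / 20 | samples per group |
| lfc_effect | 2.0 | log2 shift of planted genes in tumour |
| r_high / corr_shift | 0.8 / 0.8 | normal-tissue correlation, its loss in tumour |
| planted_density / background_density | 0.6 / 0.02 | PPI edge probability |
| score_high / score_low | 0.7–0.95 / 0.4–0.7 | association-score ranges |
| noise_sd | 0.5 | residual log2 noise |

Co-expression uses a single latent factor per group: planted gene
values are `base + sd·(√r·f + √(1−r)·ε)` with the factor `f` shared
across the module, giving pairwise correlation ≈ r analytically; the
default corr_shift removes it entirely in tumour. Baselines are drawn
uniformly from 6–10 log2 units, the typical intensity range of
normalised arrays. The defaults describe a clearly detectable module
with a realistic sample size; they are deliberately not at the
detection threshold, because the benchmark's role is to verify the
machinery end-to-end, not to map the power boundary (the effect-size
sweep in `examples/05` does that qualitatively). When connectivity of
the planted PPI module is required, the edge set is redrawn up to 20
times before the spec is rejected as infeasible.

What the generator does **not** emulate: probe-level artefacts, batch
effects, heavy-tailed intensity noise, correlated background genes,
scale-free PPI topology, or identifier mismatch between expression and
interaction data. Passing recovery tests therefore shows the method
works when its assumptions hold, not that it is robust to the
messiness of real cohorts.

**Null calibration.** Under the null spec (no shift, no rewiring,
uniform density and scores) raw p-values reject at the nominal rate
(~1% at p < 0.01, binomial tolerance). BH-adjusted filtering is *more*
conservative under a global null — it retains essentially nothing — so
calibration is asserted on raw p-values, with the adjusted filter
checked to be no less strict, and recovery checked to sit at chance.

## Problem sizes in the test and acceptance runs

The checks run at sizes chosen to keep the full suite fast while
preserving statistical meaning: 100 instances of ≤ 12-node networks
for the exhaustive comparison, 20 generator seeds for recovery and
modularity discrimination, a 3-point effect grid × 12 seeds for
monotonicity, 10 seeds × 300 genes for null calibration, and ER
networks of 1000/2000/4000 nodes (mean degree 10) for scaling.

## Known limitations

- The search is greedy per step; pathological weight landscapes can
  hide the optimum from every start (the acceptance check tolerates up
  to 5% of small instances outside the 10% optimality band).
- Eq-style weights assume the expression matrix and PPI share gene
  identifiers; no orthology or probe mapping is attempted.
- Wall-clock scaling is measured, not proven; extremely dense graphs
  (d̄ ~ n) degrade toward O(n·m) per agent.
- The per-agent-visited experimental mode changes the territory
  semantics and is not covered by the dominance guarantees above.
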