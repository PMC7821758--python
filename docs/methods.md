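# Methods

This note records the statistical model behind each pipeline stage, the
design choices made where conventions genuinely diverge, what the
synthetic-data generator does and does not emulate, and the numerical
conventions the tests pin down.

## Differential expression

The screen is the two-criterion fold-change/t rule: FC = mean tumor FPKM /
mean normal FPKM, called up when FC ≥ 2 and down when FC ≤ 0.5, each with
two-sided *p* < 0.05. Both fold-change thresholds are inclusive; a
pseudocount (10⁻³) enters the ratio only when the denominator is zero, so
FC = 2.0 exactly is still called (genes are pre-filtered by max-FPKM ≥ 1,
so zero denominators are rare anyway). The t-test defaults to Welch
(unequal variances) on raw FPKM; pooled-variance (`equal_var`),
log2(x+1) transformation (`log_transform`) and Benjamini–Hochberg
adjustment (`bh_correct`) are flags, off by default because raw-scale
testing without multiplicity adjustment is the workflow's standard
operating point. Raw FPKM is heavy-tailed, so the log flag is the safer
choice for data with extreme outliers; both paths are tested.

Outlier samples are flagged by complete-linkage hierarchical clustering
(Euclidean distance over gene vectors) on tumor samples: the dendrogram
is cut into two clusters and, when the smaller holds under 5% of the
current samples, its members are flagged and the cut repeats on the rest,
at most five rounds. The cut fraction and round cap are this package's
convention — agglomerative outlier trimming has no canonical stopping
rule — and both are parameters. Under a pure null the rule still trims a
few extreme samples per two hundred; that mirrors how the procedure is
used in practice (it is a trimming heuristic, not a test).

## Co-expression network

Pearson correlations are computed over tumor samples on the expression
scale, blockwise so memory stays linear in emitted edges. The p-value
uses the exact t transform *t* = *r*·√((n−2)/(1−*r*²)) with df = n−2 and
*p* = 0 at |*r*| = 1. The edge rule is |*r*| ≥ 0.65 with *p* < 0.05; the
sign is kept as an edge attribute so signed analyses remain possible, but
thresholding is on the absolute value. Constant genes are excluded with a
warning (their correlations are undefined). The GCN is the largest
connected component, ties broken toward the component containing the
lexicographically smallest gene id. Network density is 2m/(n(n−1)).

## Module detection

Three algorithms produce candidate partitions:

- **multi-level** — Louvain greedy modularity optimisation (igraph's C
  implementation, resolution 1, RNG seeded per call);
- **label propagation** — asynchronous, implemented here: each sweep
  visits nodes in a fresh seeded random order; a node adopts its
  neighbours' most frequent label, keeping its current label when it is
  among the tied leaders (required for the "all labels locally majority"
  stopping rule to be reachable) and otherwise breaking ties by a seeded
  uniform draw; bounded by `max_sweeps` (default 100) with a warning on
  non-convergence;
- **edge betweenness** — Girvan–Newman divisive removal (igraph), with
  the dendrogram cut at the maximum-modularity level. On a single edge
  this correctly returns one module (Q = 0 beats two singletons at
  −0.5).

Modularity Q = Σ_c [m_c/m − (d_c/2m)²] is implemented in-package and
cross-checked against networkx in the tests; every returned partition
stores the Q recomputed by this one function, so stored and recomputed
values agree to 10⁻¹². Selection takes the highest Q with exact ties
resolved by the fixed order multi-level > label propagation > edge
betweenness. Modules under `min_module_size` (default 50) become
"unassigned" — retained in outputs so downstream joins stay total — and
survivors are renumbered m1, m2, … by descending size.

## Module–trait and survival association

The module eigengene is the first principal-component score vector of the
samples × member-genes submatrix after per-gene mean-centering (unit
variance scaling is a flag, off by default to match the common
covariance-PCA convention), normalised to unit length and sign-oriented
so it correlates non-negatively with the module's mean centred
expression. Eigengene–indicator association is plain Pearson *r* with
two-sided *p* over pairwise-complete samples; T is encoded 1–4
(sub-stages collapsed), N/M/event as 0/1; constant indicators yield NaN.

Per-gene prognostic significance comes from a univariate Cox
proportional-hazards fit on log2(FPKM+1) with Wald two-sided *p*;
PS = −log10 *p* (base 10; *p* clipped at 10⁻³⁰⁰), and a module's PS-value
is the exact sum over its members. Continuous covariates are used rather
than percentile dichotomisation: the regression *p*-value is the defined
quantity, and cuts would add an arbitrary parameter. Fits use lifelines,
whose tie handling is Efron's; the synthetic survival times are
continuous, where Efron and Breslow coincide. Non-converged fits get
*p* = 1 (PS = 0) with a warning; a cohort with no events is an error.
The key module is the argmax of max |*r*| over the four indicators (ties
to the larger module); when the PS argmax differs a disagreement warning
is logged and both are reported.

## PPI topology scores and hub calling

Edge lists are STRING-export style; the score scale (0–1000 vs 0–1) is
auto-detected, duplicates collapse keeping the maximum, and edges are
kept at combined score ≥ 0.400 (boundary inclusive). The nine scores:

- **Degree**; **MNC** — node count of the largest connected component of
  the subgraph induced by N(v); **DMNC** — that component's edges divided
  by its node count to the power ε = 1.7 (the defining publication's
  exponent), 0 when the component has ≤ 1 node.
- **EPC** — mean, over seeded Monte-Carlo replicates (default 1000,
  retention 0.5), of the number of nodes still connected to v after
  independent edge percolation. No normalisation is applied; a
  normalisation hook would be needed to match plugin outputs whose
  scaling is undocumented, so magnitudes are implementation-defined and
  only conventions are asserted.
- **BottleNeck** — for each root, a breadth-first shortest-path tree is
  grown with a pinned deterministic parent rule (neighbours explored in
  ascending node-id order; parent = earliest-discovered neighbour); node
  v ≠ s counts for root s when v's subtree holds strictly more than a
  quarter of the reachable nodes. BFS trees are not unique, so the parent
  rule is a convention pinned by tests, including the two-node boundary
  case where each endpoint scores 1.
- **Closeness** — harmonic: Σ 1/d(v,u), unreachable nodes contributing 0;
  **Radiality** — Σ (Δ_C + 1 − d(v,u))/(n_C − 1) within v's component
  (diameter Δ_C, size n_C), 0 for singletons.
- **Betweenness** and **Stress** — over unordered source–target pairs;
  betweenness sums geodesic fractions (Brandes), stress sums raw geodesic
  counts via per-source BFS σ-counting.

All eight deterministic scores are verified exactly against brute-force
enumeration references (Floyd–Warshall distances, explicit shortest-path
enumeration, parent-chain walking) on random small graphs, and EPC
against exact 2^m edge-subset enumeration. Hub calling takes the k = 5
highest scores per column, includes every gene tied with the rank-k
value, and unites across columns with per-gene provenance. On graphs
where an integer-valued column (often BottleNeck) ties at rank 5 with a
low value, the tie-inclusive rule can widen the union considerably; the
union is therefore best read through its provenance.

## Validation stages

Independent-cohort expression tests are per-gene Welch (or paired) t
tests with direction by mean comparison; absent genes are reported, not
fatal. AUC is U/(n₊·n₋) from the Mann–Whitney statistic — ties counted
one half — with the attached *p* from the two-sided normal approximation
with tie correction; the positive class is tumor, and AUC < 0.5 is
reported as-is. Methylation uses a paired t-test by default (the data are
explicitly paired), falling back to unpaired with a warning when the
pairing table is inconsistent; hypo/hypermethylation calls require the
corresponding mean ordering plus *p* < α. Over-representation is the
upper-tail hypergeometric P(X ≥ k) against a user-supplied universe and
gene-set collection, with BH-adjusted values always reported alongside.

## Synthetic data generator

Tumor expression follows a one-factor model per planted block on the
log2 scale: z_g = λ_g f_b + √(1−λ_g²) ε with λ_g ~ U(0.85, 0.98), so
within-block Pearson correlations concentrate near λ² (≈0.72–0.96);
log2 expression is μ_g + Δ_g + σ·z with noise σ = 0.5, exponentiated to
an FPKM-like scale. Exponentiation attenuates correlations only slightly
at this σ (a planted λ² = 0.81 measures ≈0.80 on the FPKM scale).
Defaults: 1200 genes, 200 tumor / 50 normal samples (a scaled-down
tumor-dominant cohort), three blocks of 80/60/50 genes, 25% of genes
differentially expressed with log2FC ~ U(1, 3) (block genes all up,
background DEGs 90% up / 10% down), 5% of genes planted below the
max-FPKM filter. Hub genes draw their log2FC from the upper half of the
range: a hub is by definition a member of the DEG-derived key module, so
its differential expression must sit clearly inside the callable region,
matching the strong up-regulation real hub genes show.

Consecutive blocks are joined by three "rotating bridge" genes loading
0.95·(cos θ, sin θ) on the two adjacent factors, θ = π/8, π/4, 3π/8.
Orthogonal factors cannot be linked by individual genes at |r| ≥ 0.65
(two loadings a, b with a² + b² ≤ 1 cannot both clear 0.65/0.98), and
borderline constructions fail intermittently once raw-scale attenuation
and outlier trimming bite; the gradual rotation yields robust ≥0.75
chain correlations. Without a bridge the largest-component step would
keep exactly one block.

Clinical indicators derive from the prognostic block's latent factor f
with slope s (default 1): T is an ordinal cut of s·f + N(0,1) at fixed
marginal proportions (45/30/15/10%), and event, N, M are logistic with
slopes 0.7s, 0.4s, 0.2s — ordering the correlation strengths
T > event > N > M. Survival time is exponential with hazard
h₀·exp(β·f) (h₀ = 10⁻³ per day, β = 1), censored by an independent
uniform over [0, 3000] days giving ≈30% censoring; the censoring rate
and stage distribution are package defaults, not claims about any real
cohort. The PPI generator attaches each of 3 planted hubs to other
prognostic-module members with probability 0.85 at scores 600–999, over
an Erdős–Rényi background (p = 0.05, scores 150–699); methylation draws
paired betas around U(0.35, 0.65) baselines with shared patient effects,
shifting hub genes down (hypo) and a matched count of background genes
up (hyper) by 0.2, clipped into (0,1) with a warning.

Every generator consumes an independent, fixed-offset stream spawned
from the single seed, so identical config + seed reproduces all four
data sets bit for bit.

**What the generator does not emulate:** library-size or GC biases,
batch effects, count-level noise (mean–variance coupling beyond the
lognormal), overlapping or hierarchical modules, missing clinical
values, informative censoring, probe-level methylation structure, or
realistic PPI degree distributions. Passing recovery tests therefore
show the pipeline's logic is correct under its own assumptions — block
correlation, monotone links, proportional hazards — not that those
assumptions hold in any particular real cohort.

## Problem sizes and numerical conventions

Multi-seed studies (recovery, calibration) use ten seeds at the default
cohort size; oracle sweeps use 100 random connected graphs of ≤ 8 nodes
(exact enumeration stays trivial there) and exhaustive set-partition
enumeration up to 8–10 nodes. EPC uses 1000 replicates; its Monte-Carlo
checks use 3-standard-error bands from exact enumeration variances.
Degenerate inputs are handled explicitly: empty edge sets and all-below-
threshold PPI lists warn and return empty graphs; all-constant modules
return zero eigengenes with a warning; modularity on an edgeless graph,
density below two nodes, Cox without events, single-class AUC and empty
ORA universes raise errors. Seeds fan out to stages by fixed offsets so
each stage is independently reproducible.

## Known limitations

Raw-FPKM Pearson correlation and Welch tests are sensitive to heavy
tails; the log-scale flags exist for that reason. The Girvan–Newman step
is O(m²n) and is practical only up to a few thousand edges — at larger
scales, drop it from the candidate list. EPC magnitudes are not
comparable to plugin outputs whose normalisation is undocumented. The
key-module rule reduces a correlation matrix to one argmax; in real
analyses the full eigengene–indicator matrix and PS ranking deserve
inspection, which is why both are always written out.
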