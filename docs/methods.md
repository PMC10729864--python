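# Methods

## The co-regulation model

The unit of evidence is a *contrast*: one two-group comparison (treatment
vs control) with a handful of samples per arm.  Every contrast is reduced
to per-gene calls — DEG or not, and the sign of the log2 fold change —
yielding the binary DEG matrix `B ∈ {0,1}^{G×K}` and the signed matrix
`S ∈ {−1,0,+1}^{G×K}` with `S ≠ 0` exactly where `B = 1`.

For an unordered gene pair, the observed statistic is
`n = #{k : B_ik = B_jk = 1}`, with `n₊∕₋` of those contrasts discordant
(`S_ik ≠ S_jk`).  The null keeps each gene's DEG propensity and each
contrast's DEG yield: random matrices with exactly the row and column sums
of `B`.  The pair's null co-occurrence count over `K` contrasts is modeled
as beta-binomial,

    P(X = n | K, α, β) = C(K, n) · B(n + α, K − n + β) / B(α, β),

i.e. `K` Bernoulli trials whose success probability is itself
Beta(α, β)-distributed, capturing the contrast-to-contrast heterogeneity of
the co-DEG probability.  The pair's p-value is the inclusive upper tail
`P(X ≥ n_obs)`; FDR is Benjamini–Hochberg across all retained pairs.

Assumptions worth keeping in mind: contrasts are treated as exchangeable
and independent; DEG calls are taken at face value (no uncertainty
propagation); the beta-binomial is a fitted summary of the fixed-margin
ensemble, not an exact law of it (the exact distribution is intractable,
which is why the ensemble is sampled).

## Fixed-margin sampling

Matrices are drawn by curveball trades: pick two rows, pool the column
indices owned by exactly one of them, and deal the pool back at random
sizes preserved.  Trades preserve both margin vectors and the walk's
stationary distribution over the fixed-margin state space is uniform; the
test suite verifies uniformity by exhaustive enumeration on small matrices
(chi-square over all states at 10 000 samplings) and cross-checks means
against a naive checkerboard-swap sampler.

Each of the `n_samplings` (default 1000) matrices is an independent
restart from the observed matrix separated by `n_swaps` trades, default
5× the number of nonzero entries — a mixing parameter, deliberately
generous for the sparse matrices this method sees.  Sub-seeds derive
deterministically from the ensemble seed, so results are bit-reproducible.
Samplings are processed streamingly; only per-pair counts are retained.
The trade loop is numba-compiled; one sampling of a 200 × 100 matrix at 5%
density costs ~1 ms.

Pairs with observed `n < min_obs` (default 2) are dropped before null
tabulation: a pair never observed together cannot reach significance, and
the per-pair null vectors dominate memory/time at scale.  Set `min_obs=0`
on small inputs.

## Beta-binomial fitting

Per pair, method of moments on the null count vector: with sample mean `m`
and variance `v`, `p = m/K`, and `α+β = (K − c)/(c − 1)` where
`c = v / (K·p·(1−p))`.  Edge cases:

* `v` at or below the binomial variance (no overdispersion): `α+β` is set
  to 10⁶ at fixed mean, reproducing Binomial(K, p) to float precision;
* `c ≥ K` (variance at the beta-binomial maximum): `α+β = 0.02`,
  approaching the maximally overdispersed limit;
* zero-variance vectors (e.g. all zeros): a degenerate point-mass null —
  `p = 1` when the observation does not exceed the mass point, machine
  floor otherwise.  On very sparse inputs with few samplings this makes
  low-count pairs look extreme; the remedy is more samplings, not a
  different fallback.

Maximum-likelihood refinement (`method="mle"`, Nelder–Mead on the
log-parameters) is available but unnecessary for 1000-sample vectors;
moments fitting is closed-form and vectorized across pairs.

## DEG calling

The downstream method consumes only `B` and `S`, so the caller is a
replaceable default: Welch t-test on log2-scale values, BH-adjusted
p < 0.05 within each contrast, and |log2FC| ≥ 1 (both configurable);
matrices can instead be imported from TSV if an external DE tool produced
them.  log2FC is mean(group 1) − mean(group 0); count-scale input is
log2(x+1)-transformed first.  Constant genes get (0, 0) silently; a group
with fewer than two samples is an error.

## Nonlinear score and Simpson detection

`score = 1 − |1 − 2·n₊∕₋/n|` ∈ [0, 1], symmetric under swapping concordant
and discordant counts, 1 only at an even split, 0 only at a pure split.
Pairs with score ≥ 0.5 are labeled `nonlinear`, the rest
`linear_concordant`/`linear_discordant` by majority direction; the 0.5
cutoff is a labeling convention, configurable.

Simpson's-paradox detection needs explicit thresholds to be reproducible:
a pair is flagged iff at least `min_contrasts = 3` contrasts have
|r| ≥ `r_within = 0.3` with one common sign, and the pooled correlation
over those samples has the opposite sign with |r| ≥ `r_pooled = 0.3`.
Per-contrast correlations pool both groups of the contrast.  Constant
vectors are excluded with a warning.  The cutoffs are this package's
choices; the count of flagged pairs is sensitive to them.

## Network stage

Scale-free cutoff: for each candidate FDR threshold, build the network and
regress log10 degree density on log10 degree over up to 10 logarithmic
bins (empty bins dropped, ≥3 occupied required).  The candidate maximizing
R² subject to a negative slope wins; ties break toward the stricter
threshold.  This is the standard scale-free topology fit index; it is a
model-selection heuristic, not a hypothesis test.

Recursive Louvain: communities larger than `max_module_size = 1000` are
re-partitioned on their induced subgraph until nothing oversized remains
or a subgraph refuses to split; modules below `min_module_size = 5` are
labeled unassigned (−1).  Louvain comes from networkx with a derived seed,
so partitions are deterministic per (graph, seed).

Annotation interaction density = (edges whose endpoints share ≥1 term) /
(edges with both endpoints annotated), compared against Erdős–Rényi
G(n, m) graphs on the same genes with the same edge count (empirical
p = (1 + #{null ≥ obs}) / (1 + n_random)); a degree-preserving rewiring
null is available for sensitivity analysis.

## Synthetic data

The generator emulates the heterogeneous-compendium setting: K = 100
contrasts, 5 samples per arm, 200 genes, background DEG rate 5% with
random signs, Gaussian log2-scale expression (baseline N(8, 1) across
genes, within-group sd 0.25) and log2 effect size 2 where a gene is a DEG.
At these settings the Welch caller's per-gene power is effectively 1, so
the emitted truth table is recovered verbatim and end-to-end tests can
score against it.  Planted pairs are jointly DEG with `co_deg_rate`
(default 0.4) per contrast, with signs set by their type; outside joint
events the genes fall back to independent background behavior.

Simpson pairs are written directly in expression space: contrast centers
drift upward along the identity line (step 0.5 per contrast) while samples
within a contrast spread along a negative axis (sd 0.4, plus sd 0.1
independent noise); co-DEG events displace the groups along the same
negative axis, so within-contrast r ≈ −0.96 and pooled r > 0.9.  A
standalone `simulate_simpson_pair` produces the textbook geometry
(centers at (c·trend, c·trend), within-slope −1) for detector tests.

What the generator does *not* emulate: count noise (expression is
Gaussian, not negative-binomial — only the DEG calls matter downstream),
correlated background genes, shared samples between contrasts, batch
structure within a contrast, or repository-scale cardinality (thousands of
studies, tens of thousands of genes).  Passing tests therefore demonstrate
statistical correctness of the machinery under the stated conditions, not
robustness to real-data pathologies upstream of the DEG matrix.

## Problem sizes and numerics

Validation runs use 200 genes × 100 contrasts × 1000 samplings × 20 seeds
for calibration/power, exhaustively enumerable matrices (≤4×4) for
uniformity, 10⁵-draw simulations for fit recovery, and 2000-node graphs
for the cutoff scan.  pmf evaluation uses log-gamma throughout; tail sums
are clipped to [0, 1]; pair order is canonical (matrix row order, i < j);
self-pairs are excluded.
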