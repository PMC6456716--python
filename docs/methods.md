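# Methods

## Profile construction

Site methylation is quantified per condition as
`M = log2((RPKM_IP + 0.1)/(RPKM_Input + 0.1))`; the 0.1 pseudo-count is
part of the definition and not configurable. Biological replicates are
merged by arithmetic mean of RPKM before anything else (the merging
rule is configurable in principle but the mean is the default and the
only one shipped). The processing order is: merge replicates → compute
M-values per merged condition → quantile-normalize the M-value matrix.
Normalizing the IP and input RPKM matrices first and taking M-values
second is available via `normalize_on="rpkm"`; the two orders are not
equivalent and the M-value-space default was chosen because it
normalizes the quantity that actually enters the correlation networks.
Gene expression is merged, quantile-normalized, then log2(x + 0.1)
transformed — correlations on log expression, not raw RPKM, since RPKM
is roughly lognormal and Pearson correlation on the raw scale is
dominated by the right tail.

Quantile normalization maps each column onto the row-wise mean of the
per-column order statistics; tied values receive the mean of the
reference values over their tied positions, so ranks are preserved
exactly and all columns end with identical value multisets.

Site filtering is sequential, each percentile computed on the
survivors of the previous step: (1) support from strictly more than 10
experiments; (2) mean M-value at or below the 70th percentile of
per-site means — "within the 70 percentile" is read as excluding the
extreme-high, likely saturated sites; the opposite reading is exposed
as `level_rule="ge_pct"`; (3) per-site variance at or above the 20th
percentile (the top 80% most variable, i.e. most actively regulated,
sites). Percentiles use linear interpolation between order statistics
and ties at a threshold are retained. Because the percentile
thresholds are recomputed from whatever is passed in, applying the
filter twice removes more sites than applying it once; the filter is a
one-shot preprocessing step, not a projection.

## Association networks

SS, GG and SG networks test all (unordered or cross) row pairs:
Pearson correlation across conditions, two-sided p-value from the
Fisher z-transform (`z = atanh(r)·sqrt(n−3)`; the t-reference
alternative is behind `method="t"`), Bonferroni adjustment with
divisor equal to the number of pairs actually tested (constant rows
are skipped and shrink the divisor), and retention when adjusted
p < 0.05 *and* the correlation ranks in the top or bottom 10
percentile of all tested correlations in that network (ties at the
threshold kept). The percentile is global per network, not per node.
Edge weight is |r| — correlation sign is deliberately not distinguished
in the network because methylation can either enhance or repress
expression; the signed r is carried along for the direction call only.

DD similarity is the Jaccard index of MeSH term sets, all pairs kept
with no cut-off; zero-similarity pairs are simply not stored, which is
equivalent under column normalization. DG is the curated bipartite
list, deduplicated, weight 1.

## Transition matrix

Nodes are ordered diseases, genes, sites. Each sub-block is
column-normalized independently, then scaled by its layer weight (1/2
for the two blocks of disease and site columns, 1/3 for the three
blocks of gene columns — all five networks weighted equally; learning
these weights is out of scope). The disease–site block is a structural
zero. When a node has edges in only some of its blocks, the default
`redistribute` policy reassigns the missing blocks' weight
proportionally to the present ones so the column still sums to 1;
without this (policy `leak`), such columns are sub-stochastic and
walker mass decays geometrically — harmless for ranking but it makes
probabilities across diseases less comparable. Fully isolated nodes
keep zero columns; the restart term keeps the iteration bounded
regardless.

## Random walk with restart

`P[s+1] = (1−r)·W·P[s] + r·P0` with r = 0.75 and an indicator seed.
The stopping rule compares successive iterates in the L∞ norm against
tol = 1e-10 (the norm is not dictated by the recursion itself; L1 is
available via config). For column-stochastic W the map contracts in L1
by the factor (1−r) = 0.25, so convergence takes at most ~25
iterations at this tolerance; a max_iter = 1000 safety cap flags
(rather than raises on) non-convergence. `rwr_solve` computes the
exact fixed point `P = r(I − (1−r)W)⁻¹P0` by dense linear solve and is
the oracle the iterative path is tested against at up to 2000 nodes.

## Significance and direction

100 random networks are built by degree-preserving edge exchange
applied to each of the five sub-networks independently — rewiring
within a sub-network preserves both the layer structure and each
sub-network's degree sequence, which is the stricter and more
conservative reading of randomizing "while maintaining topology".
Each proposed exchange a-b, c-d → a-d, c-b is accepted only if neither
new edge exists and no self-loop arises; 10 attempted swaps per edge.
For weighted within-layer networks only the topology is rewired and
each edge keeps its weight through the swap — an approximation, since
a weight-aware null is not defined by the procedure. Degenerate
networks with no legal swap are returned unchanged with a warning.

The empirical p for a (disease, site) pair is
`(1 + #{null ≥ observed}) / (K + 1)` against the site's own K null
probabilities (a pooled null over all sites is available by flag); the
add-one form cannot return 0 from finite permutations and is
super-uniform under the null.

Direction: per disease gene, the Pearson correlation between the
site's M-value profile and the gene's expression, sign-flipped for
genes labelled under-expressed in that disease; the median of these
signed correlations calls hyper (> 0) or hypo (< 0), with an exact
zero reported as NA rather than arbitrarily assigned.

## Baseline and evaluation

The hypergeometric baseline scores a (disease, site) pair by the
upper-tail probability of the observed overlap between the disease's
genes (DG) and the site's genes (SG) out of m genes total. The printed
form of the tail omits the `C(x, i)` factor; the implemented
distribution is the standard hypergeometric upper tail, which is the
test the method names. No multiple-testing correction is applied in
the ranking.

Cross-validation holds out 10% of DG edges per fold (balanced random
partition, seeded). Disease–site associations have no gold standard,
so recovery is measured on the held-out disease–gene links: positives
are a test disease's held-out genes, negatives its never-associated
genes (an all-genes variant is a flag). The walk scores a (disease,
gene) pair by the gene node's stationary probability. The baseline
has no native gene score, so it is adapted one hop out: gene g is
scored by the hypergeometric overlap between the disease's training
genes and the genes co-linked with g through shared sites — still
using only DG + SG information. The random control draws i.i.d.
uniform scores. ROC uses midrank tie handling (trapezoidal AUC equals
the normalized Mann–Whitney statistic); per-disease AUCs pool each
disease's scores across folds and require both classes present; both
the unweighted mean and the median of per-disease AUCs are reported.

The host-gene diagnostic computes, per site, the correlation between
its methylation profile and its host gene's expression, against a null
of random site–gene pairings (default 1000 permutations) — on real
MeRIP-seq derived data these distributions are expected to be close,
which is the argument that the site layer is not redundant with
expression.

## Synthetic benchmark

The generator plants exactly the structure the method assumes and
nothing else that could leak truth directly. Genes split into
`n_modules` contiguous modules; module factors are i.i.d. standard
normal per condition; gene log-expression is
`sqrt(rho)·u_g·f + sqrt(1−rho)·eps` with rho = `corr_strength` and the
per-gene coupling `u_g ~ U(1 − 1.25(1−rho), 1)` — at the default
rho = 0.8 that is U(0.75, 1), giving a mean within-module correlation
near rho with realistic gene-to-gene spread, and collapsing to perfect
correlation as rho → 1. Sites inherit their host gene's coupling and
module factor with independent noise scaled by `noise_sd`; the IP
channel is reconstructed from the input channel and the target M-value
so the pseudo-count path is exercised; RPKM is lognormal around ~12
(roughly 1–100). Six of the conditions carry two jittered replicates.
Each disease gets one module (60%) or two (40%) and links to half of
each module's genes, sampled with weight `exp(8(u_g − u_min))`:
curated disease annotations are biased toward strongly co-regulated,
well-studied genes. This bias is what separates the walk (which sees
the graded |r| edge weights) from the binary-overlap baseline in the
benchmark ordering. MeSH terms mix a per-module pool with background
vocabulary so same-module diseases are more similar. Planted truth is
(disease, site) for sites hosted by genes of the disease's modules;
truth never enters any emitted data file except through this module
structure.

Defaults (50 diseases, 300 genes, 800 sites, 38 conditions, 10
modules, corr 0.8, seed 7) mirror the scale of the motivating data in
conditions and keep the full pipeline's network around 1,100 nodes, so
the complete cross-validated comparison runs in seconds on one core.
What passing on this benchmark shows: the pipeline's plumbing and the
propagation's ability to exploit module structure. What it does not
show: performance on real MeRIP-seq data, where modules are not clean
blocks, noise is heteroskedastic, annotation bias is stronger and
unmodelled, and the disease–gene network is far sparser relative to
the gene universe.

## Numerical choices and edge cases

- Percentiles: linear interpolation; ties at thresholds kept.
- Bonferroni: divisor = tested pairs; adjusted p capped at 1.
- Constant profiles: skipped in correlation networks with a warning.
- Empty correlation networks are valid outputs (warning, not error).
- Site ranking ties broken lexicographically by site id; baseline
  ranking ties likewise — all orderings deterministic.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence.spawn`; the pipeline's
  outputs are byte-identical across reruns with the same seed.

## Known limitations

- The weighted edge-swap null rewires topology only; weights travel
  with edges, so the null preserves the weight multiset but not any
  weight–degree correlation.
- The mean-M-value filter direction and the quantile-normalization
  stage order are genuine ambiguities of the procedure; both readings
  are implemented, one is the documented default.
- The permutation stage dominates runtime at scale (it re-runs the
  walk per random network per disease); for exploratory use
  `n_random_networks` can be lowered at the cost of p-value
  resolution (minimum attainable p is 1/(K+1)).
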