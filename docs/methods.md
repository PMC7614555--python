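# Methods

## Synthetic cohort model

The generator draws standardised scores from an orthogonal latent-factor
model

    X = F Λᵀ + E · diag(√ψ),      F ~ N(0, I_k),  E ~ N(0, I_p),

with the 19 × 5 loading matrix Λ and uniqueness vector ψ transcribed from
the published varimax solution, so the population correlation of the
standardised scores is ΛΛᵀ + diag(ψ) (row communality + uniqueness ≈ 1 for
every transcribed row, within 0.012). Scores are then mapped affinely onto
each measure's published mean and SD, clipped to its published range, and
rounded for count-type measures (reading, sums, digit and dot-matrix
spans). The three composite measures (fluid reasoning, search, speed) are
kept on the z scale (mean 0, SD 1, range ±4) because their published
descriptives are subscore-level.

Two consequences of the clipping/rounding step matter for tests: measures
whose mean sits close to a scale bound acquire a deterministic truncation
bias (growth mindset's ceiling lies 0.71 SD above its target mean, biasing
its realised mean by ≈ 0.12 SD), and the realised correlation structure is
perturbed by a few hundredths. Test tolerances absorb both.

Missingness is cell-wise MCAR. The default rate 0.0145 is calibrated so
the expected complete-row fraction (1 − r)¹⁹ matches the study's
complete-case count (397 of 519 ≈ 76.5%); no missingness mechanism beyond
MCAR is modelled, and absent children (who never enter the table) are not
modelled at all. The generator therefore supports testing the exclusion
rule, imputation, and all downstream stages — it does not emulate school
or class structure, age trends, or informative missingness, so passing
tests say nothing about those aspects of real data.

The Gaussian-graphical-model sampler builds a precision matrix with
Bernoulli(edge_density) support, off-diagonal magnitudes uniform in
`partial_range` with random signs, unit diagonal inflated by the smallest
shift that makes the matrix positive definite (error if the required shift
exceeds 5). Inflation shrinks realised partial correlations slightly below
the nominal range; the returned truth matrix is always computed from the
final precision.

## Preprocessing

Pipeline order is standardise-then-impute. Rows with missing fraction
strictly greater than `max_missing_fraction` (default 0.20) are excluded
first. Standardisation uses observed-cell means and SDs (n − 1). The kNN
imputer (default k = 9) uses complete rows only as donors; distance from
an incomplete row to a donor is the Euclidean distance over the row's
observed columns divided by √(number of shared columns), ties broken by
donor row order, and each hole is filled with the unweighted mean of the
k nearest donors' values. With 19 weakly coupled measures the imputer's
per-column error cannot beat the column SD for high-uniqueness measures
(the information simply is not there; the best achievable RMSE is about
√ψⱼ, and averaging k donors adds ≈ 1/k variance), but the pooled RMSE over
a 5% masked sample of a complete cohort is ≈ 0.94–0.96 and beats
column-mean imputation on every seed tried.

Power utilities use the Fisher z approximation: power =
Φ(|atanh r|·√(n−3) − z₁₋α/₂) (both rejection tails are included; the
wrong-sign tail only matters near r = 0, where it makes the null limit
equal α), and the minimum detectable correlation inverts it as
tanh((z₁₋α/₂ + z_power)/√(n−3)).

## Dimensions

Components come from the eigendecomposition of the Pearson correlation
matrix; loadings are eigenvector × √eigenvalue with a deterministic sign
convention (largest-magnitude entry of each column non-negative). Varimax
uses the standard SVD update scheme (tolerance 1e-6 on the criterion, max
1000 sweeps) with Kaiser row-normalisation on by default; columns are
reordered by descending sum of squared loadings. Rotation preserves row
communalities to 1e-8, and for k = 2 the achieved criterion matches an
exhaustive 1e-4-radian scan over the rotation angle.

Parallel analysis simulates standard-normal datasets of the observed
shape (default 1000 iterations), takes the per-index 95th percentile of
their correlation eigenvalues as thresholds, and retains leading observed
components sequentially until the first failure. The number of rotated
components defaults to the Kaiser count (strictly > 1), with the parallel
retention recorded alongside — mirroring a report that rotates five
components while flagging three as significant.

## Clustering

Nonmetric (Kruskal) MDS of pairwise Euclidean distances, SMACOF
majorisation with monotone regression, best of `n_restarts` random starts
(default 4), stress reported as Kruskal stress-1. k-means uses k-means++
seeding with 10 restarts, best by within-cluster sum of squares.

Two silhouette variants are implemented and the choice is recorded in
every result. The *classical* statistic (Rousseeuw; mean over samples of
(b − a)/max(a, b) with a the mean intra-cluster and b the best mean
inter-cluster distance) is the reporting default. The *centroid* variant
replaces the two means by distances to the own and nearest-other centroid;
it is O(nk) but sits systematically above the classical value (a point at
its centroid scores 1), by ≈ 0.14 on unimodal 2-D embeddings of this
cohort (≈ 0.49 vs ≈ 0.35). Published silhouettes for this design are
"just under 0.4" against a 0.5 threshold, which is consistent with the
classical statistic's scale and not with the centroid variant's; the
classical default follows from that, and the decision rule
(max-over-k > 0.5, strict) is unchanged either way — both variants stay
below 0.5 on cohorts from the factor model.

## Network

Edges are partial correlations from the precision matrix; sparsity comes
from the graphical lasso with the penalty on off-diagonal precision
entries only (coordinate descent, duality-gap tolerance 1e-6, entries
below 1e-8 treated as exact zeros; at the smallest penalties the dual gap
can stall near the solver's numerical floor, in which case the stalled
solution is used — the residual gap is orders of magnitude below any
reported quantity). λ = 0 falls back to plain inversion.

Penalty selection: 30 log-spaced values from λ_max (the largest
off-diagonal |correlation|) down to λ_max/100; 5-fold CV with seeded fold
assignment; score is the mean held-out Gaussian log-likelihood
log det Ω − tr(S_test Ω); the grid argmax is returned. Note that
likelihood-optimal CV is prediction-oriented and selects dense networks
(on sparse-truth simulations at n = 519 it picks λ ≈ 0.02 and keeps
roughly two thirds of all possible edges); it is not model-selection
consistent, and the bootstrap significance rules below are what prunes
the estimate.

Bootstrap (default B = 3000; reduced sizes are used in tests and scripts,
stated below): resample children with replacement, re-estimate the
network — re-selecting λ per iteration when `lambda_mode="retune"` (the
default), or reusing the full-data λ (`"fixed"`, used by the drivers for
speed) — and record the binary edge set and weight matrix; degenerate
resamples (a constant column) are redrawn and counted. Occurrence
significance: the chance count is the 100·(1−α) percentile (uncorrected)
or 100·(1−α/m) percentile (Bonferroni, m = p(p−1)/2 = 171 for 19 nodes,
i.e. the 99.97th percentile at α = 0.05) of the per-iteration edge
totals, linear-interpolation percentile convention throughout; divided by
m it becomes a fraction of the possible edges, and an edge is significant
when its occurrence probability strictly exceeds it. CI significance: the
2.5th/97.5th percentiles of each edge's weight over all iterations
(absent edges entered as 0) must exclude 0.

On simulated sparse truths the two rules behave very differently: the CI
rule is conservative and accurate (sensitivity 1.0, specificity ≈ 0.99 at
n = 519, B = 200 on a density-0.2, 19-node model), while the occurrence
rule is liberal — borderline spurious edges recur in more resamples than
the chance fraction, capping its specificity near 0.8 at the CV-selected
penalty (and near 0.87 even at strongly sparser penalties). Users wanting
edge-set recovery should prefer the CI mask; the occurrence rule is kept
because it is part of the procedure under study.

Node layout is nonmetric MDS on distances between variable columns
(children as dimensions), so nodes answered similarly sit together; for
standardised columns the distance is monotone in √(2(1 − r)). Marginal
Pearson correlations with Holm step-down correction are produced for
comparison with the partial-correlation network.

## Orchestration and determinism

`pipeline.run_pipeline` executes cohort → preprocess → dimensions →
clustering → network from one config; every stage seed is derived from
the master seed by CRC-32 hashing of the stage name (kept below 2³¹), so
adding a stage never perturbs earlier stages' draws and identical
config + seed gives byte-identical CSV artifacts. All artifacts are plain
CSV/JSON/GraphML.

## Problem sizes used in tests and scripts

Chosen so the default suites run comfortably on one CPU: bootstrap B = 200
for recovery experiments and 10–25 for determinism checks; parallel
analysis at 200–1000 iterations; cluster-null replication on two seeded
cohorts with 2 MDS restarts; CV interior-optimum checks on single seeds;
large-n convergence checks at n = 20 000 (factor model) and n = 50 000
(5-node GGM). `analysis/05_network.py` defaults to B = 300 with the
full-scale B = 3000 behind a flag.

## Known limitations

- MCAR missingness and orthogonal factors only; no hierarchical (school /
  class) structure.
- The subscore-to-variable reduction (mean of orientation-aligned
  z-scores) is the simplest defensible rule; the original reduction is
  not documented, so it is isolated behind a configurable mapping.
- Likelihood-CV density and occurrence-rule liberality, as discussed
  above.
- Nonmetric MDS with very few points (e.g. 3 nodes) is under-determined;
  tied ranks may be pooled by the monotone regression.
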