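# Methods

This note documents the models and procedures implemented in `stockpriority`,
the defaults they use, and the choices made where the design was open.

## Data model

The analysis unit is the *collection*: all diploid multilocus genotypes from
one river in one year. Alleles are integer fragment lengths; `0` is missing,
and a genotype missing one allele is treated as wholly missing at that locus
(conservative, and the convention of the common desktop packages).
Rivers with several sampling years are pooled with
`pool_temporal_replicates` once temporal homogeneity has been established
(the AMOVA among-collection level is the check); all among-river statistics
operate on pooled rivers. GENEPOP is the interchange format (2- and 3-digit
dialects, auto-detected; mixed widths rejected).

## Diversity

* Unbiased expected heterozygosity uses Nei's small-sample correction
  H_E = 2n/(2n−1) · (1 − Σ p_a²).
* F_IS is the Weir–Cockerham single-population f computed from per-allele
  variance components (b, c) and combined as 1 − Σc/Σ(b+c) — a ratio of
  summed components, not a mean of ratios. Monomorphic loci are undefined
  (NaN), never 0.
* Rarefied allelic richness is the exact hypergeometric expectation
  R = Σ_a [1 − C(N−N_a, 2g)/C(N, 2g)] over 2g genes, evaluated with
  log-binomials to avoid overflow; `g` counts standard diploid individuals,
  so the subsample is 2g genes. Defaults follow the published standard of
  g = 24 (alewife) / 26 (blueback) when sample sizes allow.

## Conformance screens

HWE and LD tests are Monte-Carlo exact tests rather than Markov-chain exact
tests: the null is identical (condition on allele counts), and a permutation
scheme is directly verifiable against brute-force enumeration on tiny tables.
Default 9999 permutations, seeded; p = (b+1)/(n_perm+1) (add-one smoothing, so
p ≥ 1/(n_perm+1) always). The HWE statistic is Levene's conditional
probability of the genotype array; a one-sided heterozygote-deficit variant is
available because field departures at microsatellites are almost always
deficits (null alleles). The LD statistic is the G (log-likelihood-ratio)
statistic of the two-locus genotype table, permuting one locus across
individuals. Families of simultaneous tests are corrected by Holm sequential
Bonferroni; the family is an explicit argument (the published analyses used
families of 20, 1100 and 1560 tests whose exact grouping is not recoverable,
so no grouping is hard-wired).

For the lnRV/lnRH screen, fragment lengths are converted to repeat numbers as
(length − min observed length)/repeat-unit length, since no size-to-repeat
map is published; lnRV = ln(V1/V2) of repeat-number variances and
lnRH = ln[((1/(1−H1))²−1)/((1/(1−H2))²−1)] per population pair, averaged over
pairs and standardized across loci; |z| > 1.96 flags a locus. Pairs with
H ∈ {0, 1} or zero variance are excluded for that locus.

## Differentiation

θ is the Weir–Cockerham (1984) estimator with the full unequal-sample-size
coefficients (n̄, n_c), summed over alleles and loci before the ratio is
taken. Small negative estimates are retained, not clamped. Pairwise
significance (optional) permutes individuals between the two rivers.

θ′ (standardized F′_ST) divides θ by θ_max, computed by recoding allele codes
with a per-population offset so no allele is shared between populations while
within-population frequencies are untouched. The global θ′ uses whole-dataset
recoding (every river gets its own allele space); the published global values
do not state their recoding scheme, so this choice is documented rather than
assumed to match.

Genic tests permute pooled gene copies across populations and use the G
statistic on the alleles × populations table; per-locus p-values are combined
by Fisher's method (−2Σln p, χ² with 2L df; Monte-Carlo p-values carry
add-one smoothing so ln 0 cannot occur). A χ² variant of the per-locus test
exists and is what the power simulation uses (drift-based power assessment is
conventionally χ²-based, and it keeps hundreds of replicates tractable).

AMOVA uses the count of non-shared alleles between two diploid genotypes
(0/1/2 per locus, summed) as the squared inter-individual distance — the
standard choice for unordered microsatellite alleles — and the classical
nested sums-of-squares decomposition with unequal-size coefficients.
Permutation tests: Φ_CT permutes whole rivers among groups, Φ_SC individuals
among rivers within groups, Φ_ST individuals among all rivers.

The power simulation drifts each population independently from shared base
frequencies for t generations with t chosen so the expected
F_ST = 1 − (1 − 1/(2N_e))^t matches the target (binomial/multinomial gamete
sampling, N_e = 1000 by default), then samples diploids and runs the combined
genic test. At target 0 the rejection rate is the realized α.

## Clustering

The admixture Gibbs sampler updates, per sweep: allele-copy origins
z | q, P (categorical); cluster allele frequencies P | z (Dirichlet
posterior); admixture vectors q | z (Dirichlet(α + counts)); and α by a
log-normal Metropolis step with a Uniform(0, 10) prior. The correlated
(F-model) prior links each cluster's frequencies to ancestral frequencies
with per-cluster drift parameters, both updated by Metropolis; the
independent-frequency model is the default for tests because it mixes
considerably faster at these problem sizes. lnPr(X|K) is estimated from the
thinned post-burn-in trace as mean(lnL) − var(lnL)/2.

Label switching is resolved after sampling (Hungarian assignment on cluster
frequency profiles, or on the confusion matrix against truth labels when
computing recovery accuracy); the sampler itself carries no identifiability
constraint.

K selection reports both criteria: ΔK = mean(|L(K+1) − 2L(K) + L(K−1)|)/SD(L(K))
over ≥3 replicate runs, and a likelihood-plateau rule (smallest K after which
the mean lnPr gain no longer exceeds the replicate SD). When they disagree
the result carries an explicit flag; nothing is silently auto-selected. The
hierarchical scan re-runs K selection inside each top-level cluster's member
rivers and uses the plateau rule, because ΔK is undefined at the boundary and
cannot return K = 1 — the expected answer for a homogeneous stock.

Desk-scale MCMC defaults are used throughout the tests and drivers: burn-in
300–500 sweeps, 600–1500 kept sweeps, 3 replicates, K ∈ 1..5. These are about
two orders of magnitude below the published run lengths; on the synthetic
data used here (strong stock signal, 150–450 individuals, 12 loci) chains
equilibrate within tens of sweeps and ΔK recovery is stable across seeds.
Longer runs remain available through the function arguments.

PCoA double-centers −D²/2 and eigendecomposes; percent variation is reported
over positive eigenvalues only, and a degenerate (all-zero) matrix is flagged
rather than ordinated.

## Isolation by distance

The marine distance engine is 8-neighbour Dijkstra over ocean cells of a
boolean raster, with each step weighted by the great-circle distance between
cell centres (so longitude steps shrink with cos latitude). Dijkstra was
chosen over fast-marching because it is exactly testable against an
independent oracle; the 8-neighbour discretization overestimates true
geodesics by at most ~8% (path angles are quantized to 45°), which cancels in
rank-based IBD inference. River mouths snap to the nearest passable cell
within 3 cells. Mantel tests permute rows and columns of one matrix
simultaneously; the default tail is one-sided for positive association (the
IBD hypothesis), and the IBD slope is the OLS slope of linearized θ′ on
distance in km.

## Trends

Theil-Sen slopes are the median of all pairwise slopes (duplicate-year
records are rejected at ingestion). Mann-Kendall uses the tie-corrected
variance of S; for n ≤ 10 without ties the exact null distribution of S is
computed from the inversion-count generating function, otherwise the normal
approximation with continuity correction applies. Trend categories are the
five-way classification: sign of the Theil-Sen slope × two-sided p vs 0.05,
with "no change" meaning a slope of exactly 0 (|slope| < 1e−12).

Run-size series are z-score normalized (sample SD, n−1) before slope
estimation, making slopes dimensionless; mean-length slopes stay in raw
units/yr. This matches the prioritization thresholds: −0.05/yr is only
meaningful in normalized units. Sexes are analyzed as separate series with a
pooled option.

Slope comparisons are ordinary fixed-effects linear models (type-II F tests)
with Tukey-Kramer pairwise comparisons, valid under unequal group sizes.

## Prioritization

`classify_variable` is a step function: slope > 0 → low,
cut < slope ≤ 0 → medium, slope ≤ cut → high, with cuts −0.75 (mean length)
and −0.05 (normalized run size). `merge_designations` is the join on the
ordered lattice low < medium < high (commutative, associative, idempotent):
whenever a river or stock has several designations, the most protective wins.
Where a river has separate male/female slopes, the same precautionary join
applies across sexes. Stock designations average all member series slopes per
variable before classifying. Rivers without genetic sampling are attached to
the stock of the nearest sampled river (along-coast distance when a grid is
available, else great-circle; exact ties go to the more northern neighbour,
with a warning). Case-specific upgrades are explicit, logged overrides —
never hidden logic. A quantile-based threshold finder
(`quantile_thresholds`) reproduces the "split the declining series roughly in
half" construction of the published cuts, but the printed −0.75/−0.05 are the
defaults.

## Synthetic data

The genotype generator is a two-level Dirichlet F-model: ancestral
frequencies ~ symmetric Dirichlet; stock frequencies ~
Dirichlet(p·(1−F_stock)/F_stock); river frequencies ~
Dirichlet(p_stock·(1−F_river)/F_river); genotypes drawn under HWE. Defaults —
3 stocks × 5 rivers, 12 loci, 8 alleles, F_stock = 0.10, F_river = 0.01,
2% missing — give a global θ of a few percent and clearly separable stocks,
the structure the pipeline assumes. The generator was chosen over coalescent
simulation because the pipeline tests estimators, not genealogies, and the
F-model has closed-form expectations.

What it does **not** emulate: null alleles and scoring artifacts, stepwise
mutation (allele sizes are exchangeable labels except in the lnRV screen),
temporal drift between sampling years, clinal within-stock geography, and
family structure. Passing tests therefore demonstrate estimator and pipeline
correctness under the assumed model, not robustness to those real-data
pathologies.

Time series are linear trends with AR(1) noise and optional missing years;
the coastline is a land half-plane with a random-walk edge, mouths spaced
south to north. All generators are deterministic under their seed, and every
derived seed stays below 2³¹.

## Known limitations

* The published headline values (global θ′ = 0.119/0.067, Mantel r =
  0.73/0.71, K = 3/4) depend on the unreleased genotype dataset and cannot be
  recomputed; the package validates the machinery on synthetic data instead.
* The direct tally of the published alewife priority column (6/23/16 over 45
  rivers) differs from the narrative totals (6/23/15); the package reports
  its own tally and does not reconcile the two.
* One clustering engine is implemented; the published cross-check against a
  second (mixture-model) engine is out of scope.
* The sampler's mixing diagnostics are limited to the replicate-SD plateau
  check; pathological non-mixing at much larger K is not auto-detected.
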