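# Methods

This note documents the models, algorithms and numerical choices behind
`gpqtl`, and what the synthetic benchmark does and does not establish.

## Cross simulation

A pseudo-F1 progeny descends from two heterozygous parents; at a
fully-informative (abxcd) marker the transmitted maternal (a/b) and
paternal (c/d) haplotypes are unambiguous, so offspring genotypes are
complete observations of both meioses.  The simulator draws each parental
allele sequence along a chromosome as a two-state Markov chain whose switch
probability between adjacent markers is the Haldane recombination fraction
`r = (1 - exp(-2d/100))/2` of their cM distance `d`.  Haldane (no
crossover interference) was chosen because it makes the two-point formulas
used throughout — progeny simulation, the genotype-probability bridge, and
LD decay — mutually exact for a Markov meiosis model.

Default map shape: 19 chromosomes, 3,961 markers (nine chromosomes carry
209 markers and ten carry 208), 80 cM and 20 Mb per chromosome, markers
equidistant (uniform-random spacing available).  The real population the
benchmark emulates fixes only the totals (188 offspring, 3,961 markers, 19
chromosomes); per-chromosome counts and lengths are this package's own
defaults.  Physical positions are cumulative gamma increments rescaled to
the chromosome length, which makes the cM-to-bp relation random but
strictly monotone — enough to exercise the loess conversion.  All
randomness flows through seeded generators; replicate `i` of a study uses
`base_seed + i`.

## Design encoding

Each marker contributes eight predictor columns: additive counts of the
a, b, c, d alleles (each 0/1, summing to 2 per offspring) and indicators
of the four genotype classes (summing to 1).  The blocks are deliberately
redundant (rank at most 4 per marker): every parental allelic effect stays
explicitly representable and the penalties absorb the collinearity.  The
encoding convention itself (allele counts + class indicators) is a design
choice; only the column count p = 8m is externally fixed.  Dose codings
(0/1/2, count of allele a plus allele c) exist for LD computation and PVE
regressions only.

## Trait simulation

Traits follow Y = XB + E.  For the "same" layout the 4s additive rows at
the s shared QTL markers are i.i.d. k-variate normal with covariance
V_B = [[s1^2, rho_B s1 s2], [rho_B s1 s2, s2^2]]; for "diff" each trait
has its own disjoint s markers with independent N(0, sigma_B^2) effects,
so between-trait genetic correlation exists only under "same".  Dominance
rows are always zero.  QTL markers are sampled uniformly over the whole
map, not stratified by chromosome.

The error variance is deduced per replicate and per trait from the
*realized* sample variance of the genetic values,
`sigma_E^2 = var(g) (1 - h2) / h2`, so every replicate hits its target
heritability in expectation regardless of the effects drawn; deducing from
the expected variance (s·sigma_B^2 scaled) would let heritability drift
with the luck of the draw.  Errors are row-i.i.d. k-variate normal with
correlation rho_E (0 by default).  Defaults mirror the benchmark's first
simulation set (rho_B = 0.8, sigma_B^2 = 0.1, h2 in {0.1, 0.2, 0.4, 0.8},
s in {2, 50}); the second set (s in {20, 200}, h2 = 0.1/0.5,
sigma_B^2 = 1, rho_B = 0.5) runs through the same code path, as do extra
QTL counts (100, 1000).

## Penalized regression

Objective, on the standardized scale (predictors scaled by population
standard deviation, responses centered, intercept unpenalized):

    (1/2n) ||Yc - Z beta||_F^2
      + lambda [ alpha P1(beta) + (1-alpha)/2 ||beta||_F^2 ]

with P1 the L1 norm (univariate) or the row-wise group L2 norm
(multi-task), so lambda is on the per-observation scale familiar from
penalized-regression tooling.  alpha = 0 is ridge, alpha = 1 LASSO/group
LASSO.  Multi-task methods select predictors jointly across traits but
allow different effect values per trait.

Solvers.  Ridge is exact: `beta = Z'(ZZ' + n lambda I)^{-1} Yc` via one
eigendecomposition of the n x n kernel, reused across the whole lambda
grid (a primal solve is used instead when p <= n, which is better
conditioned at tiny lambda).  L1-containing penalties use cyclic
coordinate descent with (group) soft-thresholding, compiled with numba;
the univariate update is the k = 1 case of the group update.  Convergence
stops when the largest coefficient change in a sweep falls below
`tol * max(1, max|beta|)` (default 1e-7 for single fits, 1e-3 inside
cross-validation where only the MSE ranking of tuning points matters —
measured accuracy is unchanged while tuning runs several times faster).
Paths are warm-started and screened with sequential strong rules; after
every fit the stationarity conditions are checked on all p predictors and
violators are re-admitted, so screening is a pure speed-up and the
returned solution satisfies the KKT conditions of the full problem.  The
unit tests verify the ridge closed form, the KKT conditions, the
alpha-limit equivalences (EN(0) = ridge, EN(1) = LASSO) and agreement
with an independent coordinate-descent implementation (scikit-learn) to
~1e-4 on small instances.

Tuning grids: lambda paths are log-spaced from lambda_max (the smallest
all-zero lambda, `max_j |z_j' yc| / (n alpha)`; group norm for
multi-task).  Default span is 4 decades with 100 points (500 for elastic
net, which also gets 20 equispaced alpha values); ridge, whose lambda_max
is unbounded, anchors its grid 10^3 above the L1 lambda_max and spans 7
decades.  Cross-validation picks the (alpha, lambda) minimizing mean CV
MSE, breaking ties toward the largest (sparsest) lambda; fold partitions
are seeded and shared across methods and traits.  Constant predictor
columns keep their position with coefficient 0 so column indexing never
shifts.

## Interval mapping

Because genotypes are complete and fully informative, the probability of
each genotype class between two flanking markers is an exact two-point
Markov bridge: `P(a at x | a at L, a at R) = (1-rL)(1-rR)/(1-rLR)` and so
on, with the class probability the product of the maternal and paternal
bridges.  The grid holds markers plus points every 0.1 cM by default;
inside cross-validation the scan is restricted to marker positions, where
the probabilities are exact indicators anyway.

The LOD score at a position is `(n/2) log10(RSS0/RSS1)` from Haley-Knott
regression of the trait on three of the four class probabilities plus an
intercept (the four sum to one; RSS is parameterization-invariant).
Perfect fits are capped at LOD 300 with a warning.  Significance uses
permutation of the trait vector (1000 permutations for stand-alone QTL
detection, 10 inside cross-validation), taking the empirical (1-FWER)
quantile of genome-wide maxima.

MIM greedily adds the position with the best penalized LOD
(`pLOD = LOD - penalty * nQTL`), sweeps backward drops, and refines
positions coordinate-wise, with randomized tie-breaking across restarts
(plain stepwise search is deterministic; restarts matter only when the
scan surface has near-ties).  Since only main effects are modelled, the
per-QTL penalty is the genome-wide single-scan permutation threshold — a
simplification relative to deriving it from a two-dimensional permutation
scan, which may make the search marginally more liberal.  Prediction from
an interval-mapping model is ordinary least squares of the trait on the
class probabilities at the selected positions (pseudo-inverse under rank
deficiency); an empty model predicts the training mean.

## Robust selection

Stability selection refits the LASSO (or multi-task group LASSO) path on
`n_subsamples` (default 100) random half-samples; a predictor's selection
probability is the fraction of half-samples where it is nonzero at any
lambda of the grid, and the threshold is 0.6 (univariate) or 0.7
(multi-task) by convention.  The mFDR estimate at lambda is
`EF = p * 2 Phi(-lambda alpha sqrt(n)/sigma_hat)` — the marginal-null
probability that a standardized predictor's score `|z_j' r / n|` clears
the active L1 threshold — divided by the selection count and clamped to
[0, 1], with `sigma_hat^2 = RSS/(n - S - 1)`; selection takes the
smallest lambda whose estimate stays below the level (10% by default).
mFDR is univariate only.  An orthogonal-design Monte-Carlo oracle checks
the estimator's calibration in the tests.

## Evaluation

Nested CV: outer k1 = 5 folds estimate performance; inner k2 = 5 folds on
each outer training set tune the method; partitions are seeded, shared
across methods and traits, and the leakage guard asserts that outer test
rows never enter a tuning call.  Metrics: Pearson and Spearman
correlation (reported as 0 with a flag when predictions are constant),
RMSPE, model efficiency `1 - SSE/SST`, and t-tests of intercept = 0 and
slope = 1 from regressing observations on predictions.  Accuracy on
simulated data is the correlation with the *true* genetic values.

ROC: a selection sweep varies one tuning parameter; a QTL counts as found
when any selected marker lies within 2 cM on its chromosome; false
positives are selected markers outside every window, with the number of
markers outside all windows as denominator; per-trait rates are averaged.
pAUC integrates the curve by trapezoid over FPR in [0, 0.1]: duplicate
FPRs collapse to their best TPR, a curve starting above FPR 0 is anchored
by a linear segment from (0, 0), and one ending short of 0.1 is extended
horizontally — observed sweeps rarely land exactly on the integration
bounds, so some anchoring convention is unavoidable.

Broad-sense heritability on a genotype-mean basis is computed as
`H2 = var_G / (var_G + var_GY/n_year + var_e/(n_year n_rep))` from
supplied variance components.  Trait clustering (used to split large
trait panels into groups for multivariate runs) is Ward hierarchical
clustering on per-trait standardized values cut at three groups; the
distance/linkage choice is this package's own, as is the loess span
below.

## Consensus QTLs

LD is the squared Pearson correlation of dose codings, computed within
chromosomes; the expansion threshold is the 95% quantile of all
within-chromosome pairwise values.  Expansion is a single pass (markers
in high LD with a selected marker), not a transitive closure, to avoid
chromosome-wide percolation.  A marker is highly reliable when selected
(post-expansion) by at least five distinct method labels or by both
EN.mFDR and MIM; expansion precedes the tally.  Each reliable marker
anchors a +/-3 cM window; overlapping windows merge (per trait and per
chromosome), bounds convert to physical coordinates via a lowess fit of
bp on cM (span 0.3) forced monotone by a cumulative maximum and evaluated
on a dense grid (linear interpolation below five markers, flagged), and
intervals overlapping across traits merge by physical union.  PVE per
trait is the adjusted R-squared of the trait on the centered dose codings
of all anchor markers, with the model degrees of freedom taken as the
predictor-matrix rank so aliased anchors do not inflate the adjustment.

## The benchmark grid and problem sizes

`gpqtl.study` re-runs the desk-scale benchmark: one synthetic 188 x 3,961
cross; trait pairs for every cell of {s = 2, 50} x {same, diff} x
{h2 = 0.1, 0.2, 0.4, 0.8}; seven methods (SIM, RR, LASSO, EN, MTV_RR,
MTV_LASSO, MTV_EN) under 5-fold outer CV.  The desk-scale defaults are 3
simulation replicates per cell, 3 inner folds, lambda paths of 8 points
over 2 decades (the customary lambda.min ratio of 0.01 for n << p) with
the saturated tail frozen once more than 1,000 predictors are active
(the cross-validation optimum in every cell sits well below that count,
so the cap only skips fits CV would never choose), elastic-net alpha in
{0.3, 0.7}, CV solver tolerance 1e-3, scans at
marker positions, and 10 permutations per training fold — chosen so the
whole grid runs in minutes on one CPU while preserving the orderings of
interest (interval mapping dominant with 2 major QTLs, shrinkage methods
dominant with 50 minor ones, accuracy rising in heritability, and a
best-cell accuracy near 0.98).  Standardizers and ridge kernels are
cached per training subset and shared across methods, which is valid
because fold partitions are common to all methods by design.

## What the synthetic benchmark does not show

The simulator produces clean, complete, fully-informative genotypes with
Gaussian traits, equidistant markers, no genotyping error, no missing
data, no dominance or epistatic variance, and no
genotype-by-environment structure.  Passing tests therefore validate the
statistical machinery and its relative method ordering under the stated
model — not performance on real populations, where partially informative
markers, imputation error, non-Gaussian residuals and shared environment
effects can change both accuracy levels and method rankings.  The
experimental-data stages of a real analysis (mixed-model BLUPs per trait,
map construction, genotype calling) are out of scope; the pipeline
consumes genotypic values directly.
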