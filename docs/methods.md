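# Methods

`kinscape` implements the statistical core of a landscape population-genetics
study design: determine whether a fragmented, non-migratory songbird
population is genetically subdivided, estimate the spatial scale of recent
dispersal from the geography of first-order relatives, and relate local
genetic diversity to the availability of suitable habitat. This note records
the models, the parameters that matter, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Genotype data and quality control

Genotypes are diploid microsatellite calls: per individual and locus an
unordered pair of positive integer allele codes, or missing (all-or-nothing
per call; the internal sentinel is a dedicated marker, never allele code 0).
GENEPOP files (2- and 3-digit dialects, `000`/`000000` missing) and a flat
CSV dialect (`locus_1`/`locus_2` columns) round-trip losslessly.

**Duplicate error rate.** Re-genotyped birds give a per-allele mismatch
proportion: mismatching alleles over compared alleles, skipping loci missing
in either replicate and ignoring within-call allele order. Empirical panels
of this kind report rates below 0.1%, which motivates the default genotyping
error rate ε = 0.001 used throughout.

**Hardy–Weinberg exact test.** The conditional (Levene) distribution of a
genotype table given its allele counts is

P(table) = n! · 2^H · ∏ᵢ nᵢ! / [(2n)! · ∏ᵢ≤ⱼ nᵢⱼ!],

with H heterozygotes. The p-value is the probability-method tail: the total
probability of tables no more probable than the observed one. Tables are
fully enumerated while their number stays below a cap (10⁶ by default);
otherwise a Markov chain over gene-copy pairings — uniform random
transpositions of a 2n-vector paired consecutively, which visits genotype
tables in proportion to their conditional probability — estimates the same
tail, with a batch-means standard error. The chain default is 10 000 burn-in
swaps and 100 batches × 5 000 iterations; the QC screen uses much shorter
chains (1 000 + 10 × 200) because a 0.05-level filter is insensitive to
Monte Carlo noise of ~0.01. Monomorphic tables return p = 1.

**Locus filter.** A locus is dropped when significant at α = 0.05 in at
least half of the aggregations (both knobs configurable). This
operationalizes "out of HWE across multiple localities"; no multiple-testing
adjustment is applied at the screen because the fraction-of-groups rule
already requires replication. A genotypic LD screen is provided as a
permutation test (G statistic of the joint genotype table, one locus
permuted within aggregation); it is a deliberate simplification of the
GENEPOP genotypic LD test.

## Diversity statistics

Per aggregation and locus: Ho is the heterozygote fraction; He = 1 − Σp²
(the biased estimator, matching common calculator defaults; the unbiased
(2n/(2n−1))·He is also emitted); F = 1 − Ho/He averaged over loci with
He > 0. Rarefied allelic richness uses the hypergeometric closed form
Ar = Σᵢ [1 − C(N−Nᵢ, g)/C(N, g)] with g defaulting to the smallest gene
count among compared groups. Pairwise relatedness is the symmetrized
Queller–Goodnight estimator with numerators and denominators summed over
loci before division; reference allele frequencies default to the pooled
dataset (sensible when the dataset forms a single genetic cluster), with a
per-aggregation alternative. Between-group differentiation is
Weir–Cockerham θ (negative estimates reported as estimated, optional floor
at zero). Isolation by distance is a Mantel test on the upper-triangular
elements: Z = Σxy, r = Pearson correlation, one-sided p from joint
row/column permutations with the add-one convention; the genetic matrix
defaults to linearized FST/(1−FST) with a raw-FST option.

## Population delimitation

Between two groups at one locus, the allele-count table is tested against
the multivariate hypergeometric null with the probability method, by full
enumeration when the table space is small and otherwise by iid sampling of
tables from the null (vectorized multivariate-hypergeometric draws; add-one
estimator; batch-means SE). Independent sampling replaces the conventional
Markov-chain walk deliberately: for this null an exact iid sampler exists,
is unbiased, and vectorizes. Per-locus p-values are floored at 10⁻⁴ and
combined with Fisher's method (−2Σln p against χ² with 2k df); the floor
keeps a single locus from dominating the combined test. Combined tests use
α = 0.01 per pair without multiple-test adjustment.

Two grouping modes are implemented. The default, **components**, runs one
pass of all pairwise combined tests and returns connected components of the
graph whose edges are non-significant pairs. The alternative, **pooled**,
merges the least-differentiated pair, pools genotypes, retests, and repeats
while the maximum pairwise p exceeds α. The pooled mode is provided for
comparison but is *not* calibrated: merging the most similar groups first
biases pooled allele frequencies apart, so with many null groups the
procedure stalls at several spuriously "distinguishable" pools (a selection
effect analogous to significance testing after clustering). On panmictic
simulations (18 groups × 15 birds, 19 loci) the components mode returns a
single population essentially always, and it separates two demes at
FST = 0.1 (n = 30/deme) essentially always. A helper drops one member of
each supported relative dyad (the one with more missing data; ties
lexicographic) for relatives-excluded reruns.

## Kinship classification

Pairs are classified among U, PO, FS, HS by IBD-coefficient likelihoods:
per locus, L = k₀P₀ + k₁P₁ + k₂P₂ with k = (1,0,0), (0,1,0), (¼,½,¼),
(½,½,0) respectively, and P_m the joint probability of the two genotypes
given m alleles shared identical by descent under HWE. Genotyping error is
integrated analytically — each observed allele is the true allele with
probability 1−ε, otherwise uniform over the locus's other alleles — by
conjugating the joint-probability matrices with the per-genotype error
matrix once per locus, so classifying a pair is a table lookup. Unseen
alleles receive a 10⁻⁴ frequency floor. Posteriors use a uniform prior over
the four categories; "first-order" is posterior(PO) + posterior(FS) because
the two are often pairwise-indistinguishable. A dyad is *supported* when
its first-order posterior exceeds 0.9 and it survives a greedy, seeded
sibship-refinement pass (pairs scanned in random order; two sib groups merge
when the summed first-order-vs-unrelated log-likelihood over cross pairs is
positive) in every one of three replicate scans. Identical genotype vectors
are flagged as duplicates and excluded.

This pairwise scheme replaces a full-pedigree sibship reconstruction and is
an approximation with known costs, measured by simulation on a 19-locus
panel with He ≈ 0.78 and ε = 0.001:

* FS-specific recall at the 0.9 threshold is ~0.75 (FS leaks posterior mass
  to HS without pedigree context); PO recall is ~0.98; mixed first-order
  recall is ~0.85. Full-pedigree methods report FS false-negative rates
  near 12–13% on comparable panels, so the pairwise FS cost is real but
  moderate.
* In a full dataset of ~270 individuals (~36 000 candidate pairs), a small
  per-pair false-positive rate (~10⁻⁴) yields a handful of borderline
  (posterior < 0.99) false dyads; the end-to-end false-discovery proportion
  at these sizes is ~0.15–0.2, versus ≤ 0.05 in the per-pair benchmark
  with equal numbers of true and negative pairs. Users who need a purer
  dyad list should raise the threshold or require posterior > 0.99.

The locus panel used in these benchmarks is held fixed (it represents the
study's empirical allele frequencies); seeds drive only the simulated
dyads and the error process.

## Effective population size

**LD method.** For each locus pair and allele pair, the Burrows composite
disequilibrium is estimated from dosages, Δ̂ = S/(S−1) · (mean(g_A g_B)/2 −
2p̂_A p̂_B), and squared over p_A(1−p_A)p_B(1−p_B). Alleles below the MAF
screen (default 0.01) are excluded. Allele-pair r̂² are averaged within a
locus pair and combined across locus pairs weighted by their number of
comparisons. The sampling expectation E[r²|S] = 1/S + 3.19/S² (S ≥ 30;
0.0018 + 0.907/S + 4.44/S² below) is subtracted and the drift signal
inverted via Ne = (1/3 + √(1/9 − 2.76·r²_drift))/(2·r²_drift); a
non-positive drift signal (or negative discriminant) returns ∞ with a flag.
Confidence intervals jackknife over locus pairs (the closest analogue of
jackknifing over loci that the estimator structure allows; flagged as an
approximation). On Wright–Fisher simulations with true Ne = 50, S = 50,
20 loci × 10 alleles, the median estimate over 100 replicates falls near 58
— within a ±30% band of truth — with the documented convention; exact
agreement with any particular program depends on its (undocumented) r̂²
weighting, which is why the convention here is spelled out and isolated.

**Sibship method.** Under random mating, 1/Ne = (2·Q̃_FS + Q̃_HS)/4 with Q̃
the observed supported sib-pair frequencies among all C(n,2) sampled pairs;
bootstrap over individuals gives the CI. With no observed sib pairs the
estimate is ∞.

## Habitat suitability

The partitioned Mahalanobis D² model scores each 150 m cell by the
similarity of its environment to the multivariate mean of conditions at
occurrence points. To keep densely surveyed regions from dominating, the
calibration occurrences (at most one per cell) are bootstrapped 1 000 times
with at most 50 points per geographic area per iteration; each iteration
standardizes the environmental values and takes a PCA of their correlation
matrix (correlation, not covariance, because the variables have mixed
units). Eigenvector sign ambiguity is resolved against the first
iteration's vectors; means, scales, eigenvalues and eigenvectors are
averaged over iterations and the eigenvectors renormalized. D² on a
component partition is Σ score²/λ; the default partition is the components
with averaged eigenvalue < 1 (the consistently "constrained" environmental
axes, following the partitioned-D² literature), falling back to all
components when none qualify. The D²→[0,1] rescaling is the chi-square
upper-tail transform with df = |partition| (HSI = 1 at the mean, strictly
decreasing in D²); it is isolated in one function because the rescaling
used by legacy implementations is not published, and a min–max alternative
can be swapped in. Suitability is HSI ≥ 0.5 (inclusive).

The synthetic landscape generator produces smoothed Gaussian random fields
as environment, a true suitability that decays with environmental distance
from an optimum, occurrences sampled proportional to that truth, and an
ocean margin of nodata. Because the truth is full-dimensional, recovery
benchmarks score with the all-components partition; they show the fitted
model ranks cells concordantly with truth (Spearman ρ ≈ 0.86–0.95) and
that occurrence cells score above background (Mann–Whitney p < 0.01). What
these tests do *not* show: performance under correlated or categorical
environmental layers, spatial sampling bias beyond the per-area cap, or
occurrence location error — all present in real survey data.

## Landscape distances

Friction is the inverse of HSI with HSI floored at 0.01 (friction cap 100),
so barren cells are traversable but strongly avoided; an option treats
HSI = 0 as impassable. Least-cost paths run Dijkstra on the 8-connected
cell graph with edge cost = mean friction of the two cells × center
distance (cell size; ×√2 diagonally), in meter-equivalents (equal to path
length where friction is 1). On a uniform surface the 8-connected metric
overestimates off-lattice Euclidean distance by at most the documented
factor ≈ 1.083. Same-cell queries return the straight within-cell distance.
Buffer summaries count cell centers within the radius; nodata (ocean) cells
are excluded from numerator and denominator. Rasters are ESRI ASCII with
nodata −9999, row 0 at the top, cell (0,0) center at (xll + 75, ytop − 75)
for 150 m cells.

## Diversity-vs-habitat regression

Highly correlated predictors (|r| > 0.7) are reduced to the most relevant
one per pair via a user-supplied relevance order. Moran's I with
row-standardized inverse-distance weights (normal-approximation p,
E[I] = −1/(n−1)) screens for spatial autocorrelation before latitude and
longitude are considered. The response (allelic richness) is fitted by OLS
against percent suitable habitat both linearly and as y = a + b·ln x (the
base of the logarithm only shifts the intercept); R², residual SE and the
prediction curve are reported, and model choice is left to diagnostics
rather than automated. On the bundled 18-aggregation gnatcatcher table the
logarithmic fit gives R² = 0.527 at the 30 km scale; the steep decline of
diversity below ~10% suitable habitat is a property of the fitted curve,
not a separately estimated breakpoint.

## Synthetic data

The generator's defaults mirror the study conditions: 18 demes × 15
individuals (≈ 270 birds), 19 loci with 10 alleles and Dirichlet(0.5)
ancestral frequencies (expected He ≈ 0.78), Balding–Nichols deme
frequencies at a target FST (0.02 by default — weak structure; the
empirical pairwise range is 0–0.089), genotyping error ε = 0.001, planted
first-order dyads by Mendelian transmission (cross-deme dyads emulate
dispersal), and a 100 × 100-cell, 150 m landscape with a 6-area occurrence
set. Everything is a deterministic function of the master seed, and fixture
bundles carry a manifest (seed + spec hash). A diploid Wright–Fisher
simulator (random mating, free recombination) supports the Ne benchmarks.

## Pipeline and problem sizes

`RunManifest` is the single configuration source — every threshold (HWE
α 0.05, merge α 0.01, p-floor 10⁻⁴, kin threshold 0.9, MAF 0.01, HSI
threshold 0.5), the buffer radii (5 and 30 km), bootstrap settings and one
seed per stochastic stage — written as flat `key = value` text, echoed into
the output directory, and hashed; stages whose outputs exist under the same
hash are skipped on rerun. The test suite and the acceptance script run the
calibration studies at 40–50 replicate datasets and 100 Wright–Fisher
replicates, sizes at which the binomial/median acceptance bands are already
narrow while a full run stays in the minutes range on one CPU.

## Known limitations

* The kinship classifier is pairwise; families larger than two are only
  weakly exploited by the greedy refinement, and FS/HS discrimination is
  the weakest link (see the measured error rates above).
* The pooled-agglomerative delimitation mode is uncalibrated by
  construction and should be used only for comparison with the default.
* LD-Ne confidence intervals jackknife over locus pairs, which
  underestimates between-locus dependence relative to a locus-level
  jackknife.
* The habitat model assumes continuous, jointly quasi-Gaussian
  environmental variables on one planar grid; no CRS handling.
* The Mantel and Moran tests use standard permutation/normal
  approximations; no spatially structured alternatives (SAR/CAR) are
  provided.
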