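# Methods

This note documents the statistical models, the numerical conventions, and
the design choices behind `poolscan`, in the spirit of the methods
documentation of estimator-heavy packages.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pooled sampling model

Pool-seq replaces genotypes with read counts.  Two layers of binomial
sampling separate a read count from the population allele frequency: the
pool draws `n = 2 × pool_individuals` chromosomes from the population, and
the sequencer draws `M` reads from the pool.  For a pool frequency `k/n`
the minor read count is `m ~ Binom(M, k/n)`, and a site is only *callable*
as a SNP when the minor count reaches the detection bound `b`.  All
diversity corrections and the synthetic generator use exactly this model;
its variance, `Var(m/M) = f(1−f)[(1−1/n)/M + 1/n]`, is verified against
simulation in the test suite.

## Diversity estimators

Let `A(n, M, b)` and `B(n, M, b)` be the double sums defined in
`poolscan.popgen` (neutral 1/k frequency weighting × binomial read
sampling × detectability `b ≤ m ≤ M−b`).  Under the neutral site-frequency
spectrum the expected number of *detected* SNPs per site is `θ·A` and the
expected detected raw heterozygosity is `θ·B`, so

* θ̂_W(window) = Σ_SNPs 1/A(n, M_site, b) / n_sites_covered
* π̂(window)  = Σ_SNPs raw_het_site / B(n, M_site, b) / n_sites_covered

are unbiased for the per-site scaled mutation rate.  The implementation is
checked to 1e−10 against an independent brute-force double summation, and
calibrated by infinite-sites neutral simulation (θ = 0.005/site, n = 72,
coverage 40, b = 2): both window means land within a few percent of truth.
Exact numerical parity with any particular external pooled-diversity tool
is *not* claimed; calibration is established by simulation instead.

Tajima's D uses the corrected window sums, `D = (π_sum − θ_sum)/√(e1·S +
e2·S(S−1))`, with Tajima's variance constants evaluated at the effective
sample size `n* = n(1 − ((n−1)/n)^M)` — the expected number of distinct
chromosomes hit by `M` reads — rounded to the nearest integer (floor 2).
D is only computed from sites at one fixed coverage (default 36 reads per
population) precisely so a single `n*` applies; sites at other coverages
are excluded.  On neutral simulations the window mean of D sits within
±0.05 of zero (the test asserts the looser ±0.3).

Average heterozygosity is the mean over SNPs of `2p(1−p)` with `p` the
major-allele read frequency, hence bounded by 0.5.

## SNP filter sets

Three named filter sets mirror standard pooled-scan practice:

| set        | per-pop MAC | per-pop coverage | pooled MAC | pooled coverage |
|------------|------------|------------------|-----------|-----------------|
| diversity  | 2          | 10–500           | 4         | 20–1,000        |
| fst_scan   | –          | 10–500           | 4         | –               |
| subset     | –          | 36–500           | 6         | –               |

"Pooled" quantities sum counts across all populations; the subset rule's
coverage bound is applied per population (every population must lie in
36–500), matching the stringent-subset convention.  Sites are reduced to
their two most frequent pooled alleles; ties are broken by the fixed order
A < T < C < G so calls are deterministic and order-free.

## F_ST

The per-SNP estimator is the conventional heterozygosity-ratio form with
`M/(M−1)` small-sample factors and the *unweighted* mean of the two
population frequencies for the total — consistent between the per-SNP and
ratio-of-sums window forms.  Negative values (identical frequencies at
finite coverage) are retained; truncation would bias window and matrix
means upward, and the outlier rule only uses upper tails.  Window F_ST is
Σ(π_total − π_within)/Σπ_total over SNPs in non-overlapping 100-kb windows
tiled from coordinate 1.

Empirical outliers: for each pair the tail is every SNP whose F_ST strictly
exceeds the value at rank ⌈(1−q)L⌉ of that pair's sorted values (q = 0.005
by default); ties at the threshold are excluded, which makes the rule
deterministic, order-free, and checkable by brute force.  When `qL < 1`
the tail is empty and a warning is logged.  A SNP is a consensus outlier
when it falls in the tails of at least 5 pairs.

## Bayesian outlier model

Effective allele counts bridge pooled reads to the genotype world:
`n_eff = round(n·M/(n+M))` (both sampling layers contribute ≈ binomially
with these denominators) and `a = round(minor_freq · n_eff)`.  The model is

    a_ij ~ BetaBinomial(n_eff_ij, p_i θ_ij, (1−p_i) θ_ij),
    θ_ij = (1−FST_ij)/FST_ij,   logit(FST_ij) = α_i + β_j

with priors `p_i ~ U(0,1)`, `β_j ~ N(−1, 1)`, and `α_i ~ N(0, 3²)` included
with prior probability `1/(1+prior_odds)` (default odds 100).  The sampler
combines vectorized random-walk Metropolis updates of `p` and included `α`,
a reversible-jump toggle that uses the prior as the birth proposal (so the
acceptance ratio reduces to likelihood ratio × prior odds), and
per-population updates of `β`.  Proposal scales are tuned during pilot runs
toward 0.25–0.45 acceptance.  The default configuration carries the
standard settings for this model class (55,000 total iterations, burn-in
50,000, thinning 10, 20 pilot runs of 5,000); tests and the acceptance
script use a scaled-down chain (5 pilots × 400, burn-in 2,000, 7,000 total,
thinning 10 — still 500 retained samples), which the simulations show is
enough for stable flagging at the default problem size of ~500 loci.

Flagging uses the Bayesian q-value: sort loci by decreasing posterior
inclusion probability; the q of the top-k set is its mean (1−PIP); each
locus takes the minimum over sets containing it; flag at q ≤ 0.05.  The
sign of the posterior-mean α labels flagged loci directional (α > 0) or
balancing (α < 0).

## Environmental association

The across-population covariance Ω is estimated from neutral loci as
`Ω̂ = (1/L) Σ_l x_l x_lᵀ` with `x_lj = (f_lj − f̄_l)/√(f̄_l(1−f̄_l))`,
symmetrized and PSD-projected; boundary frequencies are shrunk by half a
count so the scaling stays finite.  Because the outlier flags do not
depend on Ω, "neutral" is resolved by one iteration: a provisional Ω from
all loci → flag (outlier routes and provisional Bayes factors) → final Ω
from unflagged loci.

Given standardized environmental values `e`, the effect model
`x ~ N(βe, Ω)`, `β ~ N(0, τ²)` is linear-Gaussian, so the Bayes factor has
the closed form `(1+τ²A)^{−1/2} exp(τ²B²/(2(1+τ²A)))` with
`A = eᵀΩ⁻¹e`, `B = eᵀΩ⁻¹x` (ridge 1e−6 on Ω).  Computing it exactly makes
the statistic deterministic and testable — the quadrature oracle agrees to
better than 1e−6 relative — and the conventional three "replicate runs"
are retained only for interface parity (they are identical; the median is
reported).  τ defaults to 1 on the standardized scale and is exposed.

## Structure and annotation

PCoA is classical scaling of −½·J·D²·J; axes with positive eigenvalues are
retained and negative eigenvalues reported unused (a Lingoes correction is
available as a flag but off by default, so coordinates reflect the raw
matrix).  Neighbor joining follows Saitou–Nei with deterministic tie-breaks;
a negative branch length is clamped to zero and its deficit moved to the
sibling edge of the join (for the final three-way join, to the longest
remaining edge), preserving total path length.  Bootstrap support resamples
loci (not populations) with replacement and reports the percentage of
replicates containing each internal bipartition of the point tree.

The Mantel test correlates off-diagonal upper triangles with
`p = (1 + #{permuted r ≥ observed})/(n_perm + 1)` (default 9,999
permutations, configurable).  Isolation-by-distance defaults to linearized
F_ST against log great-circle distance computed from the metadata
coordinates; a waterway or other custom distance matrix can be supplied
instead, and no attempt is made to reproduce any particular published IBD
coefficient, since the published analyses' distance convention is not
fixed by the data shipped here.

SNP→gene assignment is inclusive interval containment (1-based); BED input
is converted from half-open 0-based on read; overlapping or nested genes
each receive the SNP.  GO enrichment is the two-sided exact hypergeometric
(Fisher) test per term — matching tail enumeration exactly for all margins
tested — with Benjamini–Hochberg adjustment across terms, candidates being
genes hit by intersection outliers or associated SNPs and the background
the genes hit only by the remaining neutral SNPs.

## Synthetic seascape generator

The generator's defaults *are* the study conditions the pipeline assumes:
10 pools of 36 diploids with the bundled Baltic salinity/temperature
gradient; 500 neutral loci at Balding–Nichols c = 0.02 (low genome-wide
differentiation of a few percent); 20 divergent loci at c = 0.4; 40
environment-associated loci with effect 1.5 on the logit scale applied on
top of a neutral draw (so they keep realistic dispersion); Poisson
coverage with mean 50 per population (a gamma-Poisson overdispersion knob
exists but is off by default); sequencing error 0.002 flipping reads to a
uniformly chosen other base.  Balding–Nichols was chosen over coalescent
simulation because its F_ST has a closed expectation, giving every
estimator an analytic recovery target; loci are laid out on 1,500-bp
spacing across 210-kb chromosomes so 100-kb windows hold ~70 loci.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: linkage and haplotype structure (loci are
independent), RAD locus dropout and restriction-site polymorphism,
demographic history (bottlenecks, expansion, migration asymmetries),
reference bias, and mapping artefacts.  The generator also emits only
candidate variable sites, not invariant genome, so per-covered-site
diversity in simulated runs is far higher than genome-wide values from real
data; diversity *calibration* instead uses the infinite-sites neutral
simulator, which does model invariant sites.

## Numerical conventions and edge cases

* All coordinates are 1-based inclusive internally; windows tile from
  position 1; a trailing partial window is reported with its true span and
  flagged.
* Reads shorter than the 90-bp trim length are discarded (reason
  `too_short`) rather than padded; the >5% low-quality fraction rule uses
  strict inequality; ambiguous (N) bases count as failing any quality
  threshold — how such bases were treated upstream is genuinely ambiguous,
  and this is the conservative reading.
* mpileup indel encodings contribute neither nucleotide nor deletion
  counts (deletions come only from `*`), keeping counts interpretable.
* Undefined statistics (zero-SNP windows for D, π_total = 0 for F_ST) are
  NaN, never errors; structurally impossible requests (window ≤ 0, M < 2b,
  < 3 taxa) raise.
* Every stochastic component takes an explicit seed and uses a dedicated
  `numpy` generator; identical configuration and seeds reproduce
  byte-identical files, which the pipeline manifest certifies by SHA-256.

## Problem sizes

Simulation studies use sizes chosen to make Monte-Carlo error small
relative to the asserted tolerances: ≥5,000 loci for F_ST calibration,
80 windows of 100 kb for θ/π calibration, 250 windows for Tajima's D, the
560-locus default seascape for recovery, and 1,000 random instances for
the Bayes-factor oracle.  Chain lengths for the Bayesian model are the
scaled-down configuration described above.

## Known limitations

* The pooled corrections assume the neutral frequency spectrum; under
  strong selection or rapid demographic change the diversity estimators
  are calibrated only in the sense of the neutral baseline.
* The beta-binomial outlier model treats populations as exchangeable given
  β and ignores spatial autocorrelation; the covariance-controlled Bayes
  factor handles shared structure for association but not for outlier
  flagging.
* The closed-form Bayes factor conditions on a point estimate of Ω rather
  than integrating over its uncertainty.
* Consensus tails require `q·L ≥ 1` per pair to be non-empty; with few
  hundred loci the empirical route is intentionally conservative.
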