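# poolscan

Pooled-sequencing (pool-seq) population genomics for seascape surveys:
pool-corrected diversity statistics, windowed pairwise F<sub>ST</sub> scans
with dual (empirical + Bayesian) outlier detection, covariance-controlled
environmental association, population-structure summaries, and gene/GO
annotation — with a synthetic seascape generator that provides labelled
ground truth for every stage.

The package targets the analysis design of low-differentiation marine
systems such as Baltic Sea three-spined sticklebacks: ~10 pooled population
samples (36 diploids each) distributed along steep salinity and temperature
gradients, genotyped by pooled RAD-seq, with genome-wide mean pairwise
F<sub>ST</sub> of only a few percent and a minority of loci showing
selection or environment-tracking allele frequencies.  It is written for
population geneticists who have pooled allele counts (mpileup or sync text)
plus sampling metadata and want the full scan as a reusable, tested
pipeline rather than a chain of one-off tools.

## Models and statistics

**Pool-corrected diversity.**  With `n` chromosomes in a pool, site
coverage `M` and a minor-allele detection bound `b`, each detected SNP
contributes `1/A(n,M,b)` to θ̂<sub>W</sub> and its raw sample
heterozygosity divided by `B(n,M,b)` to π̂, where

    A = Σ_{k=1}^{n−1} (1/k) · P(b ≤ m ≤ M−b),        m ~ Binom(M, k/n)
    B = Σ_{k=1}^{n−1} (1/k) · E[2m(M−m)/(M(M−1)) · 1{b ≤ m ≤ M−b}]

so both are unbiased for the per-site scaled mutation rate under the
neutral site-frequency spectrum.  Tajima's D is computed from the corrected
window sums at uniform coverage, with the pool size replaced by the
expected number of distinct chromosomes sampled.

**F<sub>ST</sub>.**  The heterozygosity-ratio estimator with small-sample
factors, `FST = (π_total − π_within)/π_total`, per SNP and as ratio of sums
in 100-kb windows; negative values are retained so averages stay unbiased.

**Outlier detection.**  Empirical route: SNPs in the upper 0.5% tail of at
least 5 of the 45 pairwise comparisons.  Bayesian route: a reversible-jump
MCMC decomposition `logit(FST_ij) = α_i + β_j` with beta-binomial read
likelihood, prior odds 100 against selection, and flagging by Bayesian
q-value at FDR 0.05.  Only SNPs flagged by both routes count as truly
differentiated.

**Environmental association.**  Population structure is controlled through
the covariance Ω of standardized allele frequencies estimated from neutral
loci; each locus × variable gets a closed-form log10 Bayes factor under
`x ~ N(βe, Ω)`, `β ~ N(0, τ²)`, with association called at log10 BF > 1.5
and > 5.

**Structure and annotation.**  PCoA (classical scaling), neighbor joining
with locus bootstrap, Mantel tests for isolation by distance (linearized
F<sub>ST</sub> vs log distance), interval SNP→gene annotation, and exact
hypergeometric GO enrichment with Benjamini–Hochberg adjustment.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic seascape (560 loci: 500 neutral at c = 0.02, 20 divergent at
c = 0.4, 40 environment-associated at logit effect 1.5; 10 pools of 36
diploids at mean coverage 50×):

```bash
python analysis/01_simulate_seascape.py
python analysis/02_diversity_windows.py
python analysis/03_fst_scan.py
python analysis/04_outlier_detection.py
python analysis/05_env_association.py
python analysis/06_structure_annotation.py
```

Output of the outlier and association stages (seed 11):

```
560 SNPs under the FST filter set
mean windowed pairwise FST: 0.04191
481 SNPs under the stringent subset filter
in ≥1 tail: 21; consensus (≥5 pairs): 8; Bayesian FDR 0.05: 39; intersection: 8
divergent-class sensitivity (Bayesian): 0.88 of 16 planted
realized false-discovery proportion: 0.000
salinity: 31 SNPs at log10 BF > 1.5, 11 at > 5
temperature: 30 SNPs at log10 BF > 1.5, 12 at > 5
environment-class ranking AUC vs neutral: 0.999
IBD Mantel (linearized FST vs log km): r = 0.503, p = 0.0007
```

The Bayesian scan recovers 14 of the 16 planted divergent loci that survive
the stringent filter with no neutral false positives, and the Bayes-factor
ranking separates environment-associated from neutral loci almost
perfectly.  The isolation-by-distance signal arises because the
environment-tracking loci follow the (spatially structured) salinity and
temperature gradients.  A single-command equivalent is available as
`poolscan run-all --config <yaml>`, and each stage as its own subcommand
(`simulate`, `filter`, `diversity`, `fst`, `outliers`, `envassoc`,
`structure`, `annotate`).

The package also ships the published ten-population Baltic survey tables
(sampling metadata and the 10×10 mean pairwise F<sub>ST</sub> matrix) as
bundled fixtures; the matrix worked example gives a pairwise range of
0.00864 (FOR–KAS) to 0.01548 (MAR–PJM) over the 45 pairs.

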