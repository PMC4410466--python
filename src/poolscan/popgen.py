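"""SNP calling from pooled counts and pool-corrected diversity statistics.

Pooled sequencing replaces genotypes with read counts, so the classical
estimators of nucleotide diversity (π), Watterson's θ and Tajima's D must be
corrected for two layers of sampling: reads are drawn binomially from the
pool allele frequency, and a site is only *detectable* as a SNP when the
minor allele appears in at least ``b`` reads.  Writing ``n`` for the number
of chromosomes in the pool and ``M`` for the site coverage, the correction
factors are

    A(n, M, b) = Σ_{k=1}^{n-1} (1/k) · P(b ≤ m ≤ M−b),   m ~ Binom(M, k/n)
    B(n, M, b) = Σ_{k=1}^{n-1} (1/k) · E[2m(M−m)/(M(M−1)) · 1{b ≤ m ≤ M−b}]

so that under the neutral site-frequency spectrum each detected SNP
contributes 1/A to θ̂_W and (raw sample heterozygosity)/B to π̂, both
unbiased for the per-site scaled mutation rate.  This is the correction
family used by pooled-sequencing diversity pipelines; calibration is
established by simulation (see the test-suite and methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SiteCounts

#: column order of nucleotide counts; doubles as the allele tie-break order
NUCLEOTIDES = ("A", "T", "C", "G")


@dataclass(frozen=True)
class SiteFilterConfig:
    """Coverage and minor-allele-count thresholds defining analyzable sites."""

    min_minor_count_pop: int = 2
    cov_min_pop: int = 10
    cov_max_pop: int = 500
    min_minor_count_total: int = 4
    cov_min_total: int = 20
    cov_max_total: int = 1000
    min_base_q: int = 20

    def __post_init__(self):
        if self.cov_min_pop > self.cov_max_pop:
            raise ValueError("cov_min_pop > cov_max_pop")
        if self.cov_min_total > self.cov_max_total:
            raise ValueError("cov_min_total > cov_max_total")
        if min(self.min_minor_count_pop, self.min_minor_count_total) < 0:
            raise ValueError("minor-allele counts must be non-negative")

    @classmethod
    def diversity(cls) -> "SiteFilterConfig":
        """Genome-wide π/θW set: per-pop MAC 2, cov 10–500; pooled MAC 4,
        pooled cov 20–1,000."""
        return cls()

    @classmethod
    def fst_scan(cls) -> "SiteFilterConfig":
        """Genome-wide FST set: pooled MAC 4, per-pop cov 10–500."""
        return cls(min_minor_count_pop=0, cov_min_pop=10, cov_max_pop=500,
                   min_minor_count_total=4, cov_min_total=0,
                   cov_max_total=10**9)

    @classmethod
    def selection_subset(cls) -> "SiteFilterConfig":
        """Stringent subset for outlier detection: pooled MAC 6, coverage
        36–500 in every population."""
        return cls(min_minor_count_pop=0, cov_min_pop=36, cov_max_pop=500,
                   min_minor_count_total=6, cov_min_total=0,
                   cov_max_total=10**9)


def _rank_alleles(pooled: np.ndarray) -> np.ndarray:
    """Order the four nucleotide columns by descending count, ties broken
    by the fixed order A < T < C < G (the column order itself)."""
    return np.lexsort((np.arange(4), -pooled))


def call_snps(sites: Iterable[SiteCounts], cfg: SiteFilterConfig) -> pd.DataFrame:
    """Call biallelic SNPs across populations.

    A site is a SNP when, after pooling counts across populations, at least
    two alleles are observed, the pooled minor (second most frequent) allele
    count is ≥ ``min_minor_count_total``, the pooled coverage lies within the
    total bounds, and every population's coverage lies within the per-
    population bounds.  Reads supporting third/fourth alleles are dropped.

    Returns a DataFrame with one row per SNP: chrom, pos, major, minor
    (allele characters) and ``major_counts``/``minor_counts`` (per-population
    integer arrays).
    """
    rows = []
    for site in sites:
        acgt = site.counts[:, :4]
        pop_cov = acgt.sum(axis=1)
        if (pop_cov < cfg.cov_min_pop).any() or (pop_cov > cfg.cov_max_pop).any():
            continue
        pooled = acgt.sum(axis=0)
        total_cov = int(pooled.sum())
        if not cfg.cov_min_total <= total_cov <= cfg.cov_max_total:
            continue
        order = _rank_alleles(pooled)
        maj, mnr = order[0], order[1]
        if pooled[mnr] < max(cfg.min_minor_count_total, 1):
            continue
        if (pooled > 0).sum() < 2:
            continue
        rows.append((site.chrom, site.pos, NUCLEOTIDES[maj], NUCLEOTIDES[mnr],
                     acgt[:, maj].copy(), acgt[:, mnr].copy()))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "major", "minor", "major_counts",
                       "minor_counts"]
    )


def call_snps_per_population(
    sites: Iterable[SiteCounts], cfg: SiteFilterConfig
) -> tuple[list[pd.DataFrame], list[pd.DataFrame]]:
    """Per-population SNP calls and covered-site tables for diversity windows.

    For population ``j`` a site is covered when its coverage lies within the
    per-population bounds and the pooled coverage within the total bounds;
    it is a SNP for ``j`` when additionally the population's own second
    allele count is ≥ ``min_minor_count_pop`` and the pooled minor count is
    ≥ ``min_minor_count_total``.

    Returns ``(snps, covered)``: two lists (one entry per population) of
    DataFrames with columns (chrom, pos, major_count, minor_count) and
    (chrom, pos, coverage) respectively.
    """
    snp_rows: list[list[tuple]] = []
    cov_rows: list[list[tuple]] = []
    n_pops: int | None = None
    for site in sites:
        if n_pops is None:
            n_pops = site.n_populations
            snp_rows = [[] for _ in range(n_pops)]
            cov_rows = [[] for _ in range(n_pops)]
        acgt = site.counts[:, :4]
        pop_cov = acgt.sum(axis=1)
        pooled = acgt.sum(axis=0)
        total_cov = int(pooled.sum())
        total_ok = cfg.cov_min_total <= total_cov <= cfg.cov_max_total
        order = _rank_alleles(pooled)
        pooled_minor_ok = pooled[order[1]] >= cfg.min_minor_count_total
        for j in range(n_pops):
            if not (cfg.cov_min_pop <= pop_cov[j] <= cfg.cov_max_pop and total_ok):
                continue
            cov_rows[j].append((site.chrom, site.pos, int(pop_cov[j])))
            own = np.sort(acgt[j])[::-1]
            if own[1] >= max(cfg.min_minor_count_pop, 1) and pooled_minor_ok:
                snp_rows[j].append((site.chrom, site.pos, int(own[0]), int(own[1])))
    snp_cols = ["chrom", "pos", "major_count", "minor_count"]
    cov_cols = ["chrom", "pos", "coverage"]
    return (
        [pd.DataFrame(r, columns=snp_cols) for r in snp_rows],
        [pd.DataFrame(r, columns=cov_cols) for r in cov_rows],
    )


# ---------------------------------------------------------------------------
# per-site statistics and pooled corrections
# ---------------------------------------------------------------------------

def site_pi_raw(major: int, minor: int) -> float:
    """Raw sample heterozygosity of a read stack: (M/(M−1))·2f(1−f)."""
    M = major + minor
    if M < 2:
        raise ValueError("site_pi_raw needs at least two reads")
    f = major / M
    return (M / (M - 1)) * (1.0 - f * f - (1.0 - f) ** 2)


@lru_cache(maxsize=100_000)
def pooling_corrections(n: int, M: int, b: int) -> tuple[float, float]:
    """Detection-probability corrections (A_theta, B_pi) for a pooled site.

    ``n`` chromosomes in the pool, ``M`` reads at the site, ``b`` minimum
    minor-allele read count for a SNP call.  See the module docstring for
    the defining double sums.
    """
    if n < 2 or b < 1:
        raise ValueError("need n >= 2 and b >= 1")
    if M < 2 * b:
        raise ValueError(f"coverage M={M} below 2b={2*b}: no detectable site")
    k = np.arange(1, n)
    m = np.arange(b, M - b + 1)
    pmf = stats.binom.pmf(m[None, :], M, (k / n)[:, None])
    inv_k = 1.0 / k
    a_theta = float(inv_k @ pmf.sum(axis=1))
    w = 2.0 * m * (M - m) / (M * (M - 1.0))
    b_pi = float(inv_k @ (pmf @ w))
    return a_theta, b_pi


def _tajima_constants(n: int) -> tuple[float, float]:
    """Tajima's (e1, e2) variance constants for sample size n."""
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return c1 / a1, c2 / (a1**2 + a2)


def effective_pool_size(n: int, coverage: int) -> int:
    """Expected number of distinct chromosomes hit by ``coverage`` reads,
    n·(1 − ((n−1)/n)^coverage), rounded to the nearest integer (≥ 2)."""
    n_star = n * (1.0 - ((n - 1) / n) ** coverage)
    return max(2, int(round(n_star)))


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------

def window_diversity(
    snps: pd.DataFrame,
    covered: pd.DataFrame,
    n: int,
    b: int = 2,
    window_size: int = 100_000,
    min_covered_fraction: float = 0.6,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-site π and θ_W in non-overlapping windows tiled from position 1.

    ``snps`` has columns (chrom, pos, major_count, minor_count); ``covered``
    has (chrom, pos, coverage) for every analyzable site.  Window statistics
    are sums of per-SNP corrected contributions divided by the number of
    covered sites; windows whose covered fraction falls below
    ``min_covered_fraction`` get NaN statistics.  A trailing partial window
    (requires ``chrom_lengths``) is reported with its true span and flagged.
    """
    if window_size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, cov_c in covered.groupby("chrom", sort=True):
        snp_c = snps[snps["chrom"] == chrom]
        widx_cov = (cov_c["pos"].to_numpy() - 1) // window_size
        n_cov = pd.Series(widx_cov).value_counts().to_dict()
        by_window: dict[int, tuple[float, float, int]] = {}
        if len(snp_c):
            widx = (snp_c["pos"].to_numpy() - 1) // window_size
            maj = snp_c["major_count"].to_numpy()
            mnr = snp_c["minor_count"].to_numpy()
            for w, ma, mi in zip(widx, maj, mnr):
                M = int(ma + mi)
                a_t, b_p = pooling_corrections(n, M, b)
                pi_s, th_s, s = by_window.get(int(w), (0.0, 0.0, 0))
                by_window[int(w)] = (
                    pi_s + site_pi_raw(int(ma), int(mi)) / b_p,
                    th_s + 1.0 / a_t,
                    s + 1,
                )
        chrom_len = (chrom_lengths or {}).get(chrom)
        max_w = max(n_cov) if n_cov else -1
        for w in range(int(max_w) + 1):
            start = w * window_size + 1
            end = (w + 1) * window_size
            partial = False
            if chrom_len is not None and end > chrom_len:
                end = chrom_len
                partial = True
            span = end - start + 1
            nc = int(n_cov.get(w, 0))
            pi_s, th_s, s = by_window.get(w, (0.0, 0.0, 0))
            if nc == 0 or nc / span < min_covered_fraction:
                pi = theta = float("nan")
            else:
                pi = pi_s / nc
                theta = th_s / nc
            rows.append((chrom, start, end, nc, s, pi, theta, partial))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites_covered", "n_snps",
                       "pi", "theta_w", "partial"]
    )


def window_tajimas_d(
    major_counts: Sequence[int],
    minor_counts: Sequence[int],
    n: int,
    required_cov: int = 36,
    b: int = 2,
) -> float:
    """Tajima's D for one window from SNPs at uniform coverage.

    Only SNPs whose coverage equals ``required_cov`` contribute (others are
    excluded up front by the caller's filter); the pooled sample size is
    replaced by the expected number of distinct chromosomes sampled at that
    coverage.  Returns NaN when no SNP qualifies or the variance is zero.
    """
    maj = np.asarray(major_counts, dtype=np.int64)
    mnr = np.asarray(minor_counts, dtype=np.int64)
    keep = (maj + mnr) == required_cov
    maj, mnr = maj[keep], mnr[keep]
    S = len(maj)
    if S == 0:
        return float("nan")
    a_t, b_p = pooling_corrections(n, required_cov, b)
    pi_sum = sum(site_pi_raw(int(a), int(m)) for a, m in zip(maj, mnr)) / b_p
    theta_sum = S / a_t
    n_star = effective_pool_size(n, required_cov)
    e1, e2 = _tajima_constants(n_star)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_sum - theta_sum) / math.sqrt(var)


def windowed_tajimas_d(
    snps: pd.DataFrame,
    n: int,
    required_cov: int = 36,
    b: int = 2,
    window_size: int = 100_000,
) -> pd.DataFrame:
    """Tajima's D per window over a per-population SNP table."""
    rows = []
    for chrom, snp_c in snps.groupby("chrom", sort=True):
        widx = (snp_c["pos"].to_numpy() - 1) // window_size
        for w in np.unique(widx):
            sel = snp_c[widx == w]
            d = window_tajimas_d(sel["major_count"], sel["minor_count"], n,
                                 required_cov, b)
            rows.append((chrom, int(w) * window_size + 1,
                         (int(w) + 1) * window_size, d))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tajimas_d"])


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def average_heterozygosity(major_freqs: Sequence[float]) -> float:
    """Mean of 2p(1−p) over SNPs, with p the major-allele frequency."""
    p = np.asarray(major_freqs, dtype=float)
    if p.size == 0:
        raise ValueError("no SNPs supplied")
    if ((p < 0.5) | (p > 1.0)).any():
        raise ValueError("major-allele frequencies must lie in [0.5, 1]")
    return float(np.mean(2.0 * p * (1.0 - p)))


def frequency_validation_correlation(
    pool_freqs: pd.DataFrame, individual_freqs: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Pearson r between pool-based and genotype-based allele frequencies.

    Both tables are locus × population with matched allele orientation.
    Returns per-population correlations and the correlation pooled over all
    matched non-missing pairs.  Requires ≥ 3 matched pairs.
    """
    common_loci = pool_freqs.index.intersection(individual_freqs.index)
    common_pops = pool_freqs.columns.intersection(individual_freqs.columns)
    a = pool_freqs.loc[common_loci, common_pops]
    b = individual_freqs.loc[common_loci, common_pops]
    mask = a.notna() & b.notna()
    if int(mask.to_numpy().sum()) < 3:
        raise ValueError("fewer than 3 matched non-missing frequency pairs")
    per_pop = {}
    for pop in common_pops:
        m = mask[pop]
        if m.sum() >= 3:
            per_pop[pop] = float(
                stats.pearsonr(a.loc[m, pop], b.loc[m, pop]).statistic
            )
        else:
            per_pop[pop] = float("nan")
    flat_a = a.to_numpy()[mask.to_numpy()]
    flat_b = b.to_numpy()[mask.to_numpy()]
    pooled = float(stats.pearsonr(flat_a, flat_b).statistic)
    return pd.Series(per_pop, name="pearson_r"), pooled
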