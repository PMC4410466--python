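"""SNP calling filters, pooled corrections, and window statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from poolscan import popgen
from poolscan.io_formats import SiteCounts
from poolscan.simulate import simulate_neutral_sites


def _site(per_pop_acgt, chrom="chrI", pos=100, ref="A"):
    counts = np.zeros((len(per_pop_acgt), 6), dtype=int)
    counts[:, :4] = per_pop_acgt
    return SiteCounts(chrom, pos, ref, counts)


class TestCallSnps:
    def test_pooled_minor_count_filter(self):
        # pooled A=30, T=3 fails a pooled-MAC-4 filter
        cfg = popgen.SiteFilterConfig.fst_scan()
        site = _site([[15, 2, 0, 0], [15, 1, 0, 0]])
        assert len(popgen.call_snps([site], cfg)) == 0
        site_ok = _site([[15, 2, 0, 0], [15, 2, 0, 0]])
        assert len(popgen.call_snps([site_ok], cfg)) == 1

    def test_population_coverage_bounds(self):
        cfg = popgen.SiteFilterConfig.fst_scan()  # per-pop coverage 10–500
        site = _site([[5, 4, 0, 0], [30, 10, 0, 0]])  # first pop coverage 9
        assert len(popgen.call_snps([site], cfg)) == 0

    def test_stringent_subset_accepts_qualifying_site(self):
        cfg = popgen.SiteFilterConfig.selection_subset()
        site = _site([[33, 3, 0, 0], [33, 3, 0, 0], [40, 0, 0, 0]])
        out = popgen.call_snps([site], cfg)
        assert len(out) == 1
        assert out.iloc[0]["major"] == "A" and out.iloc[0]["minor"] == "T"
        assert list(out.iloc[0]["minor_counts"]) == [3, 3, 0]
        # one population below coverage 36 disqualifies the site
        low = _site([[33, 3, 0, 0], [33, 3, 0, 0], [35, 0, 0, 0]])
        assert len(popgen.call_snps([low], cfg)) == 0

    def test_third_allele_reads_dropped(self):
        cfg = popgen.SiteFilterConfig(min_minor_count_pop=0, cov_min_pop=0,
                                      cov_max_pop=10**6, min_minor_count_total=2,
                                      cov_min_total=0, cov_max_total=10**6)
        site = _site([[30, 10, 1, 0]])
        out = popgen.call_snps([site], cfg)
        assert list(out.iloc[0]["major_counts"]) == [30]
        assert list(out.iloc[0]["minor_counts"]) == [10]

    def test_empty_stream_is_empty_result(self):
        assert len(popgen.call_snps([], popgen.SiteFilterConfig())) == 0

    def test_allele_tiebreak_is_fixed_order(self):
        cfg = popgen.SiteFilterConfig(min_minor_count_pop=0, cov_min_pop=0,
                                      cov_max_pop=10**6, min_minor_count_total=2,
                                      cov_min_total=0, cov_max_total=10**6)
        site = _site([[0, 10, 10, 0]])  # T and C tied: T wins (A<T<C<G)
        out = popgen.call_snps([site], cfg)
        assert out.iloc[0]["major"] == "T" and out.iloc[0]["minor"] == "C"


class TestSitePiRaw:
    @pytest.mark.parametrize("major,minor,expected", [
        (1, 1, 1.0),
        (10, 0, 0.0),
        (5, 5, (10 / 9) * 0.5),
    ])
    def test_hand_values(self, major, minor, expected):
        assert popgen.site_pi_raw(major, minor) == pytest.approx(expected)

    def test_single_read_rejected(self):
        with pytest.raises(ValueError):
            popgen.site_pi_raw(1, 0)


def brute_force_corrections(n, M, b):
    """Independent double-summation oracle for the pooled corrections."""
    a_theta = 0.0
    b_pi = 0.0
    for k in range(1, n):
        for m in range(b, M - b + 1):
            pmf = binom.pmf(m, M, k / n)
            a_theta += pmf / k
            b_pi += (2 * m * (M - m) / (M * (M - 1))) * pmf / k
    return a_theta, b_pi


class TestPoolingCorrections:
    def test_minimal_case_by_hand(self):
        # n=2, M=2, b=1: A = Binom(1; 2, 0.5) = 0.5
        a_theta, _ = popgen.pooling_corrections(2, 2, 1)
        assert a_theta == pytest.approx(0.5, abs=1e-12)

    def test_detection_certain_in_deep_coverage_limit(self):
        a_theta, _ = popgen.pooling_corrections(2, 2000, 1)
        assert a_theta == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("n,M,b", [
        (2, 4, 1), (5, 10, 2), (10, 20, 2), (20, 36, 2), (72, 36, 2),
        (72, 50, 2), (100, 100, 4), (36, 80, 3), (7, 15, 1),
    ])
    def test_matches_brute_force_double_sum(self, n, M, b):
        got = popgen.pooling_corrections(n, M, b)
        expected = brute_force_corrections(n, M, b)
        assert got[0] == pytest.approx(expected[0], abs=1e-10)
        assert got[1] == pytest.approx(expected[1], abs=1e-10)

    def test_undetectable_configuration_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            popgen.pooling_corrections(10, 3, 2)


class TestWindowDiversity:
    def _covered(self, n_sites, chrom="c", coverage=40):
        return pd.DataFrame({"chrom": chrom, "pos": np.arange(1, n_sites + 1),
                             "coverage": coverage})

    def test_no_snps_full_coverage_gives_zero(self):
        snps = pd.DataFrame(columns=["chrom", "pos", "major_count",
                                     "minor_count"])
        out = popgen.window_diversity(snps, self._covered(1000), n=72, b=2,
                                      window_size=1000,
                                      min_covered_fraction=0.5)
        assert out.iloc[0]["pi"] == 0.0 and out.iloc[0]["theta_w"] == 0.0

    def test_single_snp_ratio_identity(self):
        # π/θW of a one-SNP window equals (site_pi_raw/B)·A
        snps = pd.DataFrame([("c", 10, 30, 10)],
                            columns=["chrom", "pos", "major_count",
                                     "minor_count"])
        out = popgen.window_diversity(snps, self._covered(100), n=72, b=2,
                                      window_size=100,
                                      min_covered_fraction=0.0)
        a_t, b_p = popgen.pooling_corrections(72, 40, 2)
        ratio = out.iloc[0]["pi"] / out.iloc[0]["theta_w"]
        assert ratio == pytest.approx(popgen.site_pi_raw(30, 10) / b_p * a_t)

    def test_low_coverage_window_undefined(self):
        snps = pd.DataFrame(columns=["chrom", "pos", "major_count",
                                     "minor_count"])
        out = popgen.window_diversity(snps, self._covered(10), n=72, b=2,
                                      window_size=1000,
                                      min_covered_fraction=0.6)
        assert math.isnan(out.iloc[0]["pi"])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        pos = rng.choice(np.arange(1, 5000), size=200, replace=False)
        snps = pd.DataFrame({"chrom": "c", "pos": pos,
                             "major_count": rng.integers(20, 40, 200),
                             "minor_count": rng.integers(2, 15, 200)})
        covered = pd.DataFrame({"chrom": "c", "pos": np.arange(1, 5000),
                                "coverage": 40})
        a = popgen.window_diversity(snps, covered, 72, 2, 1000, 0.0)
        shuffled = snps.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = popgen.window_diversity(shuffled, covered, 72, 2, 1000, 0.0)
        pd.testing.assert_frame_equal(a, b)

    def test_trailing_partial_window_flagged(self):
        snps = pd.DataFrame(columns=["chrom", "pos", "major_count",
                                     "minor_count"])
        out = popgen.window_diversity(snps, self._covered(1500), n=72, b=2,
                                      window_size=1000,
                                      min_covered_fraction=0.0,
                                      chrom_lengths={"c": 1500})
        assert list(out["partial"]) == [False, True]
        assert out.iloc[1]["end"] == 1500


class TestEstimatorCalibration:
    def test_window_theta_and_pi_near_truth(self):
        theta = 0.005
        snps = simulate_neutral_sites(theta, n=72, mean_coverage=40,
                                      n_windows=60, b=2, seed=5)
        theta_hats, pi_hats = [], []
        for _, g in snps.groupby("window"):
            th = pi = 0.0
            for ma, mi in zip(g["major_count"], g["minor_count"]):
                a_t, b_p = popgen.pooling_corrections(72, int(ma + mi), 2)
                th += 1.0 / a_t
                pi += popgen.site_pi_raw(int(ma), int(mi)) / b_p
            theta_hats.append(th / 100_000)
            pi_hats.append(pi / 100_000)
        assert np.mean(theta_hats) == pytest.approx(theta, rel=0.15)
        assert np.mean(pi_hats) == pytest.approx(theta, rel=0.15)

    def test_neutral_tajimas_d_centred_at_zero(self):
        snps = simulate_neutral_sites(0.005, n=72, mean_coverage=36,
                                      n_windows=200, b=2, seed=6,
                                      fixed_coverage=True)
        ds = [popgen.window_tajimas_d(g["major_count"].to_numpy(),
                                      g["minor_count"].to_numpy(), 72, 36, 2)
              for _, g in snps.groupby("window")]
        assert len(ds) >= 200
        assert abs(np.nanmean(ds)) < 0.3


class TestTajimasD:
    def test_no_qualifying_snps_undefined(self):
        assert math.isnan(popgen.window_tajimas_d([40, 40], [0, 0], 72, 36, 2))
        assert math.isnan(popgen.window_tajimas_d([], [], 72, 36, 2))

    def test_only_uniform_coverage_sites_contribute(self):
        d_all = popgen.window_tajimas_d([30, 30, 33], [6, 6, 6], 72, 36, 2)
        d_sub = popgen.window_tajimas_d([30, 30], [6, 6], 72, 36, 2)
        assert d_all == pytest.approx(d_sub)

    def test_effective_pool_size_bounds(self):
        assert popgen.effective_pool_size(72, 36) in (28, 29)
        assert popgen.effective_pool_size(72, 10**6) == 72
        assert popgen.effective_pool_size(72, 1) == 2


class TestAverageHeterozygosity:
    @pytest.mark.parametrize("freqs,expected", [
        ([0.5], 0.5),
        ([0.9], 0.18),
        ([0.5, 1.0], 0.25),
    ])
    def test_hand_values(self, freqs, expected):
        assert popgen.average_heterozygosity(freqs) == pytest.approx(expected)

    def test_bounds_and_maximum_condition(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.5, 1.0, 100)
        h = popgen.average_heterozygosity(p)
        assert 0.0 <= h < 0.5
        assert popgen.average_heterozygosity([0.5, 0.5]) == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            popgen.average_heterozygosity([])


class TestFrequencyValidation:
    def _tables(self, a, b):
        idx = [f"l{i}" for i in range(len(a))]
        return (pd.DataFrame({"P1": a}, index=idx),
                pd.DataFrame({"P1": b}, index=idx))

    def test_identical_vectors(self):
        pool, ind = self._tables([0.1, 0.4, 0.9], [0.1, 0.4, 0.9])
        per_pop, pooled = popgen.frequency_validation_correlation(pool, ind)
        assert pooled == pytest.approx(1.0)
        assert per_pop["P1"] == pytest.approx(1.0)

    def test_reflection_about_mean(self):
        a = np.array([0.1, 0.5, 0.9])
        pool, ind = self._tables(a, a.mean() - (a - a.mean()))
        _, pooled = popgen.frequency_validation_correlation(pool, ind)
        assert pooled == pytest.approx(-1.0)

    def test_perfect_linearity(self):
        pool, ind = self._tables([0.1, 0.5, 0.9], [0.2, 0.5, 0.8])
        _, pooled = popgen.frequency_validation_correlation(pool, ind)
        assert pooled == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self):
        pool, ind = self._tables([0.1, 0.5], [0.2, 0.5])
        with pytest.raises(ValueError, match="matched"):
            popgen.frequency_validation_correlation(pool, ind)
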