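"""Pairwise FST from pooled counts, windowed summaries, and the empirical
tail-consensus outlier rule.

The estimator is the conventional heterozygosity-ratio form.  With
``f_x`` the major-allele frequency and ``M_x`` the coverage in population
``x``, per-population heterozygosity carries the small-sample factor
M/(M−1):

    π_x      = 2 f_x (1−f_x) · M_x/(M_x−1)
    π_within = (π_i + π_j)/2
    π_total  = 2 f̄ (1−f̄) · (M_i+M_j)/(M_i+M_j−1),   f̄ = (f_i+f_j)/2
    FST      = (π_total − π_within)/π_total

Negative values are retained so that window and matrix averages stay
unbiased; the consensus rule only looks at upper tails.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TailConsensusConfig:
    """Upper-tail quantile and the number of pairs required for consensus."""

    tail_quantile: float = 0.005
    min_pairs: int = 5

    def __post_init__(self):
        if not 0.0 < self.tail_quantile < 1.0:
            raise ValueError("tail_quantile must lie in (0, 1)")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")


def population_pairs(codes: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered population pairs, in input order (45 for 10 codes)."""
    return list(combinations(codes, 2))


def fst_components(
    major_i: float, minor_i: float, major_j: float, minor_j: float
) -> tuple[float, float]:
    """(π_total − π_within, π_total) for one SNP and one population pair."""
    M_i = major_i + minor_i
    M_j = major_j + minor_j
    if M_i < 2 or M_j < 2:
        raise ValueError("both coverages must be >= 2")
    f_i = major_i / M_i
    f_j = major_j / M_j
    pi_i = 2.0 * f_i * (1.0 - f_i) * M_i / (M_i - 1.0)
    pi_j = 2.0 * f_j * (1.0 - f_j) * M_j / (M_j - 1.0)
    pi_within = 0.5 * (pi_i + pi_j)
    f_bar = 0.5 * (f_i + f_j)
    M_t = M_i + M_j
    pi_total = 2.0 * f_bar * (1.0 - f_bar) * M_t / (M_t - 1.0)
    return pi_total - pi_within, pi_total


def snp_fst(major_i: float, minor_i: float, major_j: float, minor_j: float) -> float:
    """Per-SNP pairwise FST; NaN when π_total = 0 (both pops fixed alike)."""
    num, den = fst_components(major_i, minor_i, major_j, minor_j)
    if den == 0.0:
        return float("nan")
    return num / den


def pair_fst_table(snps: pd.DataFrame, codes: Sequence[str]) -> pd.DataFrame:
    """Long per-SNP per-pair FST table with ratio-of-sums components.

    ``snps`` is the output of :func:`poolscan.popgen.call_snps` (columns
    ``major_counts``/``minor_counts`` hold per-population arrays ordered as
    ``codes``).  Returns columns (chrom, pos, pop_i, pop_j, num, den, fst).
    """
    if len(snps) == 0:
        return pd.DataFrame(
            columns=["chrom", "pos", "pop_i", "pop_j", "num", "den", "fst"]
        )
    maj = np.vstack(snps["major_counts"].to_numpy()).astype(float)
    mnr = np.vstack(snps["minor_counts"].to_numpy()).astype(float)
    M = maj + mnr
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(M > 0, maj / M, np.nan)
        pi_pop = 2.0 * f * (1.0 - f) * M / (M - 1.0)
    frames = []
    idx = {c: k for k, c in enumerate(codes)}
    for a, b_ in population_pairs(list(codes)):
        i, j = idx[a], idx[b_]
        ok = (M[:, i] >= 2) & (M[:, j] >= 2)
        f_bar = 0.5 * (f[:, i] + f[:, j])
        M_t = M[:, i] + M[:, j]
        pi_total = 2.0 * f_bar * (1.0 - f_bar) * M_t / (M_t - 1.0)
        num = pi_total - 0.5 * (pi_pop[:, i] + pi_pop[:, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(pi_total > 0, num / pi_total, np.nan)
        frames.append(pd.DataFrame({
            "chrom": snps["chrom"].to_numpy(),
            "pos": snps["pos"].to_numpy(),
            "pop_i": a, "pop_j": b_,
            "num": np.where(ok, num, np.nan),
            "den": np.where(ok, pi_total, np.nan),
            "fst": np.where(ok, fst, np.nan),
        }))
    return pd.concat(frames, ignore_index=True)


def window_fst(
    pair_table: pd.DataFrame, window_size: int = 100_000
) -> pd.DataFrame:
    """Ratio-of-sums FST per 100-kb window per pair: Σnum / Σden over SNPs."""
    if window_size <= 0:
        raise ValueError("window size must be positive")
    t = pair_table.dropna(subset=["num", "den"]).copy()
    t["window"] = (t["pos"] - 1) // window_size
    grouped = t.groupby(["chrom", "window", "pop_i", "pop_j"], sort=True).agg(
        num=("num", "sum"), den=("den", "sum"), n_snps=("num", "size")
    ).reset_index()
    grouped["start"] = grouped["window"] * window_size + 1
    grouped["end"] = (grouped["window"] + 1) * window_size
    with np.errstate(divide="ignore", invalid="ignore"):
        grouped["fst"] = np.where(grouped["den"] > 0,
                                  grouped["num"] / grouped["den"], np.nan)
    return grouped[["chrom", "start", "end", "pop_i", "pop_j", "n_snps", "fst"]]


def mean_fst_matrix(pair_table: pd.DataFrame, codes: Sequence[str]) -> pd.DataFrame:
    """Arithmetic mean per-pair FST over SNPs with defined values.

    Returns a symmetric DataFrame with zero diagonal, indexed by ``codes``.
    Raises when a pair has no defined FST.
    """
    mat = pd.DataFrame(0.0, index=list(codes), columns=list(codes))
    means = pair_table.dropna(subset=["fst"]).groupby(["pop_i", "pop_j"])["fst"].mean()
    for a, b in population_pairs(list(codes)):
        if (a, b) in means.index:
            v = float(means.loc[(a, b)])
        elif (b, a) in means.index:
            v = float(means.loc[(b, a)])
        else:
            raise ValueError(f"no defined FST values for pair ({a}, {b})")
        mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def matrix_min_max(mat: pd.DataFrame) -> tuple[float, float]:
    """Min and max over the off-diagonal pairwise values of a square matrix."""
    vals = mat.to_numpy()[np.triu_indices(len(mat), k=1)]
    return float(np.min(vals)), float(np.max(vals))


def empirical_outlier_consensus(
    fst_wide: pd.DataFrame, cfg: TailConsensusConfig = TailConsensusConfig()
) -> pd.DataFrame:
    """Tail-consensus outlier detection over a SNP × pair FST table.

    For each pair the tail set holds the SNPs whose FST strictly exceeds the
    empirical (1−q) quantile of that pair's defined values, where the
    quantile is the value at rank ⌈(1−q)·L⌉ of the sorted values (ties at
    the threshold are excluded).  A SNP is an outlier when it falls in the
    tails of at least ``min_pairs`` pairs; missing values never count.

    Returns a DataFrame indexed like ``fst_wide`` with columns
    ``tail_count``, ``is_outlier``, ``in_any_tail``.
    """
    q = cfg.tail_quantile
    tail = pd.DataFrame(False, index=fst_wide.index, columns=fst_wide.columns)
    for pair in fst_wide.columns:
        vals = fst_wide[pair].dropna()
        L = len(vals)
        if L == 0:
            continue
        if q * L < 1:
            logger.warning("pair %s: tail quantile %g of %d values selects "
                           "no SNPs", pair, q, L)
        rank = math.ceil((1.0 - q) * L)
        threshold = np.sort(vals.to_numpy())[rank - 1]
        tail[pair] = fst_wide[pair] > threshold
    tail_count = tail.sum(axis=1)
    return pd.DataFrame({
        "tail_count": tail_count.astype(int),
        "is_outlier": tail_count >= cfg.min_pairs,
        "in_any_tail": tail_count >= 1,
    })


def pair_table_to_wide(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long per-SNP per-pair table to SNP × pair FST values."""
    t = pair_table.copy()
    t["pair"] = t["pop_i"].astype(str) + "-" + t["pop_j"].astype(str)
    wide = t.pivot_table(index=["chrom", "pos"], columns="pair",
                         values="fst", aggfunc="first", dropna=False)
    wide.columns.name = None
    return wide
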