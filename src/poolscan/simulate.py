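"""Synthetic pool-seq seascape generator with labelled ground truth.

The generator emulates the study design the pipeline targets: ten pooled
populations of 36 diploids along an environmental gradient, weak genome-wide
differentiation, a minority of loci under divergent selection or tracking an
environmental variable, heterogeneous per-population coverage, and
sequencing error.

Population allele frequencies follow the Balding–Nichols model: around an
ancestral frequency ``p`` each population draws
``f ~ Beta(p(1−c)/c, (1−p)(1−c)/c)`` whose expected FST is ``c`` — giving an
analytic recovery target for the estimators.  Divergent loci use an elevated
``c_out``; environment-associated loci add an effect ``b·e_j`` on the logit
scale on top of a neutral draw, where ``e_j`` is the standardized value of
the driving variable in population ``j``.  Pooled sequencing is two-stage
binomial: the pool allele count is Binomial(2N, f), read counts
Binomial(M, k/2N) at Poisson coverage, and each read is flipped to a random
other base with the error probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io_formats import PopulationMeta, SiteCounts, baltic_metadata, write_sync

LOCUS_CLASSES = ("neutral", "divergent", "env")
_BASES = np.array(["A", "T", "C", "G"])
_BASE_IDX = {"A": 0, "T": 1, "C": 2, "G": 3}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic seascape.

    Defaults mirror the targeted survey: 10 pools of 36 diploids with the
    bundled Baltic salinity/temperature gradient, baseline Balding–Nichols
    differentiation c = 0.02 (low, matching the observed genome-wide mean of
    a few percent), 20 divergent loci at c_out = 0.4, 40 environment-
    associated loci at logit effect 1.5, mean coverage 50× (Poisson), and
    sequencing error 0.002.
    """

    n_neutral: int = 500
    n_divergent: int = 20
    n_env: int = 40
    c_neutral: float = 0.02
    c_divergent: float = 0.4
    env_effect: float = 1.5
    mean_coverage: float | tuple[float, ...] = 50.0
    error_rate: float = 0.002
    locus_spacing: int = 1500
    chrom_length: int = 210_000
    chrom_prefix: str = "chr"
    coverage_overdispersion: float | None = None  # None → Poisson
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.c_neutral < 1.0 or not 0.0 < self.c_divergent < 1.0:
            raise ValueError("differentiation parameters must lie in (0, 1)")
        if np.min(np.atleast_1d(self.mean_coverage)) < 1:
            raise ValueError("mean coverage must be >= 1")
        if min(self.n_neutral, self.n_divergent, self.n_env) < 0:
            raise ValueError("class counts must be non-negative")

    @property
    def n_loci(self) -> int:
        return self.n_neutral + self.n_divergent + self.n_env

    def positions(self) -> list[tuple[str, int]]:
        """(chrom, pos) for each locus: evenly spaced, tiling chromosomes."""
        per_chrom = self.chrom_length // self.locus_spacing
        out = []
        for l in range(self.n_loci):
            chrom = f"{self.chrom_prefix}{l // per_chrom + 1}"
            pos = (l % per_chrom) * self.locus_spacing + self.locus_spacing // 2
            out.append((chrom, pos))
        return out


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, c: float,
                     J: int) -> np.ndarray:
    shape1 = p * (1.0 - c) / c
    shape2 = (1.0 - p) * (1.0 - c) / c
    return rng.beta(shape1[:, None], shape2[:, None], size=(len(p), J))


def simulate_frequencies(
    cfg: SimConfig,
    metadata: Sequence[PopulationMeta] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw true per-population allele frequencies and the truth table.

    Loci are laid out neutral, then divergent, then environment-associated;
    the truth table records class, ancestral frequency, effect size, driving
    variable (env loci alternate between salinity and temperature), genomic
    position, and the per-population true frequencies.
    """
    meta = list(metadata) if metadata is not None else baltic_metadata()
    J = len(meta)
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    p = rng.uniform(0.05, 0.95, size=L)
    classes = (["neutral"] * cfg.n_neutral + ["divergent"] * cfg.n_divergent
               + ["env"] * cfg.n_env)
    freqs = np.empty((L, J))
    sl_neutral = slice(0, cfg.n_neutral)
    sl_div = slice(cfg.n_neutral, cfg.n_neutral + cfg.n_divergent)
    sl_env = slice(cfg.n_neutral + cfg.n_divergent, L)
    freqs[sl_neutral] = _balding_nichols(rng, p[sl_neutral], cfg.c_neutral, J)
    freqs[sl_div] = _balding_nichols(rng, p[sl_div], cfg.c_divergent, J)

    env_values = {
        "salinity": np.array([m.salinity for m in meta]),
        "temperature": np.array([m.temperature for m in meta]),
    }
    env_std = {k: (v - v.mean()) / v.std(ddof=1) for k, v in env_values.items()}
    env_names = list(env_std)
    effects = np.zeros(L)
    variables = [""] * L
    g = _balding_nichols(rng, p[sl_env], cfg.c_neutral, J)
    g = np.clip(g, 1e-9, 1.0 - 1e-9)
    for i, l in enumerate(range(sl_env.start, L)):
        var = env_names[i % len(env_names)]
        effects[l] = cfg.env_effect
        variables[l] = var
        freqs[l] = expit(logit(g[i]) + cfg.env_effect * env_std[var])

    positions = cfg.positions()
    truth = pd.DataFrame({
        "locus": np.arange(L),
        "chrom": [c for c, _ in positions],
        "pos": [x for _, x in positions],
        "class": classes,
        "ancestral_p": p,
        "effect_size": effects,
        "env_variable": variables,
    })
    for j, m in enumerate(meta):
        truth[f"f_{m.code}"] = freqs[:, j]
    return freqs, truth


def simulate_pool_reads(
    freqs: np.ndarray,
    cfg: SimConfig,
    metadata: Sequence[PopulationMeta] | None = None,
    rng: np.random.Generator | None = None,
) -> list[SiteCounts]:
    """Sequence the pools: two-stage binomial sampling plus error.

    For each locus the alternative allele frequency is ``freqs``; reference
    and alternative bases are drawn per locus.  Coverage is Poisson (or
    gamma-Poisson when ``coverage_overdispersion`` is set) around each
    population's mean; each read flips to a uniformly chosen other base with
    probability ``error_rate``.
    """
    meta = list(metadata) if metadata is not None else baltic_metadata()
    J = len(meta)
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    L = freqs.shape[0]
    means = np.broadcast_to(np.atleast_1d(np.asarray(cfg.mean_coverage,
                                                     dtype=float)), (J,))
    positions = cfg.positions()
    sites = []
    for l in range(L):
        ref_i, alt_i = rng.choice(4, size=2, replace=False)
        counts = np.zeros((J, 6), dtype=np.int64)
        for j, m in enumerate(meta):
            two_n = m.n_chromosomes
            k = rng.binomial(two_n, freqs[l, j])
            if cfg.coverage_overdispersion:
                lam = rng.gamma(cfg.coverage_overdispersion,
                                means[j] / cfg.coverage_overdispersion)
            else:
                lam = means[j]
            M = rng.poisson(lam)
            if M == 0:
                continue
            alt_reads = rng.binomial(M, k / two_n)
            for base_i, n_reads in ((ref_i, M - alt_reads), (alt_i, alt_reads)):
                if n_reads == 0:
                    continue
                errs = rng.binomial(n_reads, cfg.error_rate)
                counts[j, base_i] += n_reads - errs
                if errs:
                    others = [bi for bi in range(4) if bi != base_i]
                    spread = rng.multinomial(errs, [1 / 3] * 3)
                    for bi, e in zip(others, spread):
                        counts[j, bi] += e
        chrom, pos = positions[l]
        sites.append(SiteCounts(chrom=chrom, pos=pos, ref=_BASES[ref_i],
                                counts=counts))
    return sites


def write_mpileup(sites: Sequence[SiteCounts], path: str | Path,
                  qual_char: str = "I") -> None:
    """Write SiteCounts as samtools-style mpileup text (all bases Q40)."""
    with open(path, "w") as out:
        for s in sites:
            fields = [s.chrom, str(s.pos), s.ref]
            ref_idx = _BASE_IDX.get(s.ref.upper())
            for row in s.counts:
                parts = []
                for i, sym in enumerate(["A", "T", "C", "G", "N", "*"]):
                    n_reads = int(row[i])
                    if n_reads == 0:
                        continue
                    ch = "." if i == ref_idx else sym
                    parts.append(ch * n_reads)
                bases = "".join(parts)
                depth = int(row.sum())
                if depth == 0:
                    fields += ["0", "*", "*"]
                else:
                    fields += [str(depth), bases, qual_char * depth]
            out.write("\t".join(fields) + "\n")


def simulate_annotation(
    cfg: SimConfig,
    gene_length: int = 6000,
    gene_spacing: int = 15_000,
    n_go_terms: int = 30,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Synthetic gene models tiling the simulated chromosomes with GO terms.

    Genes of ``gene_length`` bp start every ``gene_spacing`` bp; each gene
    gets 1–4 GO terms drawn from a pool of ``n_go_terms``.  Returns a gene
    table (gene_id, chrom, start, end, strand) and the gene→GO map.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    n_chroms = -(-cfg.n_loci * cfg.locus_spacing) // cfg.chrom_length + 1
    terms = [f"GO:{i:07d}" for i in range(1, n_go_terms + 1)]
    rows = []
    go_map: dict[str, set[str]] = {}
    gid = 0
    for c in range(1, n_chroms + 1):
        chrom = f"{cfg.chrom_prefix}{c}"
        for start in range(1, cfg.chrom_length - gene_length, gene_spacing):
            gid += 1
            name = f"gene{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((name, chrom, start, start + gene_length - 1, strand))
            k = int(rng.integers(1, 5))
            go_map[name] = set(rng.choice(terms, size=k, replace=False))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand"])
    return genes, go_map


def simulate_dataset(
    cfg: SimConfig,
    out_dir: str | Path,
    metadata: Sequence[PopulationMeta] | None = None,
) -> dict[str, Path]:
    """Emit a mutually consistent synthetic dataset into ``out_dir``.

    Writes sync counts, the matching mpileup, population metadata, the
    ground-truth table, a synthetic gene annotation (GFF3) and gene→GO map.
    Reruns with the same config and seed reproduce byte-identical files.
    Returns the paths keyed by artifact name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = list(metadata) if metadata is not None else baltic_metadata()
    freqs, truth = simulate_frequencies(cfg, meta)
    sites = simulate_pool_reads(freqs, cfg, meta)
    paths = {
        "sync": out / "counts.sync",
        "mpileup": out / "counts.mpileup",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
        "annotation": out / "genes.gff3",
        "go_map": out / "gene_go.tsv",
    }
    write_sync(sites, paths["sync"])
    write_mpileup(sites, paths["mpileup"])
    pd.DataFrame([{
        "code": m.code, "latitude": m.latitude, "longitude": m.longitude,
        "salinity": m.salinity, "temperature": m.temperature,
        "pool_individuals": m.pool_individuals,
    } for m in meta]).to_csv(paths["metadata"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
    genes, go_map = simulate_annotation(cfg)
    with open(paths["annotation"], "w") as gff:
        gff.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            gff.write(f"{g.chrom}\tpoolscan_sim\tgene\t{g.start}\t{g.end}\t."
                      f"\t{g.strand}\t.\tID={g.gene_id}\n")
    with open(paths["go_map"], "w") as gm:
        for name in sorted(go_map):
            for term in sorted(go_map[name]):
                gm.write(f"{name}\t{term}\n")
    return paths


def simulate_neutral_sites(
    theta: float,
    n: int,
    mean_coverage: float,
    n_windows: int,
    window_size: int = 100_000,
    b: int = 2,
    seed: int = 0,
    fixed_coverage: bool = False,
) -> pd.DataFrame:
    """Infinite-sites neutral windows for estimator calibration.

    Under the neutral site-frequency spectrum the expected number of sites
    carrying ``k`` of ``n`` pool chromosomes is ``window_size·θ/k``; each is
    sequenced at coverage M (Poisson around ``mean_coverage``, or exactly
    that value when ``fixed_coverage``), and detected as a SNP when the
    minor read count reaches ``b``.  Returns detected SNPs with columns
    (window, major_count, minor_count).
    """
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(1, n):
        counts = rng.poisson(window_size * theta / k, size=n_windows)
        total = int(counts.sum())
        if total == 0:
            continue
        window_ids = np.repeat(np.arange(n_windows), counts)
        if fixed_coverage:
            M = np.full(total, int(mean_coverage))
        else:
            M = rng.poisson(mean_coverage, size=total)
        m = rng.binomial(M, k / n)
        minor = np.minimum(m, M - m)
        detect = minor >= b
        frames.append(pd.DataFrame({
            "window": window_ids[detect],
            "major_count": (M - minor)[detect],
            "minor_count": minor[detect],
        }))
    if not frames:
        return pd.DataFrame(columns=["window", "major_count", "minor_count"])
    return pd.concat(frames, ignore_index=True)
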