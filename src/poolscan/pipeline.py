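"""End-to-end orchestration: ingest → filter → diversity → FST → outliers →
covariance → environmental association → structure → annotation, with a
hashed results manifest.

Every stage is a pure function of (inputs, config, seed); rerunning a
configuration reproduces byte-identical outputs, which the manifest records
as SHA-256 content hashes.  The "truly differentiated" outlier set is the
intersection of the empirical tail-consensus and Bayesian flag sets; the
candidate-gene list is the union of genes hit by intersection outliers and
genes hit by SNPs whose environmental log10 Bayes factor exceeds the lower
threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bayes, fst, popgen, simulate, structure
from .io_formats import (GeneInterval, PopulationMeta, load_go_map,
                         load_metadata, read_gene_intervals_gff3, read_sync)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single configuration object for a full pipeline run.

    Exactly one of ``sync`` (with ``metadata``) or ``simulate`` must be
    given.  MCMC settings mirror the outlier-model config field names.
    """

    out_dir: str = "results/pipeline"
    sync: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    go_map: str | None = None
    simulate: dict[str, Any] | None = None
    window_size: int = 100_000
    min_minor_detect: int = 2          # b, detectability bound for corrections
    tajima_required_cov: int = 36
    consensus: dict[str, Any] = field(default_factory=dict)
    mcmc: dict[str, Any] = field(default_factory=dict)
    env_variables: tuple[str, ...] = ("salinity", "temperature")
    bf_thresholds: tuple[float, float] = (1.5, 5.0)
    bootstrap_replicates: int = 1000
    mantel_permutations: int = 9999
    seed: int = 0

    def __post_init__(self):
        if (self.sync is None) == (self.simulate is None):
            raise ValueError("exactly one of sync/simulate must be configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("env_variables", "bf_thresholds"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", index=kw.pop("index", False),
              float_format="%.8g", **kw)
    return path


def _env_table(meta: Sequence[PopulationMeta],
               names: Sequence[str]) -> dict[str, np.ndarray]:
    return {name: np.array([getattr(m, name) for m in meta]) for name in names}


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute all stages and return the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    stats: dict[str, Any] = {}

    # --- ingest -----------------------------------------------------------
    if cfg.simulate is not None:
        sim_cfg = simulate.SimConfig(**{**cfg.simulate, "seed": cfg.seed})
        sim_paths = simulate.simulate_dataset(sim_cfg, out / "simulated")
        sync_path = sim_paths["sync"]
        meta = load_metadata(sim_paths["metadata"])
        annotation_path = sim_paths["annotation"]
        go_path = sim_paths["go_map"]
        files.update({f"sim_{k}": p for k, p in sim_paths.items()})
    else:
        sync_path = Path(cfg.sync)
        meta = load_metadata(cfg.metadata)
        annotation_path = Path(cfg.annotation) if cfg.annotation else None
        go_path = Path(cfg.go_map) if cfg.go_map else None
    codes = [m.code for m in meta]
    n_chr = meta[0].n_chromosomes
    sites = list(read_sync(sync_path))
    stats["n_sites"] = len(sites)
    logger.info("ingest: %d sites, %d populations", len(sites), len(codes))

    # --- per-population diversity ----------------------------------------
    div_cfg = popgen.SiteFilterConfig.diversity()
    snps_by_pop, covered_by_pop = popgen.call_snps_per_population(sites, div_cfg)
    b = cfg.min_minor_detect
    summaries = []
    window_frames = []
    for j, code in enumerate(codes):
        snps_j, cov_j = snps_by_pop[j], covered_by_pop[j]
        wd = popgen.window_diversity(snps_j, cov_j, n=n_chr, b=b,
                                     window_size=cfg.window_size,
                                     min_covered_fraction=0.0)
        wd.insert(0, "population", code)
        window_frames.append(wd)
        if len(snps_j):
            M = snps_j["major_count"] + snps_j["minor_count"]
            het = popgen.average_heterozygosity(
                (snps_j["major_count"] / M).to_numpy())
        else:
            het = float("nan")
        summaries.append((code, len(snps_j), het,
                          float(np.nanmean(wd["pi"])) if len(wd) else np.nan,
                          float(np.nanmean(wd["theta_w"])) if len(wd) else np.nan))
    windows = pd.concat(window_frames, ignore_index=True)
    files["window_diversity"] = _write_tsv(windows, out / "window_diversity.tsv")
    summary = pd.DataFrame(summaries, columns=[
        "population", "n_snps", "avg_heterozygosity", "mean_pi", "mean_theta_w"])
    files["population_summary"] = _write_tsv(summary, out / "population_summary.tsv")
    logger.info("diversity: SNP counts per population %s",
                dict(zip(codes, summary["n_snps"])))

    # --- genome-wide FST --------------------------------------------------
    fst_snps = popgen.call_snps(sites, popgen.SiteFilterConfig.fst_scan())
    stats["n_snps_fst"] = len(fst_snps)
    pair_table = fst.pair_fst_table(fst_snps, codes)
    wfst = fst.window_fst(pair_table, cfg.window_size)
    files["window_fst"] = _write_tsv(wfst, out / "window_fst.tsv")
    stats["mean_window_fst"] = float(np.nanmean(wfst["fst"]))
    files["snp_fst"] = _write_tsv(
        pair_table[["chrom", "pos", "pop_i", "pop_j", "fst"]],
        out / "snp_fst.tsv")
    logger.info("fst: %d SNPs, mean windowed pairwise FST %.5f",
                len(fst_snps), stats["mean_window_fst"])

    # --- subset SNPs and outlier detection --------------------------------
    subset = popgen.call_snps(sites, popgen.SiteFilterConfig.selection_subset())
    stats["n_snps_subset"] = len(subset)
    if len(subset) == 0:
        raise RuntimeError("outlier stage: subset filter left no SNPs")
    sub_pairs = fst.pair_fst_table(subset, codes)
    mat = fst.mean_fst_matrix(sub_pairs, codes)
    files["mean_fst_matrix"] = _write_tsv(mat, out / "mean_fst_matrix.tsv",
                                          index=True)
    wide = fst.pair_table_to_wide(sub_pairs)
    wide = wide.loc[list(zip(subset["chrom"], subset["pos"]))]
    consensus_cfg = fst.TailConsensusConfig(**cfg.consensus)
    consensus = fst.empirical_outlier_consensus(wide, consensus_cfg)
    stats["n_consensus_outliers"] = int(consensus["is_outlier"].sum())
    stats["n_in_any_tail"] = int(consensus["in_any_tail"].sum())

    maj = np.vstack(subset["major_counts"].to_numpy())
    mnr = np.vstack(subset["minor_counts"].to_numpy())
    coverage = maj + mnr
    a_eff, n_eff = bayes.effective_allele_counts(mnr, coverage, n_chr)
    mcmc_cfg = bayes.BayeScanConfig(**{"seed": cfg.seed, **cfg.mcmc})
    posterior = bayes.fit_fst_outlier_model(a_eff, n_eff, mcmc_cfg)
    posterior.insert(0, "pos", subset["pos"].to_numpy())
    posterior.insert(0, "chrom", subset["chrom"].to_numpy())
    files["posterior_outliers"] = _write_tsv(posterior, out / "posterior_outliers.tsv")
    stats["n_bayes_flagged"] = int(posterior["flagged"].sum())

    outliers = pd.DataFrame({
        "chrom": subset["chrom"].to_numpy(),
        "pos": subset["pos"].to_numpy(),
        "tail_count": consensus["tail_count"].to_numpy(),
        "consensus_outlier": consensus["is_outlier"].to_numpy(),
        "bayes_flagged": posterior["flagged"].to_numpy(),
        "sign": posterior["sign"].to_numpy(),
    })
    outliers["intersection_outlier"] = (outliers["consensus_outlier"]
                                        & outliers["bayes_flagged"])
    files["outliers"] = _write_tsv(outliers, out / "outliers.tsv")
    stats["n_intersection_outliers"] = int(outliers["intersection_outlier"].sum())
    logger.info("outliers: %d subset SNPs → %d consensus, %d Bayesian, "
                "%d intersection", len(subset),
                stats["n_consensus_outliers"], stats["n_bayes_flagged"],
                stats["n_intersection_outliers"])

    # --- covariance and environmental association -------------------------
    with np.errstate(invalid="ignore"):
        freqs = np.where(coverage > 0, mnr / np.maximum(coverage, 1), np.nan)
    freqs = np.nan_to_num(freqs, nan=0.5)
    flagged_any = (outliers["consensus_outlier"]
                   | outliers["bayes_flagged"]).to_numpy()
    env = _env_table(meta, cfg.env_variables)
    omega0 = bayes.estimate_covariance(freqs, n_eff)
    bf0, _ = bayes.run_env_association(freqs, env, omega0, n_eff,
                                       thresholds=cfg.bf_thresholds)
    bf0_max = bf0.groupby("locus")["log10_bf"].max().to_numpy()
    neutral = ~flagged_any & (bf0_max <= cfg.bf_thresholds[0])
    if neutral.sum() >= 50:
        omega = bayes.estimate_covariance(freqs[neutral], n_eff[neutral])
    else:
        logger.warning("covariance: only %d provisional neutral loci; "
                       "keeping the all-locus matrix", int(neutral.sum()))
        omega = omega0
    omega_df = pd.DataFrame(omega, index=codes, columns=codes)
    files["covariance"] = _write_tsv(omega_df, out / "covariance.tsv", index=True)
    bf_table, bf_sets = bayes.run_env_association(
        freqs, env, omega, n_eff, thresholds=cfg.bf_thresholds)
    bf_out = bf_table.pivot(index="locus", columns="variable",
                            values="log10_bf").reset_index()
    bf_out.insert(1, "pos", subset["pos"].to_numpy())
    bf_out.insert(1, "chrom", subset["chrom"].to_numpy())
    files["env_bayes_factors"] = _write_tsv(bf_out, out / "env_bayes_factors.tsv")
    for name in cfg.env_variables:
        for thr in cfg.bf_thresholds:
            stats[f"n_bf_{name}_gt_{thr:g}"] = len(bf_sets[name][thr])
    stats["n_bf_intersection"] = len(bf_sets["intersection"])
    logger.info("envassoc: %s", {k: v for k, v in stats.items()
                                 if k.startswith("n_bf")})

    # --- population structure --------------------------------------------
    ord_res = structure.pcoa(mat)
    coords = pd.DataFrame(
        ord_res.coordinates, index=codes,
        columns=[f"PCO{i+1}" for i in range(ord_res.coordinates.shape[1])])
    files["pcoa"] = _write_tsv(coords, out / "pcoa_coordinates.tsv", index=True)
    tree, supports = structure.bootstrap_support(
        wide, codes, n_replicates=cfg.bootstrap_replicates, seed=cfg.seed)
    tree_path = out / "nj_tree.nwk"
    tree_path.write_text(tree.newick() + "\n")
    files["nj_tree"] = tree_path
    geo = structure.geographic_distance_matrix(meta)
    r_ibd, p_ibd = structure.mantel_test(
        mat, geo, n_perm=cfg.mantel_permutations, seed=cfg.seed,
        transform_a="linearized_fst", transform_b="log")
    mantel_df = pd.DataFrame([("ibd_linearized_fst_vs_log_km", r_ibd, p_ibd,
                               cfg.mantel_permutations)],
                             columns=["test", "r", "p", "n_permutations"])
    files["mantel"] = _write_tsv(mantel_df, out / "mantel.tsv")
    stats["ibd_mantel_r"] = r_ibd
    stats["ibd_mantel_p"] = p_ibd

    # --- annotation and GO enrichment -------------------------------------
    if annotation_path is not None:
        go_terms = load_go_map(go_path) if go_path else {}
        genes = read_gene_intervals_gff3(annotation_path, go_map=go_terms)
        snp_genes = structure.map_snps_to_genes(subset[["chrom", "pos"]], genes)
        files["snp_genes"] = _write_tsv(
            snp_genes[["chrom", "pos", "annotation"]], out / "snp_genes.tsv")
        bf_final_max = bf_table.groupby("locus")["log10_bf"].max().to_numpy()
        assoc = bf_final_max > cfg.bf_thresholds[0]
        inter = outliers["intersection_outlier"].to_numpy()

        def genes_of(mask: np.ndarray) -> set[str]:
            hit: set[str] = set()
            for ids in snp_genes.loc[mask, "genes"]:
                hit.update(ids)
            return hit

        candidate_genes = genes_of(inter) | genes_of(assoc)
        neutral_genes = genes_of(~(inter | assoc)) - candidate_genes
        stats["n_candidate_genes"] = len(candidate_genes)
        gene_list = pd.DataFrame(sorted(candidate_genes), columns=["gene_id"])
        files["candidate_genes"] = _write_tsv(gene_list, out / "candidate_genes.tsv")
        if go_terms and candidate_genes and neutral_genes:
            enrich = structure.go_enrichment(candidate_genes, neutral_genes,
                                             go_terms)
            files["go_enrichment"] = _write_tsv(enrich, out / "go_enrichment.tsv")

    # --- manifest ---------------------------------------------------------
    manifest = {
        "stats": stats,
        "files": {name: {"path": str(p.relative_to(out)),
                         "sha256": _sha256(p)}
                  for name, p in sorted(files.items())},
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest
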