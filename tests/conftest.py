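"""Shared fixtures: the default synthetic seascape and a fitted outlier model.

The expensive pieces (read simulation, the MCMC fit) are session-scoped so
the recovery and calibration tests share one realization of the default
study conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poolscan import bayes, popgen
from poolscan.io_formats import baltic_metadata
from poolscan.simulate import SimConfig, simulate_frequencies, simulate_pool_reads

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def metadata():
    return baltic_metadata()


@pytest.fixture(scope="session")
def default_sim(metadata):
    """Default study conditions: 500 neutral + 20 divergent + 40 env loci."""
    cfg = SimConfig(seed=DEFAULT_SEED)
    freqs, truth = simulate_frequencies(cfg, metadata)
    sites = simulate_pool_reads(freqs, cfg, metadata)
    return {"cfg": cfg, "freqs": freqs, "truth": truth, "sites": sites}


@pytest.fixture(scope="session")
def default_subset(default_sim):
    """Stringently filtered SNPs of the default simulation with truth labels."""
    subset = popgen.call_snps(default_sim["sites"],
                              popgen.SiteFilterConfig.selection_subset())
    labels = subset[["chrom", "pos"]].merge(
        default_sim["truth"][["chrom", "pos", "class"]], on=["chrom", "pos"])
    maj = np.vstack(subset["major_counts"].to_numpy())
    mnr = np.vstack(subset["minor_counts"].to_numpy())
    return {"snps": subset, "classes": labels["class"].to_numpy(),
            "major": maj, "minor": mnr, "coverage": maj + mnr}


@pytest.fixture(scope="session")
def default_posterior(default_subset):
    """Outlier-model fit on the default simulation (short tuned chain)."""
    a, ne = bayes.effective_allele_counts(
        default_subset["minor"], default_subset["coverage"], 72)
    post = bayes.fit_fst_outlier_model(a, ne, bayes.BayeScanConfig.fast(seed=1))
    post["class"] = default_subset["classes"]
    return post
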