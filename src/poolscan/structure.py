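"""Population-structure summaries and SNP annotation.

Covers classical multivariate views of a pairwise-FST matrix (principal
coordinates, neighbor-joining with locus bootstrap), isolation-by-distance
Mantel tests on linearized FST versus log geographic distance, interval
annotation of SNPs against gene spans, and GO-term enrichment of candidate
genes against the neutral background by the exact hypergeometric test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneInterval


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix."""

    labels: list[str]
    coordinates: np.ndarray   # n × k, axes ordered by decreasing eigenvalue
    eigenvalues: np.ndarray   # all n eigenvalues, descending (may be negative)
    proportion_explained: np.ndarray  # per retained axis, of positive inertia


def pcoa(
    dist: np.ndarray | pd.DataFrame,
    labels: Sequence[str] | None = None,
    negative_correction: str = "none",
) -> OrdinationResult:
    """Principal coordinates analysis (classical metric scaling).

    Eigendecomposes −½·J·D⁽²⁾·J with J the centering matrix; axes with
    positive eigenvalues are retained, negative eigenvalues are reported
    unused.  ``negative_correction="lingoes"`` adds the smallest constant to
    off-diagonal squared distances making the matrix Euclidean.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        dist = dist.to_numpy(dtype=float)
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    d2 = d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    w, v = np.linalg.eigh(B)
    if negative_correction == "lingoes" and w.min() < -1e-12:
        c = -w.min()
        d2 = d2 + 2.0 * c * (1.0 - np.eye(n))
        B = -0.5 * J @ d2 @ J
        w, v = np.linalg.eigh(B)
    elif negative_correction not in ("none", "lingoes"):
        raise ValueError(f"unknown correction {negative_correction!r}")
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > 1e-12
    coords = v[:, pos] * np.sqrt(w[pos])
    total_pos = w[pos].sum()
    prop = w[pos] / total_pos if total_pos > 0 else w[pos]
    return OrdinationResult(list(labels), coords, w, prop)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of an unrooted tree (the 'root' is just a degree-3 anchor)."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> set[str]:
        if not self.children:
            return {self.name}
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaves()
        return out

    def newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if not self.children:
            return self.name or ""
        parts = [f"{c._newick_inner()}:{ln:.6g}" for c, ln in self.children]
        label = "" if self.support is None else f"{self.support:g}"
        return f"({','.join(parts)}){label}"


def _canonical_bipartition(side: frozenset, all_leaves: frozenset,
                           anchor: str) -> frozenset:
    return frozenset(all_leaves - side) if anchor in side else side


def tree_bipartitions(root: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized to the
    side not containing the alphabetically first leaf."""
    all_leaves = frozenset(root.leaves())
    anchor = min(all_leaves)
    out: set[frozenset] = set()

    def walk(node: TreeNode):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(_canonical_bipartition(side, all_leaves, anchor))
            walk(child)

    walk(root)
    return out


def nj_tree(dist: np.ndarray | pd.DataFrame,
            labels: Sequence[str] | None = None) -> TreeNode:
    """Neighbor-joining (Saitou–Nei) tree from a distance matrix.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling edge of the join, keeping the cherry's total length.  The
    returned anchor node has degree 3 (unrooted convention).
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        dist = dist.to_numpy(dtype=float)
    D = np.asarray(dist, dtype=float).copy()
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if labels is None:
        labels = [str(i) for i in range(n)]
    nodes: list[TreeNode] = [TreeNode(name=str(lb)) for lb in labels]
    while len(nodes) > 3:
        N = D.shape[0]
        r = D.sum(axis=1)
        Q = (N - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (N - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(N) if k not in (i, j)]
        D_next = np.empty((N - 1, N - 1))
        D_next[:-1, :-1] = D[np.ix_(keep, keep)]
        D_next[-1, :-1] = D_next[:-1, -1] = d_new[keep]
        D_next[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        D = D_next
    # final three-way join
    (a, b, c) = range(3)
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    lengths = [la, lb, lc]
    for k in range(3):
        if lengths[k] < 0:  # push the deficit onto the longest other edge
            m = max((x for x in range(3) if x != k), key=lambda x: lengths[x])
            lengths[m] += lengths[k]
            lengths[k] = 0.0
    return TreeNode(children=[(nodes[k], lengths[k]) for k in range(3)])


def bootstrap_support(
    fst_wide: pd.DataFrame,
    codes: Sequence[str],
    n_replicates: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree with locus-bootstrap support on internal edges.

    ``fst_wide`` is the SNP × pair per-locus FST table (columns named
    ``"A-B"``).  Loci (rows) are resampled with replacement; each replicate
    recomputes the mean FST matrix and its NJ tree; support for an internal
    bipartition of the point-estimate tree is the percentage of replicates
    containing it.
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    if len(codes) < 3 or len(fst_wide) < 2:
        raise ValueError("need >= 3 taxa and >= 2 loci")
    rng = np.random.default_rng(seed)

    def matrix_from(table: pd.DataFrame) -> pd.DataFrame:
        mat = pd.DataFrame(0.0, index=list(codes), columns=list(codes))
        means = table.mean(axis=0, skipna=True)
        for pair, v in means.items():
            a, b = str(pair).split("-")
            mat.loc[a, b] = mat.loc[b, a] = float(v)
        return mat

    point_tree = nj_tree(matrix_from(fst_wide))
    point_bips = tree_bipartitions(point_tree)
    counts = {bip: 0 for bip in point_bips}
    L = len(fst_wide)
    for _ in range(n_replicates):
        idx = rng.integers(0, L, size=L)
        rep_bips = tree_bipartitions(nj_tree(matrix_from(fst_wide.iloc[idx])))
        for bip in point_bips:
            if bip in rep_bips:
                counts[bip] += 1
    supports = {bip: 100.0 * c / n_replicates for bip, c in counts.items()}

    all_leaves = frozenset(point_tree.leaves())
    anchor = min(all_leaves)

    def annotate(node: TreeNode):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 2 <= len(side) <= len(all_leaves) - 2:
                child.support = supports[
                    _canonical_bipartition(side, all_leaves, anchor)]
            annotate(child)

    annotate(point_tree)
    return point_tree, supports


# ---------------------------------------------------------------------------
# Mantel tests and isolation by distance
# ---------------------------------------------------------------------------

def linearized_fst(x: float) -> float:
    """FST/(1−FST), the distance transform for isolation-by-distance."""
    return x / (1.0 - x)


_TRANSFORMS: dict[str, Callable[[float], float]] = {
    "identity": lambda x: x,
    "linearized_fst": linearized_fst,
    "log": math.log,
}


def _offdiag(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_test(
    mat_a: np.ndarray | pd.DataFrame,
    mat_b: np.ndarray | pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
    transform_a: str | Callable[[float], float] = "identity",
    transform_b: str | Callable[[float], float] = "identity",
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    Transforms (identity, linearized FST, log) are applied element-wise to
    the off-diagonals; r is the Pearson correlation of the upper triangles;
    the one-sided p-value is (1 + #{permuted r ≥ observed})/(n_perm + 1),
    jointly permuting rows and columns of the second matrix.
    """
    A = np.asarray(mat_a, dtype=float) if not isinstance(mat_a, pd.DataFrame) \
        else mat_a.to_numpy(dtype=float)
    B = np.asarray(mat_b, dtype=float) if not isinstance(mat_b, pd.DataFrame) \
        else mat_b.to_numpy(dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and matched")
    ta = _TRANSFORMS[transform_a] if isinstance(transform_a, str) else transform_a
    tb = _TRANSFORMS[transform_b] if isinstance(transform_b, str) else transform_b
    n = A.shape[0]
    mask = ~np.eye(n, dtype=bool)
    At = A.copy()
    Bt = B.copy()
    try:
        At[mask] = [ta(v) for v in A[mask]]
        Bt[mask] = [tb(v) for v in B[mask]]
    except ValueError as err:
        raise ValueError(f"transform failed on off-diagonal value: {err}") from err
    a_flat = _offdiag(At)
    r_obs = float(stats.pearsonr(a_flat, _offdiag(Bt)).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = float(stats.pearsonr(
            a_flat, _offdiag(Bt[np.ix_(perm, perm)])).statistic)
        if r_perm >= r_obs:
            count += 1
    return r_obs, (1.0 + count) / (n_perm + 1.0)


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Haversine great-circle distance in kilometres."""
    rlat1, rlon1, rlat2, rlon2 = map(math.radians, (lat1, lon1, lat2, lon2))
    dlat = rlat2 - rlat1
    dlon = rlon2 - rlon1
    h = math.sin(dlat / 2) ** 2 \
        + math.cos(rlat1) * math.cos(rlat2) * math.sin(dlon / 2) ** 2
    return 2.0 * 6371.0088 * math.asin(math.sqrt(h))


def geographic_distance_matrix(metadata) -> pd.DataFrame:
    """Great-circle distance matrix (km) from population coordinates."""
    codes = [m.code for m in metadata]
    mat = pd.DataFrame(0.0, index=codes, columns=codes)
    for i, a in enumerate(metadata):
        for b in metadata[i + 1:]:
            d = great_circle_km(a.latitude, a.longitude, b.latitude, b.longitude)
            mat.loc[a.code, b.code] = mat.loc[b.code, a.code] = d
    return mat


# ---------------------------------------------------------------------------
# SNP annotation and GO enrichment
# ---------------------------------------------------------------------------

def map_snps_to_genes(
    snps: pd.DataFrame, genes: Iterable[GeneInterval]
) -> pd.DataFrame:
    """Assign each SNP to every gene whose 1-based span contains it.

    ``snps`` needs columns (chrom, pos).  Returns one row per SNP with
    ``genes`` (sorted list of gene ids, empty when intergenic) and the
    label ``"none"`` in ``annotation`` for intergenic SNPs.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    hits = []
    for chrom, pos in zip(snps["chrom"], snps["pos"]):
        tree = trees.get(str(chrom))
        ids = sorted(iv.data for iv in tree[int(pos)]) if tree is not None else []
        hits.append(ids)
    out = snps[["chrom", "pos"]].copy()
    out["genes"] = hits
    out["annotation"] = [",".join(h) if h else "none" for h in hits]
    return out


def go_enrichment(
    candidate_genes: set[str],
    background_genes: set[str],
    go_map: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Two-sided exact hypergeometric GO enrichment with BH adjustment.

    The candidate set (genes with outlier/associated SNPs) is compared to
    the disjoint neutral background; terms with zero total membership are
    skipped.  Returns per-term counts, odds ratio, exact p and adjusted p,
    sorted by p.
    """
    if not go_map:
        raise ValueError("empty gene→GO map")
    if not candidate_genes or not background_genes:
        raise ValueError("candidate and background sets must be non-empty")
    overlap = candidate_genes & background_genes
    if overlap:
        raise ValueError(f"candidate and background overlap: {sorted(overlap)[:5]}")
    terms: set[str] = set()
    for g in candidate_genes | background_genes:
        terms |= set(go_map.get(g, set()))
    rows = []
    n_cand = len(candidate_genes)
    n_bg = len(background_genes)
    for term in sorted(terms):
        cand_with = sum(1 for g in candidate_genes if term in go_map.get(g, ()))
        bg_with = sum(1 for g in background_genes if term in go_map.get(g, ()))
        if cand_with + bg_with == 0:
            continue
        table = [[cand_with, n_cand - cand_with], [bg_with, n_bg - bg_with]]
        res = stats.fisher_exact(table, alternative="two-sided")
        rows.append((term, cand_with, n_cand - cand_with, bg_with,
                     n_bg - bg_with, res.statistic, res.pvalue))
    df = pd.DataFrame(rows, columns=["go_term", "candidate_with",
                                     "candidate_without", "background_with",
                                     "background_without", "odds_ratio", "p"])
    if len(df):
        df["p_adjusted"] = multipletests(df["p"], method="fdr_bh")[1]
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        df["p_adjusted"] = pd.Series(dtype=float)
    return df
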