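"""Ordination, neighbor joining, Mantel tests, annotation, GO enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from poolscan import structure
from poolscan.io_formats import GeneInterval


class TestPcoa:
    def test_collinear_points_single_axis(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        res = structure.pcoa(d)
        assert res.eigenvalues[0] > 1e-9
        assert abs(res.eigenvalues[1]) < 1e-9
        got = abs(res.coordinates[0, 0] - res.coordinates[2, 0])
        assert got == pytest.approx(2.0)

    def test_zero_distances_zero_eigenvalues(self):
        res = structure.pcoa(np.zeros((4, 4)))
        assert np.allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = structure.pcoa(d)
        emb = res.coordinates[:, :2]
        d_hat = np.linalg.norm(emb[:, None] - emb[None, :], axis=-1)
        assert np.allclose(d_hat, d, atol=1e-9)

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            structure.pcoa(d)

    def test_lingoes_correction_removes_negativity(self):
        d = np.array([[0, 1, 4, 1], [1, 0, 1, 4], [4, 1, 0, 1],
                      [1, 4, 1, 0.0]])
        plain = structure.pcoa(d)
        fixed = structure.pcoa(d, negative_correction="lingoes")
        assert plain.eigenvalues.min() < -1e-9
        assert fixed.eigenvalues.min() >= -1e-9


def additive_matrix_from_quartet(lengths):
    """Distances on the quartet tree ((A,B),(C,D)) with given edge lengths."""
    la, lb, lc, ld, lm = lengths
    names = ["A", "B", "C", "D"]
    d = pd.DataFrame(0.0, index=names, columns=names)
    d.loc["A", "B"] = d.loc["B", "A"] = la + lb
    d.loc["A", "C"] = d.loc["C", "A"] = la + lm + lc
    d.loc["A", "D"] = d.loc["D", "A"] = la + lm + ld
    d.loc["B", "C"] = d.loc["C", "B"] = lb + lm + lc
    d.loc["B", "D"] = d.loc["D", "B"] = lb + lm + ld
    d.loc["C", "D"] = d.loc["D", "C"] = lc + ld
    return d


def _edge_lengths(tree):
    out = {}

    def walk(node):
        for child, ln in node.children:
            if not child.children:
                out[child.name] = ln
            walk(child)

    walk(tree)
    return out


def enumerate_unrooted_topologies(names):
    """All unrooted binary topologies as sets of nontrivial bipartitions."""
    n = len(names)
    topologies = []
    if n == 4:
        for a, b in itertools.combinations(names, 2):
            topologies.append({frozenset({a, b})})
    elif n == 5:
        for pair in itertools.combinations(names, 2):
            rest = [x for x in names if x not in pair]
            for other in itertools.combinations(rest, 2):
                topologies.append({frozenset(pair), frozenset(other)})
        # canonicalize: bipartition side not containing min name
        canon = []
        allset = frozenset(names)
        anchor = min(names)
        for top in topologies:
            canon.append({frozenset(allset - s) if anchor in s else s
                          for s in top})
        # deduplicate (each 5-taxon topology has exactly 2 internal edges)
        seen = []
        for top in canon:
            if top not in seen and len(top) == 2:
                ok = all(2 <= len(s) <= 3 for s in top)
                if ok:
                    seen.append(top)
        return seen
    return topologies


def ls_fit_residual(d, bipartitions, names):
    """Least-squares branch lengths for a topology; returns residual SS."""
    pairs = list(itertools.combinations(names, 2))
    edges = [frozenset({x}) for x in names] + list(bipartitions)
    X = np.zeros((len(pairs), len(edges)))
    y = np.array([d.loc[a, b] for a, b in pairs])
    for r, (a, b) in enumerate(pairs):
        for c, side in enumerate(edges):
            # an edge lies on the a–b path iff it separates a from b
            if (a in side) != (b in side):
                X[r, c] = 1.0
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(((X @ coef - y) ** 2).sum())


class TestNeighborJoining:
    def test_quartet_exact_recovery(self):
        d = additive_matrix_from_quartet([0.2, 0.3, 0.4, 0.5, 0.7])
        tree = structure.nj_tree(d)
        bips = structure.tree_bipartitions(tree)
        assert frozenset({"C", "D"}) in bips or frozenset({"A", "B"}) in bips
        lengths = _edge_lengths(tree)
        assert lengths["A"] == pytest.approx(0.2)
        assert lengths["D"] == pytest.approx(0.5)

    def test_three_taxa_unique_resolution(self):
        d = pd.DataFrame([[0, 2, 2], [2, 0, 2], [2, 2, 0.0]],
                         index=list("ABC"), columns=list("ABC"))
        tree = structure.nj_tree(d)
        lengths = _edge_lengths(tree)
        assert all(v == pytest.approx(1.0) for v in lengths.values())

    def test_taxon_order_invariance(self):
        d = additive_matrix_from_quartet([0.2, 0.3, 0.4, 0.5, 0.7])
        perm = ["C", "A", "D", "B"]
        t1 = structure.tree_bipartitions(structure.nj_tree(d))
        t2 = structure.tree_bipartitions(
            structure.nj_tree(d.loc[perm, perm]))
        assert t1 == t2

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            structure.nj_tree(np.zeros((2, 2)))

    def test_recovers_topology_on_random_additive_5taxon_matrices(self):
        rng = np.random.default_rng(9)
        names = list("ABCDE")
        topologies = enumerate_unrooted_topologies(names)
        assert len(topologies) == 15
        for trial in range(15):
            # build a random additive matrix from a random topology
            top = topologies[trial]
            edges = [frozenset({x}) for x in names] + list(top)
            lengths = {e: float(rng.uniform(0.1, 1.0)) for e in edges}
            d = pd.DataFrame(0.0, index=names, columns=names)
            for a, b in itertools.combinations(names, 2):
                total = sum(l for e, l in lengths.items()
                            if (a in e) != (b in e))
                d.loc[a, b] = d.loc[b, a] = total
            got = structure.tree_bipartitions(structure.nj_tree(d))
            # oracle: exhaustive least-squares over all 15 topologies
            fits = [(ls_fit_residual(d, t, names), i)
                    for i, t in enumerate(topologies)]
            best = topologies[min(fits)[1]]
            assert got == best == top


class TestBootstrapSupport:
    def _wide(self, rows, codes):
        pairs = [f"{a}-{b}" for a, b in itertools.combinations(codes, 2)]
        return pd.DataFrame(rows, columns=pairs)

    def test_identical_loci_full_support(self):
        codes = list("ABCD")
        row = [0.1, 0.4, 0.4, 0.4, 0.4, 0.1]
        wide = self._wide([row] * 10, codes)
        tree, supports = structure.bootstrap_support(wide, codes,
                                                     n_replicates=50, seed=0)
        assert all(v == 100.0 for v in supports.values())

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        codes = list("ABCDE")
        wide = self._wide(rng.random((30, 10)), codes)
        _, s1 = structure.bootstrap_support(wide, codes, 100, seed=5)
        _, s2 = structure.bootstrap_support(wide, codes, 100, seed=5)
        assert s1 == s2

    def test_separated_clusters_strong_support(self):
        rng = np.random.default_rng(2)
        codes = list("ABCDEF")  # clusters ABC and DEF
        rows = []
        for _ in range(120):
            row = []
            for a, b in itertools.combinations(codes, 2):
                within = (a in "ABC") == (b in "ABC")
                base = 0.01 if within else 0.3
                row.append(base + rng.normal(0, 0.01))
            rows.append(row)
        tree, supports = structure.bootstrap_support(self._wide(rows, codes),
                                                     codes, 200, seed=0)
        split = frozenset({"D", "E", "F"})
        assert supports[split] >= 95.0


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        r, p = structure.mantel_test(d, d, n_perm=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_linearized_fst_transform(self):
        assert structure.linearized_fst(0.5) == pytest.approx(1.0)

    def test_log_of_nonpositive_distance_rejected(self):
        d = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="transform"):
            structure.mantel_test(d, d, n_perm=9, transform_b="log")

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(3)
        n, draws = 10, 400
        rejections = 0
        for i in range(draws):
            a = rng.random((n, n))
            b = rng.random((n, n))
            a = (a + a.T) / 2
            b = (b + b.T) / 2
            np.fill_diagonal(a, 0)
            np.fill_diagonal(b, 0)
            _, p = structure.mantel_test(a, b, n_perm=99, seed=i)
            rejections += p <= 0.05
        assert 0.02 <= rejections / draws <= 0.08


class TestSnpGeneMapping:
    GENES = [
        GeneInterval("outer", "c1", 100, 500),
        GeneInterval("inner", "c1", 200, 300),
        GeneInterval("solo", "c2", 50, 60),
    ]

    def _map(self, chrom, pos):
        snps = pd.DataFrame({"chrom": [chrom], "pos": [pos]})
        return structure.map_snps_to_genes(snps, self.GENES).iloc[0]

    def test_start_coordinate_inclusive(self):
        assert self._map("c1", 100)["genes"] == ["outer"]

    def test_end_coordinate_inclusive_but_not_beyond(self):
        assert self._map("c2", 60)["genes"] == ["solo"]
        assert self._map("c2", 61)["annotation"] == "none"

    def test_nested_genes_both_assigned(self):
        assert self._map("c1", 250)["genes"] == ["inner", "outer"]

    def test_intergenic_labelled_none(self):
        assert self._map("c1", 50)["annotation"] == "none"


def hypergeom_two_sided_exact(k, K, n, N):
    """Two-sided Fisher p for a 2×2 table by enumerating the support:
    sum of hypergeometric point masses not exceeding the observed one."""
    lo = max(0, n - (N - K))
    hi = min(n, K)
    obs = hypergeom.pmf(k, N, K, n)
    total = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom.pmf(x, N, K, n)
        if px <= obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestGoEnrichment:
    def _go_map(self, cand_with, cand_total, bg_with, bg_total, term="GO:T"):
        cand = {f"c{i}" for i in range(cand_total)}
        bg = {f"b{i}" for i in range(bg_total)}
        gm = {}
        for i, g in enumerate(sorted(cand)):
            gm[g] = {term} if i < cand_with else {"GO:other"}
        for i, g in enumerate(sorted(bg)):
            gm[g] = {term} if i < bg_with else {"GO:other"}
        return cand, bg, gm

    def test_exclusive_term_most_significant(self):
        cand, bg, gm = self._go_map(5, 5, 0, 50)
        out = structure.go_enrichment(cand, bg, gm)
        assert out.iloc[0]["go_term"] == "GO:T"
        assert out.iloc[0]["p"] == out["p"].min()

    def test_matches_hypergeometric_enumeration(self):
        for (kw, kt, bw, bt) in [(4, 10, 10, 20), (2, 8, 12, 22),
                                 (6, 9, 3, 21), (1, 5, 14, 25)]:
            cand, bg, gm = self._go_map(kw, kt, bw, bt)
            out = structure.go_enrichment(cand, bg, gm)
            row = out[out["go_term"] == "GO:T"].iloc[0]
            expected = hypergeom_two_sided_exact(kw, kw + bw, kt, kt + bt)
            assert row["p"] == pytest.approx(expected, rel=1e-9)

    def test_identical_composition_not_significant(self):
        cand, bg, gm = self._go_map(5, 10, 10, 20)
        out = structure.go_enrichment(cand, bg, gm)
        assert (out["p"] > 0.99).all()

    def test_adjusted_p_not_below_raw(self):
        cand, bg, gm = self._go_map(4, 10, 5, 30)
        out = structure.go_enrichment(cand, bg, gm)
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            structure.go_enrichment({"g1"}, {"g1", "g2"}, {"g1": {"GO:1"}})

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="map"):
            structure.go_enrichment({"a"}, {"b"}, {})
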