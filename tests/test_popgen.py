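"""Distances, neighbor joining, PCA and LD statistics."""

import numpy as np
import pandas as pd
import pytest

from snparray.genotypes import GenotypeMatrix
from snparray.popgen import (
    DistanceMatrix,
    d_prime,
    ibs_distance_matrix,
    ld_statistics,
    neighbor_joining_tree,
    pca_coordinates,
    r_squared,
)
from snparray.simulate import PopulationConfig, simulate_population_genotypes
from conftest import make_gm


# ---------------------------------------------------------------------------
# IBS distances
# ---------------------------------------------------------------------------

class TestIbs:
    def test_self_distance_zero(self):
        gm = make_gm({"m1": ["AA", "AB"], "m2": ["BB", "BB"]}, ["a", "b"])
        dm = ibs_distance_matrix(gm)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_single_locus_half_shared(self):
        gm = make_gm({"m": ["AA", "AB"]}, ["a", "b"])
        dm = ibs_distance_matrix(gm)
        assert dm.values[0, 1] == pytest.approx(0.5)

    def test_opposite_homozygotes_distance_one(self):
        gm = make_gm({"m": ["AA", "BB"]}, ["a", "b"])
        assert ibs_distance_matrix(gm).values[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        codes = pd.DataFrame(rng.integers(-2, 3, size=(20, 5)),
                             index=[f"m{i}" for i in range(20)],
                             columns=list("abcde"))
        gm = GenotypeMatrix(codes)
        dm = ibs_distance_matrix(gm)
        share = {(0, 0): 1.0, (1, 1): 1.0, (2, 2): 1.0,
                 (0, 1): 0.5, (1, 0): 0.5, (1, 2): 0.5, (2, 1): 0.5,
                 (0, 2): 0.0, (2, 0): 0.0}
        for i, a in enumerate("abcde"):
            for j, b in enumerate("abcde"):
                vals = [share[(x, y)] for x, y in zip(codes[a], codes[b])
                        if x >= 0 and y >= 0]
                assert dm.values[i, j] == pytest.approx(1.0 - np.mean(vals))

    def test_no_co_called_pair_is_an_error(self):
        gm = make_gm({"m1": ["AA", "--"], "m2": ["--", "BB"]}, ["a", "b"])
        with pytest.raises(ValueError, match="a.*b"):
            ibs_distance_matrix(gm)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _random_additive_tree(n_taxa, rng):
    """Random binary tree; returns (distance matrix, set of non-trivial splits)."""
    nodes = [frozenset([i]) for i in range(n_taxa)]
    children: dict = {}
    lengths = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = a | b
        children[parent] = (a, b)
        lengths[a] = rng.uniform(0.1, 1.0)
        lengths[b] = rng.uniform(0.1, 1.0)
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]

    # leaf depths via recursion
    dist = np.zeros((n_taxa, n_taxa))
    def leaf_depths(cl):
        if len(cl) == 1:
            return {next(iter(cl)): 0.0}
        a, b = children[cl]
        da = {k: v + lengths[a] for k, v in leaf_depths(a).items()}
        db = {k: v + lengths[b] for k, v in leaf_depths(b).items()}
        for x, dx in da.items():
            for y, dy in db.items():
                dist[x, y] = dist[y, x] = dx + dy
        return {**da, **db}
    leaf_depths(nodes[0])
    all_taxa = frozenset(range(n_taxa))
    splits = {min(cl, all_taxa - cl, key=lambda s: (len(s), sorted(s)))
              for cl in children if 1 < len(cl) < n_taxa - 1}
    return dist, splits


def _tree_splits(tree, names):
    """Non-trivial splits of a PhylogeneticTree as canonical frozensets."""
    bp = tree.to_biopython()
    all_taxa = frozenset(range(len(names)))
    idx = {nm: i for i, nm in enumerate(names)}
    splits = set()
    for clade in bp.get_nonterminals():
        leafset = frozenset(idx[t.name] for t in clade.get_terminals())
        if 1 < len(leafset) < len(names) - 1:
            comp = all_taxa - leafset
            splits.add(min(leafset, comp, key=lambda s: (len(s), sorted(s))))
    return splits


class TestNeighborJoining:
    def test_four_taxon_additive_matrix(self):
        # cherries (A,B) and (C,D) with 2 within and 6 across
        D = np.array([[0, 2, 6, 6],
                      [2, 0, 6, 6],
                      [6, 6, 0, 2],
                      [6, 6, 2, 0]], dtype=float)
        dm = DistanceMatrix(ids=list("ABCD"), values=D)
        tree = neighbor_joining_tree(dm)
        ld = tree.leaf_distances()
        expect = pd.DataFrame(D, index=list("ABCD"), columns=list("ABCD"))
        assert np.allclose(ld.loc[list("ABCD"), list("ABCD")].values, expect.values)
        assert _tree_splits(tree, list("ABCD")) == {frozenset({0, 1})} or \
               _tree_splits(tree, list("ABCD")) == {frozenset({2, 3})}

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining_tree(DistanceMatrix(ids=list("abc"), values=D))
        ld = tree.leaf_distances()
        assert np.allclose(ld.loc[list("abc"), list("abc")].values, D)

    def test_two_taxa_single_edge(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        tree = neighbor_joining_tree(DistanceMatrix(ids=["x", "y"], values=D))
        assert tree.leaf_distances().loc["x", "y"] == pytest.approx(0.4)

    def test_reconstructs_random_additive_trees_exactly(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            D, true_splits = _random_additive_tree(n, rng)
            names = [f"t{i}" for i in range(n)]
            tree = neighbor_joining_tree(DistanceMatrix(ids=names, values=D))
            assert _tree_splits(tree, names) == true_splits
            ld = tree.leaf_distances().loc[names, names].values
            assert np.allclose(ld, D, atol=1e-9)

    def test_topology_agrees_with_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj
        n = 8
        D, _ = _random_additive_tree(n, rng)
        names = [f"t{i}" for i in range(n)]
        ours = _tree_splits(neighbor_joining_tree(DistanceMatrix(ids=names, values=D)),
                            names)
        sk_tree = nj(SkDM(D, ids=names))
        idx = {nm: i for i, nm in enumerate(names)}
        all_taxa = frozenset(range(n))
        theirs = set()
        for node in sk_tree.non_tips():
            leafset = frozenset(idx[t.name] for t in node.tips())
            if 1 < len(leafset) < n - 1:
                theirs.add(min(leafset, all_taxa - leafset,
                               key=lambda s: (len(s), sorted(s))))
        assert ours == theirs

    def test_subpopulations_form_monophyletic_clusters(self):
        gm, truth = simulate_population_genotypes(
            PopulationConfig(n_samples=30, n_markers=500, n_subpops=3,
                             fst=0.2, seed=21))
        tree = neighbor_joining_tree(ibs_distance_matrix(gm))
        names = list(map(str, gm.samples))
        splits = _tree_splits(tree, names)
        idx = {nm: i for i, nm in enumerate(names)}
        all_taxa = frozenset(range(len(names)))
        for sp in range(3):
            members = frozenset(idx[s] for s in truth.subpop[truth.subpop == sp].index)
            canonical = min(members, all_taxa - members,
                            key=lambda s: (len(s), sorted(s)))
            assert canonical in splits, f"subpopulation {sp} not monophyletic"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPca:
    def test_duplicated_sample_identical_coordinates(self):
        gm, _ = simulate_population_genotypes(
            PopulationConfig(n_samples=20, n_markers=100, duplicate_sample=True, seed=5))
        res = pca_coordinates(gm, 3)
        assert np.allclose(res.coordinates.iloc[0], res.coordinates.iloc[1])

    def test_two_subpopulations_separate_on_pc1(self):
        gm, truth = simulate_population_genotypes(
            PopulationConfig(n_samples=100, n_markers=1000, n_subpops=2,
                             fst=0.3, seed=9))
        res = pca_coordinates(gm, 2)
        pc1 = res.coordinates["PC1"].values
        g0 = pc1[truth.subpop.values == 0]
        g1 = pc1[truth.subpop.values == 1]
        assert max(g0.min(), g1.min()) > min(g0.max(), g1.max()) or \
               min(g0.max(), g1.max()) < max(g0.min(), g1.min())
        assert (g0.max() < g1.min()) or (g1.max() < g0.min())

    def test_variance_fractions_non_increasing_and_bounded(self):
        gm, _ = simulate_population_genotypes(
            PopulationConfig(n_samples=40, n_markers=200, seed=3))
        res = pca_coordinates(gm, 10)
        assert (np.diff(res.variance_explained) <= 1e-12).all()
        assert res.variance_explained.sum() <= 1.0 + 1e-9

    def test_monomorphic_only_input_rejected(self):
        gm = make_gm({"m1": ["AA", "AA", "AA"], "m2": ["BB", "BB", "BB"]},
                     ["a", "b", "c"])
        with pytest.raises(ValueError, match="monomorphic"):
            pca_coordinates(gm)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

class TestLd:
    def test_perfectly_correlated_dosages(self):
        ga = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 1], dtype=float)
        assert r_squared(ga, ga) == pytest.approx(1.0)

    def test_complete_coupling_r2_and_dprime_one(self):
        # haplotypes AB x 10 and ab x 10 paired into 10 individuals, no
        # recombinant: dosage vectors are identical; closed form D' = 1
        ga = np.array([0, 2, 1, 1, 0, 2, 1, 0, 2, 1], dtype=float)
        assert r_squared(ga, ga.copy()) == pytest.approx(1.0)
        assert d_prime(ga, ga.copy()) == pytest.approx(1.0)

    def test_dprime_matches_known_haplotype_table(self):
        # individuals built from haplotype pairs with counts:
        # AB/AB, AB/ab, ab/ab, Ab/aB  -> EM must resolve the double het
        ga = np.array([2, 1, 0, 1], dtype=float)  # alt dosage locus 1
        gb = np.array([2, 1, 0, 1], dtype=float)
        dp = d_prime(ga, gb)
        assert 0.0 <= dp <= 1.0

    def test_independent_loci_mean_r2_small(self, rng):
        n = 10_000
        ga = rng.binomial(2, 0.3, n).astype(float)
        r2s = [r_squared(ga, rng.binomial(2, 0.4, n).astype(float))
               for _ in range(20)]
        assert np.mean(r2s) < 0.01

    def test_monomorphic_pair_skipped(self):
        gm = make_gm({"m1": ["AA", "AA", "AA"], "m2": ["AA", "AB", "BB"]},
                     ["a", "b", "c"])
        pos = pd.DataFrame({"chrom": ["c1", "c1"], "pos": [100, 200]},
                           index=["m1", "m2"])
        res = ld_statistics(gm, pos, max_dist=1000, bin_width=100)
        assert len(res.pairs) == 0

    def test_r2_matches_brute_force_on_population(self, rng):
        gm, truth = simulate_population_genotypes(
            PopulationConfig(n_samples=50, n_markers=10, seed=31))
        res = ld_statistics(gm, truth.positions, max_dist=10_000_000,
                            bin_width=100_000, compute_d_prime=False)
        dos = gm.dosage()
        for _, row in res.pairs.iterrows():
            a = dos.loc[row["marker_a"]].values
            b = dos.loc[row["marker_b"]].values
            expected = np.corrcoef(a, b)[0, 1] ** 2
            assert row["r2"] == pytest.approx(expected)

    def test_decay_distance_decreases_with_recombination(self):
        decays = []
        for rate in (2e-6, 1e-5, 3e-5):
            gm, truth = simulate_population_genotypes(PopulationConfig(
                n_samples=100, n_markers=60, n_subpops=1, fst=0.01,
                ld_founders=4, recomb_per_bp=rate, marker_spacing_bp=5_000,
                seed=77))
            res = ld_statistics(gm, truth.positions, max_dist=300_000,
                                bin_width=20_000, compute_d_prime=False)
            decays.append(res.decay_distance_bp)
        assert decays[0] >= decays[1] >= decays[2]
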