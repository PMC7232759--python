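import numpy as np
import pytest
from hypothesis import given, strategies as st

from charr_gsi import (DistanceMatrix, ScenarioConfig, allele_counts,
                       bootstrap_tree, chord_distance, filter_snps,
                       generate_baseline, ld_rsq, nei_distance,
                       neighbor_joining, pcoa, wc_fst)
from charr_gsi.types import MISSING

from conftest import make_table, random_table
from oracles import (chord_distance_oracle, nei_distance_oracle,
                     random_additive_tree, splits_from_distances,
                     wc_theta_oracle)


class TestAlleleCounts:
    def test_counts_exclude_missing(self):
        t = make_table([[[1, 1]], [[1, 2]], [[MISSING, MISSING]]],
                       ["A", "A", "A"])
        c = allele_counts(t)
        assert c.alleles[0].tolist() == [1, 2]
        assert c.counts[0][0].tolist() == [3, 1]
        assert c.n[0, 0] == 4

    def test_all_missing_locus_dropped_with_warning(self):
        t = make_table([[[1, 1], [MISSING, MISSING]],
                        [[1, 2], [MISSING, MISSING]]], ["A", "A"])
        with pytest.warns(UserWarning, match="dropped"):
            c = allele_counts(t)
        assert c.loci == ["L1"]


class TestWcFst:
    def test_identical_frequencies_give_near_zero_theta(self):
        rng = np.random.default_rng(0)
        genos = [[sorted(rng.integers(1, 4, size=2).tolist())
                  for _ in range(3)] for _ in range(200)]
        t = make_table(genos + genos, ["A"] * 200 + ["B"] * 200)
        assert abs(wc_fst(allele_counts(t), "global")) < 0.02

    def test_fixed_differences_give_theta_one(self, two_pop_fixed):
        assert wc_fst(allele_counts(two_pop_fixed), "global") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_indicator_anova_oracle(self, seed):
        """Random instances agree with an independently coded estimator."""
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_collections=int(rng.integers(2, 5)),
                         n_per=int(rng.integers(3, 10)),
                         n_loci=int(rng.integers(1, 4)))
        counts = allele_counts(t)
        per_locus = []
        for l, locus in enumerate(counts.loci):
            j = t.locus_ids.index(locus)
            pops = []
            for c in t.collections():
                g = t.genotypes[t.collection == c, j, :]
                pops.append(g[g != MISSING].ravel())
            per_locus.append(pops)
        expected = wc_theta_oracle(per_locus)
        assert wc_fst(counts, "global") == pytest.approx(expected, abs=1e-12)

    def test_pairwise_uses_only_the_two_collections(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, n_collections=3, n_per=8, n_loci=3,
                         missing_rate=0.0)
        counts = allele_counts(t)
        pw = wc_fst(counts, "pairwise")
        sub = t.subset(np.isin(t.collection, ["C1", "C3"]))
        expected = wc_fst(allele_counts(sub), "global")
        assert pw.loc["C1", "C3"] == pytest.approx(expected, abs=1e-12)

    def test_theta_monotone_in_generator_drift(self):
        """The estimator tracks the generator's drift parameter."""
        thetas = []
        for f in (0.01, 0.05, 0.1, 0.2, 0.3):
            cfg = ScenarioConfig(n_regions=1, pops_per_region=(4,),
                                 f_region=0.0, f_pop=f, n_loci_msat=20,
                                 inds_per_collection=50, missing_rate=0.0,
                                 seed=97)
            table, _, _ = generate_baseline(cfg)
            thetas.append(wc_fst(allele_counts(table), "global"))
        assert thetas == sorted(thetas)


class TestLd:
    def test_duplicated_locus_r2_one(self):
        rng = np.random.default_rng(1)
        g = rng.integers(1, 3, size=(30, 1, 2))
        t = make_table(np.concatenate([g, g], axis=1), ["A"] * 30)
        assert ld_rsq(t, "L1", "L2") == pytest.approx(1.0)

    def test_independent_loci_r2_small(self):
        rng = np.random.default_rng(2)
        g = rng.integers(1, 3, size=(2000, 2, 2))
        t = make_table(g, ["A"] * 2000)
        assert ld_rsq(t, "L1", "L2") < 0.01

    def test_hand_computed_dosage_correlation(self):
        # dosages of allele 2: (0,1,2,2) and (0,1,1,2)
        genos = [[[1, 1], [1, 1]], [[1, 2], [1, 2]],
                 [[2, 2], [1, 2]], [[2, 2], [2, 2]]]
        t = make_table(genos, ["A"] * 4)
        x, y = np.array([0, 1, 2, 2.]), np.array([0, 1, 1, 2.])
        expected = np.corrcoef(x, y)[0, 1] ** 2
        assert ld_rsq(t, "L1", "L2") == pytest.approx(expected)

    def test_monomorphic_locus_returns_zero_with_warning(self):
        genos = [[[1, 1], [1, 2]], [[1, 1], [2, 2]], [[1, 1], [1, 1]]]
        t = make_table(genos, ["A"] * 3)
        with pytest.warns(UserWarning):
            assert ld_rsq(t, "L1", "L2") == 0.0

    def test_too_few_complete_individuals_raise(self):
        genos = [[[1, 2], [MISSING, MISSING]], [[MISSING, MISSING], [1, 2]],
                 [[1, 1], [1, 2]]]
        t = make_table(genos, ["A"] * 3)
        with pytest.raises(ValueError):
            ld_rsq(t, "L1", "L2")


class TestDistances:
    def test_identical_frequencies_zero_distance(self):
        genos = [[[1, 2]], [[1, 1]]]
        t = make_table(genos + genos, ["A", "A", "B", "B"])
        c = allele_counts(t)
        assert chord_distance(c).get("A", "B") == pytest.approx(0.0)
        assert nei_distance(c).get("A", "B") == pytest.approx(0.0)

    def test_fixed_differences_hit_analytic_chord_maximum(self, two_pop_fixed):
        d = chord_distance(allele_counts(two_pop_fixed))
        assert d.get("A", "B") == pytest.approx(np.sqrt(2.0))

    def test_no_shared_alleles_is_infinite_nei(self, two_pop_fixed):
        with pytest.warns(UserWarning, match="no shared"):
            d = nei_distance(allele_counts(two_pop_fixed))
        assert np.isinf(d.get("A", "B"))

    @pytest.mark.parametrize("seed", range(4))
    def test_match_direct_formula_oracles(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n_collections=2, n_per=10, n_loci=5,
                         missing_rate=0.0)
        c = allele_counts(t)
        f1 = [c.freqs(l)[0] for l in range(5)]
        f2 = [c.freqs(l)[1] for l in range(5)]
        assert chord_distance(c).get("C1", "C2") == pytest.approx(
            chord_distance_oracle(f1, f2), abs=1e-12)
        assert nei_distance(c).get("C1", "C2") == pytest.approx(
            nei_distance_oracle(f1, f2), abs=1e-12)


class TestNeighborJoining:
    def test_recovers_known_four_taxon_tree(self):
        # ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        labels = ["A", "B", "C", "D"]
        D = DistanceMatrix(labels, np.array([
            [0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0.]]))
        tree = neighbor_joining(D)
        assert {frozenset(s) for s in tree.bipartitions()} == {
            frozenset({"A", "B"})}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert tree.leaf_distance(a, b) == pytest.approx(D.values[i, j])

    def test_three_taxa_closed_form(self):
        D = DistanceMatrix(["A", "B", "C"],
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.]]))
        tree = neighbor_joining(D)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                           "C": pytest.approx(3.0)}

    def test_tie_joins_lowest_index_pair(self):
        D = DistanceMatrix(["A", "B", "C", "D"], np.array([
            [0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0.]]))
        tree = neighbor_joining(D)
        # both cherries tie; the (A, B) join must happen first
        first_join = tree.bipartitions()
        assert frozenset({"A", "B"}) in first_join

    @given(st.integers(0, 500))
    def test_additive_matrices_recovered_exactly(self, seed):
        """NJ on an additive matrix reproduces topology and path lengths."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        names, D = random_additive_tree(rng, n)
        tree = neighbor_joining(DistanceMatrix(names, D))
        assert tree.bipartitions() == splits_from_distances(names, D)
        for i in range(n):
            for j in range(i + 1, n):
                assert tree.leaf_distance(names[i], names[j]) == \
                    pytest.approx(D[i, j], abs=1e-9)

    def test_agrees_with_skbio_on_random_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        names, D = random_additive_tree(rng, 6)
        ours = neighbor_joining(DistanceMatrix(names, D))
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids=names))
        for a in names:
            for b in names:
                if a < b:
                    assert ours.leaf_distance(a, b) == pytest.approx(
                        ref.find(a).distance(ref.find(b)), abs=1e-9)

    def test_rejects_fewer_than_three_labels(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.array([[0, 1], [1, 0.]])))


class TestBootstrap:
    @pytest.fixture(scope="class")
    def structured_table(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 3, size=(15, 10, 2))
        b = rng.integers(5, 7, size=(15, 10, 2))
        genos = np.concatenate([a, a, b, b])
        colls = ["A1"] * 15 + ["A2"] * 15 + ["B1"] * 15 + ["B2"] * 15
        return make_table(genos, colls)

    def test_true_split_has_full_support(self, structured_table):
        tree = bootstrap_tree(structured_table, replicates=50, seed=1)
        supports = {frozenset(n.leaf_names()): n.support
                    for n in tree.walk() if not n.is_leaf and n is not tree}
        split = [s for s in supports if s in
                 ({"A1", "A2"}, {"B1", "B2"})]
        assert split and all(supports[s] > 95 for s in split)

    def test_single_replicate_supports_are_zero_or_hundred(self, structured_table):
        tree = bootstrap_tree(structured_table, replicates=1, seed=4)
        sups = [n.support for n in tree.walk()
                if not n.is_leaf and n is not tree]
        assert set(sups) <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self, structured_table):
        t1 = bootstrap_tree(structured_table, replicates=20, seed=9)
        t2 = bootstrap_tree(structured_table, replicates=20, seed=9)
        assert t1.to_newick() == t2.to_newick()

    def test_zero_replicates_rejected(self, structured_table):
        with pytest.raises(ValueError):
            bootstrap_tree(structured_table, replicates=0, seed=1)


class TestPcoa:
    def test_collinear_points_give_one_positive_axis(self):
        D = DistanceMatrix(["a", "b", "c"],
                           np.abs(np.subtract.outer([0, 1, 2], [0, 1, 2])).astype(float))
        o = pcoa(D)
        assert (o.eigenvalues > 1e-9).sum() == 1
        assert o.coordinates.shape[1] == 1

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        o = pcoa(DistanceMatrix([f"p{i}" for i in range(6)], D))
        rec = np.sqrt(((o.coordinates[:, None] - o.coordinates[None]) ** 2).sum(-1))
        assert np.allclose(rec, D, atol=1e-9)

    def test_duplicated_labels_coincide(self):
        D = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 0, 1], [0, 0, 1], [1, 1, 0.]]))
        o = pcoa(D)
        assert np.allclose(o.coordinates[0], o.coordinates[1])

    def test_matches_skbio_eigenvalues(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(5, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ours = pcoa(DistanceMatrix([f"p{i}" for i in range(5)], D))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        assert np.allclose(sorted(ours.eigenvalues[ours.eigenvalues > 1e-9]),
                           sorted(ref.eigvals[ref.eigvals > 1e-9]), atol=1e-6)


class TestFilterSnps:
    def _table(self, maf, miss_frac, n=200):
        g = np.full((n, 1, 2), 1, dtype=np.int64)
        n_minor = int(round(maf * 2 * n))
        g[:n_minor, 0, 0] = 2
        n_miss = int(round(miss_frac * n))
        if n_miss:
            g[-n_miss:, 0, :] = MISSING
        return make_table(np.sort(g, axis=2), ["A"] * n)

    def test_low_maf_locus_dropped(self):
        assert filter_snps(self._table(0.005, 0.0)).n_loci == 0
        assert filter_snps(self._table(0.02, 0.0)).n_loci == 1

    def test_high_missingness_dropped(self):
        assert filter_snps(self._table(0.3, 0.06)).n_loci == 0
        assert filter_snps(self._table(0.3, 0.04)).n_loci == 1

    def test_monomorphic_dropped(self):
        assert filter_snps(self._table(0.0, 0.0)).n_loci == 0
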