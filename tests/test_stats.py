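"""Map statistics: distribution reports, CDFs, Jaccard, clustering,
phenotypic diversity."""

import io
from math import comb

import numpy as np
import pytest

from foldmaps.folding import fold_map
from foldmaps.graphs import build_and_decompose, decompose_graph
from foldmaps.fixtures import caricature_graph
from foldmaps.potentials import AB, HP, BinaryPotential
from foldmaps.stats import (
    cluster_maps,
    compactness_report,
    compositional_report,
    designability_cdf,
    diversity_curve,
    jaccard,
    k_neighborhood_size,
    neutral_set_max_distance,
)


@pytest.fixture(scope="module")
def ab_map(inv8):
    return fold_map(inv8, AB)


class TestCompositionalReport:
    def test_accounting_and_bins(self, ab_map):
        rep = compositional_report(ab_map, replicates=10, seed=3)
        assert rep.observed.sum() == len(ab_map.V)
        assert len(rep.bins) == 9  # L + 1 compositional classes
        assert np.all(rep.expected_sd >= 0)

    def test_null_converges_to_binomial(self, ab_map):
        rep = compositional_report(ab_map, replicates=300, seed=0)
        nu = ab_map.nu
        expect = np.array([nu * comb(8, k) for k in range(9)])
        sem = rep.expected_sd / np.sqrt(rep.replicates)
        assert np.all(np.abs(rep.expected_mean - expect) <= 5 * sem + 0.5)

    def test_needs_replicates(self, ab_map):
        with pytest.raises(ValueError):
            compositional_report(ab_map, replicates=1)


class TestCompactnessReport:
    def test_accounting(self, ab_map, inv8):
        rep = compactness_report(ab_map, inv8, replicates=10, seed=3)
        assert rep.observed.sum() == len(ab_map.X)
        kmax = inv8.n_contacts().max()
        assert len(rep.bins) == kmax + 1

    def test_native_contact_range_matches_unique_sets(self, ab_map, inv8):
        ncont = inv8.n_contacts()
        unique_counts = ncont[inv8.counts == 1]
        observed_bins = np.flatnonzero(
            compactness_report(ab_map, inv8, replicates=2, seed=0).observed
        )
        assert observed_bins.min() >= unique_counts.min()
        assert observed_bins.max() <= unique_counts.max()


class TestDesignabilityCdf:
    def test_starts_at_one_and_decreases(self, ab_map):
        dec = build_and_decompose(ab_map)
        for level in ("neutral_set", "neutral_network"):
            c0, p = designability_cdf(dec, level)
            assert p[0] == 1.0
            assert np.all(np.diff(p) <= 1e-12)

    def test_single_cluster_step_function(self):
        dec = decompose_graph(3, [(0, 1), (1, 2)], {0: 5, 1: 5, 2: 5})
        c0, p = designability_cdf(dec)
        assert list(c0) == [1, 2, 3]
        assert list(p) == [1.0, 1.0, 1.0]

    def test_matches_direct_enumeration_on_worked_example(self):
        n, edges, phen = caricature_graph()
        dec = decompose_graph(n, edges, phen)
        c0, p = designability_cdf(dec, "neutral_set")
        sizes = np.array(sorted(dec.neutral_set_sizes.values()))
        direct = [(sizes[sizes >= c]).sum() / 84 for c in c0]
        assert np.allclose(p, direct)
        assert p[-1] == 23 / 84  # the largest set's mass


class TestJaccard:
    def test_self_similarity_is_one(self, ab_map):
        assert jaccard(ab_map, ab_map, "phenotype") == 1.0
        assert jaccard(ab_map, ab_map, "genotype") == 1.0

    def test_scaling_invariance(self, inv8, ab_map):
        m2 = fold_map(inv8, AB.scaled(2))
        assert jaccard(ab_map, m2, "phenotype") == 1.0

    def test_symmetry(self, inv8, ab_map):
        hp = fold_map(inv8, HP)
        assert jaccard(ab_map, hp, "phenotype") == jaccard(hp, ab_map, "phenotype")

    def test_empty_vs_nonempty_is_zero(self, inv8, ab_map):
        vii = fold_map(inv8, BinaryPotential(1, 1, 1))
        assert jaccard(vii, ab_map, "phenotype") == 0.0

    def test_both_empty_warns_and_returns_one(self, inv8):
        vii = fold_map(inv8, BinaryPotential(1, 1, 1))
        with pytest.warns(RuntimeWarning):
            assert jaccard(vii, vii, "phenotype") == 1.0

    def test_mismatched_lengths_rejected(self, inv8, inv10, ab_map):
        other = fold_map(inv10, AB)
        with pytest.raises(ValueError):
            jaccard(ab_map, other)


class TestClusterMaps:
    def test_identical_maps_merge_at_zero(self):
        s = np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
        dg = cluster_maps(s, "average", labels=["a", "b", "c"])
        assert dg.Z[0, 2] == pytest.approx(0.0)

    def test_three_leaf_upgma_by_hand(self):
        # distances: d(a,b)=0.2, d(a,c)=d(b,c)=0.8 -> merges at 0.2 then 0.8
        s = 1 - np.array([[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]])
        np.fill_diagonal(s, 1.0)
        dg = cluster_maps(s, "average")
        assert dg.merge_heights() == pytest.approx([0.2, 0.8])

    def test_single_vs_complete_differ_on_non_ultrametric_input(self):
        d = np.array(
            [
                [0.0, 0.1, 0.4, 0.9],
                [0.1, 0.0, 0.5, 0.8],
                [0.4, 0.5, 0.0, 0.3],
                [0.9, 0.8, 0.3, 0.0],
            ]
        )
        s = 1 - d
        np.fill_diagonal(s, 1.0)
        hs = cluster_maps(s, "single").merge_heights()
        hc = cluster_maps(s, "complete").merge_heights()
        assert not np.allclose(hs, hc)

    def test_newick_roundtrip(self):
        from Bio import Phylo

        s = 1 - np.array([[0, 0.2, 0.8], [0.2, 0, 0.8], [0.8, 0.8, 0]])
        np.fill_diagonal(s, 1.0)
        dg = cluster_maps(s, "average", labels=["HP", "AB", "(-1.00,+0.25,-0.50)"])
        tree = Phylo.read(io.StringIO(dg.newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(dg.labels)

    def test_rejects_asymmetric_matrix(self):
        s = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError):
            cluster_maps(s)


class TestDiversity:
    def test_k_neighborhood_sizes_closed_form(self):
        assert k_neighborhood_size(18, 1) == 18
        assert k_neighborhood_size(18, 3) == 987
        assert k_neighborhood_size(18, 5) == 12615

    def test_u_bounds_and_pair_count(self, ab_map):
        curve = diversity_curve(ab_map, k=2, n_sequences=30, seed=4)
        ok = ~np.isnan(curve.mean_u)
        assert np.all(curve.mean_u[ok] >= 0) and np.all(curve.mean_u[ok] <= 1)
        assert curve.n_pairs.sum() == 30 * 29 // 2
        assert curve.n_pairs[0] == 0  # sampling without replacement: no d=0

    def test_neighborhoods_disjoint_iff_far(self, ab_map):
        # vertex-disjointness of two k-balls occurs exactly when d > 2k
        k = 2
        v = ab_map.V
        rng = np.random.default_rng(0)
        sample = rng.choice(v, size=12, replace=False)
        for a in sample[:6]:
            for b in sample[6:]:
                d = bin(int(a) ^ int(b)).count("1")
                na = {int(x) for x in v if 1 <= bin(int(x) ^ int(a)).count("1") <= k}
                nb = {int(x) for x in v if 1 <= bin(int(x) ^ int(b)).count("1") <= k}
                if d > 2 * k:
                    assert not (na & nb)

    def test_oversampling_warns(self, ab_map):
        with pytest.warns(RuntimeWarning):
            diversity_curve(ab_map, k=1, n_sequences=10**6, seed=0)


class TestNeutralSetDistances:
    def test_singleton_and_complement(self):
        dec = decompose_graph(3, [], {0: 1, 1: 2, 2: 2})
        # abstract graph: no Hamming metric
        with pytest.raises(ValueError):
            neutral_set_max_distance(dec)

    def test_symmetric_potential_sets_span_sequence_space(self, inv10):
        # e_AA = e_BB: the complement of any viable sequence is viable with
        # the same native structure, so every neutral set has diameter L
        m = fold_map(inv10, BinaryPotential(-0.5, -0.25, -0.5))
        dec = build_and_decompose(m)
        if dec.n_viable == 0:
            pytest.skip("no viable sequences for this potential")
        dmax = neutral_set_max_distance(dec)
        assert all(v == 10 for v in dmax.values())
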