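"""Genotype-graph decomposition: components, neutral sets and networks."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldmaps.fixtures import (
    CARICATURE,
    bfs_decomposition_oracle,
    caricature_graph,
)
from foldmaps.folding import fold_map
from foldmaps.graphs import (
    build_and_decompose,
    cluster_diameter,
    decompose_graph,
    expected_size,
    geodesic_diameter,
    sequence_neutrality,
)
from foldmaps.potentials import AB, BinaryPotential


@pytest.fixture(scope="module")
def ab_decomp(inv8):
    return build_and_decompose(fold_map(inv8, AB))


class TestWorkedExample:
    def test_caricature_statistics(self):
        n, edges, phen = caricature_graph()
        dec = decompose_graph(n, edges, phen)
        assert n == CARICATURE["n_nodes"]
        assert dec.n_viable == CARICATURE["n_viable"] == 84
        assert Fraction(dec.n_viable, n) == Fraction(84, 192)  # nu ~ 0.43
        assert tuple(sorted(dec.component_sizes, reverse=True)) == (53, 24, 7)
        assert sorted(dec.neutral_set_sizes.values()) == sorted(
            CARICATURE["neutral_set_sizes"].values()
        )
        assert len(dec.network_sizes) == 9
        assert expected_size(dec.component_sizes) == pytest.approx(3434 / 84)

    def test_caricature_structure_details(self):
        n, edges, phen = caricature_graph()
        dec = decompose_graph(n, edges, phen)
        # largest component: 4 neutral sets, 5 neutral networks
        big = dec.component_id == 0
        assert len(np.unique(dec.phenotype[big])) == 4
        assert len(np.unique(dec.network_id[big])) == 5
        # the smallest component is a single neutral network (orange)
        small = dec.component_id == 2
        assert len(np.unique(dec.network_id[small])) == 1
        # orange (2) spans all three components; blue (1) the two largest
        assert set(dec.component_id[dec.phenotype == 2]) == {0, 1, 2}
        assert set(dec.component_id[dec.phenotype == 1]) == {0, 1}


class TestDecomposition:
    def test_single_viable_sequence(self):
        dec = decompose_graph(4, [], {2: 7})
        assert dec.n_viable == 1
        assert list(dec.component_sizes) == [1]
        assert dec.neutral_set_sizes == {7: 1}
        assert list(dec.network_sizes) == [1]

    def test_empty_map_is_valid(self, inv8):
        m = fold_map(inv8, BinaryPotential(1, 1, 0.5))  # type VII
        dec = build_and_decompose(m)
        assert dec.n_viable == 0

    def test_matches_bfs_oracle(self, inv8, ab_decomp):
        m = fold_map(inv8, AB)
        comps, sets_, nets = bfs_decomposition_oracle(m.V, m.native_idx[m.V], 8)
        dec = ab_decomp
        got_comps = {
            frozenset(dec.codes[dec.component_id == c].tolist())
            for c in np.unique(dec.component_id)
        }
        assert got_comps == set(comps)
        got_sets = {ph: frozenset(v.tolist()) for ph, v in dec.neutral_sets.items()}
        assert got_sets == sets_
        got_nets = {
            frozenset(dec.codes[dec.network_id == i].tolist())
            for i in np.unique(dec.network_id)
        }
        assert got_nets == {c for _, c in nets}

    def test_partition_accounting(self, ab_decomp):
        dec = ab_decomp
        assert dec.component_sizes.sum() == dec.n_viable
        assert sum(dec.neutral_set_sizes.values()) == dec.n_viable
        assert dec.network_sizes.sum() == dec.n_viable

    def test_deterministic_labels(self, inv8):
        m = fold_map(inv8, AB)
        d1, d2 = build_and_decompose(m), build_and_decompose(m)
        assert np.array_equal(d1.component_id, d2.component_id)
        assert np.array_equal(d1.network_id, d2.network_id)
        # ids ordered by decreasing size
        assert list(d1.component_sizes) == sorted(d1.component_sizes, reverse=True)


class TestNeutrality:
    def test_matches_direct_recount(self, ab_decomp):
        dec = ab_decomp
        pos = {int(c): i for i, c in enumerate(dec.codes)}
        for s in dec.codes[:40]:
            same = sum(
                1
                for b in range(8)
                if int(s) ^ (1 << b) in pos
                and dec.network_id[pos[int(s) ^ (1 << b)]] == dec.network_id[pos[int(s)]]
            )
            assert sequence_neutrality(dec, int(s)) == same / 8

    def test_isolated_sequence_has_zero_neutrality(self, ab_decomp):
        sizes = ab_decomp.network_sizes
        singles = np.flatnonzero(sizes == 1)
        if len(singles) == 0:
            pytest.skip("no singleton network in this map")
        s = int(ab_decomp.codes[ab_decomp.network_id == singles[0]][0])
        assert sequence_neutrality(ab_decomp, s) == 0.0

    def test_nonviable_rejected(self, ab_decomp):
        viable = set(ab_decomp.codes.tolist())
        s = next(x for x in range(256) if x not in viable)
        with pytest.raises(ValueError):
            sequence_neutrality(ab_decomp, s)


class TestExpectedSize:
    def test_worked_numbers(self):
        assert expected_size([53, 24, 7]) == pytest.approx(3434 / 84)

    def test_single_cluster(self):
        assert expected_size([17]) == 17

    def test_equal_clusters(self):
        assert expected_size([5, 5, 5]) == 5

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(1, 1000), min_size=1, max_size=20))
    def test_at_least_arithmetic_mean(self, sizes):
        assert expected_size(sizes) >= np.mean(sizes) - 1e-12
        if len(set(sizes)) == 1:
            assert expected_size(sizes) == pytest.approx(sizes[0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            expected_size([])


class TestDiameters:
    def test_singleton_diameter_zero(self):
        assert cluster_diameter([13]) == 0

    def test_complement_pair_spans_space(self):
        s = 0b0110101
        assert cluster_diameter([s, s ^ 0b1111111]) == 7

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(5)
        seqs = rng.choice(1 << 12, size=20, replace=False)
        brute = max(
            bin(int(a) ^ int(b)).count("1") for a in seqs for b in seqs
        )
        assert cluster_diameter(seqs) == brute

    def test_geodesic_diameter_on_path(self):
        dec = decompose_graph(5, [(0, 1), (1, 2), (2, 3)], {0: 1, 1: 1, 2: 1, 3: 1})
        assert geodesic_diameter(dec) == 3
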