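"""Potential classification, decomposition, and the grid sample."""

from collections import Counter
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from foldmaps.potentials import (
    AB,
    DEFAULT_GRID,
    HP,
    BinaryPotential,
    PotentialType,
    classify_type,
    decompose,
    grid_sample,
    map_equivalence_check,
    natural_binary_potentials,
    redundant_grid_pairs,
)

finite_energy = st.floats(-3, 3, allow_nan=False, allow_infinity=False)


class TestClassify:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((-1, 0, 0), "VI"),  # HP: only homomonomeric attraction
            ((-1, 1, -1), "II"),  # AB: attractive homo, repulsive hetero
            ((0.25, 0.25, 0.25), "VII"),
            ((-1, -0.5, -0.25), "III"),
            ((-1, 1, 0.5), "I"),
            ((0.5, -1, -1), "IV"),
            ((0.25, -0.75, 1), "V"),
        ],
    )
    def test_examples(self, triple, expected):
        assert classify_type(BinaryPotential(*triple)).value == expected

    def test_octant_ratio(self):
        # one representative per strict-sign octant: types in 2:1:1:2:1:1
        octants = Counter(
            classify_type(BinaryPotential(*(s * 0.5 for s in signs))).value
            for signs in product((-1, 1), repeat=3)
        )
        assert octants == {"I": 2, "II": 1, "III": 1, "IV": 2, "V": 1, "VII": 1}

    @settings(deadline=None, max_examples=100)
    @given(finite_energy, finite_energy, finite_energy, st.floats(0.1, 5))
    def test_invariant_under_scaling_and_swap(self, a, h, b, c):
        p = BinaryPotential(a, h, b)
        assert classify_type(p) == classify_type(p.scaled(c))
        assert classify_type(p) == classify_type(p.swapped())

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            BinaryPotential(float("nan"), 0, 0)


class TestDecompose:
    def test_ab_model(self):
        d = decompose(AB)
        assert (d.e_ideal, d.e_xs, d.additivity) == (-1.0, 2.0, -1.0)

    def test_hp_model(self):
        d = decompose(HP)
        assert (d.e_ideal, d.e_xs, d.additivity) == (-0.5, 0.5, 0.0)

    def test_undefined_additivity_flagged(self):
        d = decompose(BinaryPotential(-1, 0.5, 1))
        assert not d.additivity_defined and np.isnan(d.additivity)

    @settings(deadline=None, max_examples=100)
    @given(finite_energy, finite_energy)
    def test_additive_family(self, a, b):
        d = decompose(BinaryPotential(a, (a + b) / 2, b))
        assert d.e_xs == 0
        if d.additivity_defined:
            assert d.additivity == 1.0

    @pytest.mark.parametrize("triple", list(product(DEFAULT_GRID[:3], repeat=3)))
    def test_exact_on_grid(self, triple):
        p = BinaryPotential(*triple)
        d = decompose(p)
        assert d.e_ideal + d.e_xs == p.e_AB


class TestGridSample:
    def test_default_grid_yields_245(self):
        assert len(grid_sample()) == 245

    def test_rejects_duplicate_grid(self):
        with pytest.raises(ValueError):
            grid_sample((-1.0, 0.0, 0.0, 1.0))

    def test_no_all_nonnegative_triple(self):
        assert all(min(p.as_tuple()) < 0 for p in grid_sample())

    def test_no_uniform_triple(self):
        assert all(len(set(p.as_tuple())) > 1 for p in grid_sample())

    def test_swap_duplicates_absent(self):
        seen = {p.as_tuple() for p in grid_sample()}
        for a, h, b in seen:
            if a != b:
                assert (b, h, a) not in seen

    def test_scaling_duplicates_absent(self):
        seen = {p.as_tuple() for p in grid_sample()}
        for a, h, b in seen:
            assert (a / 2, h / 2, b / 2) not in seen or (a, h, b) == (a / 2, h / 2, b / 2)

    def test_deterministic_order(self):
        assert [p.label for p in grid_sample()] == [p.label for p in grid_sample()]

    def test_contains_canonical_models(self):
        seen = {p.as_tuple() for p in grid_sample()}
        assert AB.as_tuple() in seen
        assert HP.as_tuple() in seen

    def test_retained_redundant_pairs_are_the_two_self_mirrored_families(self):
        pairs = {frozenset((p.as_tuple(), q.as_tuple())) for p, q in redundant_grid_pairs()}
        assert pairs == {
            frozenset({(-1.0, 0.0, -1.0), (0.0, -1.0, 0.0)}),
            frozenset({(-1.0, 1.0, -1.0), (1.0, -1.0, 1.0)}),
        }


class TestMapEquivalence:
    def test_positive_scaling_is_equivalent(self, inv10):
        assert map_equivalence_check(HP, HP.scaled(0.5), 10, inv10)

    def test_swap_with_complement_is_equivalent(self, inv10):
        p = BinaryPotential(-1, 0.5, 0.25)
        assert map_equivalence_check(p, p.swapped(), 10, inv10)

    def test_hp_and_ab_differ(self, inv10):
        assert not map_equivalence_check(HP, AB, 10, inv10)

    def test_homo_hetero_exchange_is_equivalent(self, inv10):
        # a merge grid_sample actually performs
        p = BinaryPotential(-0.5, 0.25, -0.5)
        q = BinaryPotential(0.25, -0.5, 0.25)
        assert map_equivalence_check(p, q, 10, inv10)

    def test_retained_redundant_pairs_are_nevertheless_equivalent(self, inv10):
        for p, q in redundant_grid_pairs():
            assert map_equivalence_check(p, q, 10, inv10)


class TestNaturalAlphabet:
    def test_yields_190_pairs(self):
        m = -np.ones((20, 20))
        pots, hist = natural_binary_potentials(m)
        assert len(pots) == 190
        assert hist == {PotentialType.III: 190}

    def test_rejects_asymmetric_table(self):
        m = np.zeros((20, 20))
        m[0, 1] = 1.0
        with pytest.raises(ValueError):
            natural_binary_potentials(m)

    def test_bundled_synthetic_table(self):
        from foldmaps.fixtures import load_contact_table

        names, m = load_contact_table()
        assert len(names) == 20 and m.shape == (20, 20)
        assert np.array_equal(m, m.T)
        pots, hist = natural_binary_potentials(m, names)
        assert len(pots) == 190
        assert sum(hist.values()) == 190
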