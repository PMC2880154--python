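"""Mendelian bookkeeping, sex-limited trait expression, birth rates."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sisevol.genetics import (Allele, DegeneratePopulationError, FEMALE_LOCUS,
                              Genotype, GenotypeSpace, MALE_LOCUS,
                              PhenotypeTable, birth_rates, genotype_trait,
                              mendelian_offspring, offspring_tensor)
from sisevol.params import ParameterSet

allele_values = st.floats(min_value=0.02, max_value=0.98,
                          allow_nan=False, allow_infinity=False)


def brute_force_cross(mother: Genotype, father: Genotype,
                      space: GenotypeSpace) -> np.ndarray:
    """Independent oracle: enumerate all 2^4 equally likely gamete pairings."""
    probs = np.zeros(space.n)
    for mf, mm, ff, fm in itertools.product(mother.female_pair, mother.male_pair,
                                            father.female_pair, father.male_pair):
        g = Genotype((mf, ff), (mm, fm))
        probs[space.index_of(g)] += 1.0 / 16.0
    return probs


class TestTraitExpression:
    @pytest.mark.parametrize("female_pair,male_pair,sex,expected", [
        ((0.3, 0.3), (0.5, 0.5), "female", 0.3),   # homozygote identity
        ((0.2, 0.6), (0.5, 0.5), "female", 0.4),   # heterozygote = mean
        ((0.1, 0.9), (0.5, 0.5), "male", 0.5),     # sex-limited expression
        ((0.1, 0.9), (0.2, 0.8), "female", 0.5),
    ])
    def test_sex_limited_additive_expression(self, female_pair, male_pair,
                                             sex, expected):
        g = Genotype(female_pair, male_pair)
        assert genotype_trait(g, sex) == pytest.approx(expected, abs=1e-15)

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            genotype_trait(Genotype((0.3, 0.3), (0.5, 0.5)), "other")

    def test_allele_validation(self):
        with pytest.raises(ValueError):
            Allele(locus=FEMALE_LOCUS, value=1.0)
        with pytest.raises(ValueError):
            Allele(locus=2, value=0.5)


class TestGenotypeSpace:
    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 1), (2, 2), (3, 2)])
    def test_size_and_bijection(self, n1, n2):
        f_alleles = np.linspace(0.2, 0.8, n1)
        m_alleles = np.linspace(0.3, 0.7, n2)
        space = GenotypeSpace(f_alleles, m_alleles)
        expected = n1 * (n1 + 1) // 2 * (n2 * (n2 + 1) // 2)
        assert space.n == expected
        assert len({space.index_of(g) for g in space.genotypes}) == space.n

    def test_foreign_genotype_rejected(self):
        space = GenotypeSpace([0.2], [0.5])
        with pytest.raises(ValueError):
            space.index_of(Genotype((0.3, 0.3), (0.5, 0.5)))


class TestMendelianOffspring:
    def test_heterozygote_cross_quarters(self):
        """AB x AB at one locus segregates 1/4 : 1/2 : 1/4."""
        space = GenotypeSpace([0.2, 0.6], [0.5])
        het = Genotype((0.2, 0.6), (0.5, 0.5))
        dist = mendelian_offspring(het, het, space)
        assert dist[Genotype((0.2, 0.2), (0.5, 0.5))] == pytest.approx(0.25)
        assert dist[Genotype((0.2, 0.6), (0.5, 0.5))] == pytest.approx(0.5)
        assert dist[Genotype((0.6, 0.6), (0.5, 0.5))] == pytest.approx(0.25)

    def test_monomorphic_cross_breeds_true(self):
        space = GenotypeSpace([0.3], [0.5])
        g = Genotype((0.3, 0.3), (0.5, 0.5))
        dist = mendelian_offspring(g, g, space)
        assert dist[g] == 1.0

    def test_forced_hybrids(self):
        """AA x BB (and CC x DD at locus 2) yields only double heterozygotes."""
        space = GenotypeSpace([0.2, 0.8], [0.3, 0.7])
        mother = Genotype((0.2, 0.2), (0.3, 0.3))
        father = Genotype((0.8, 0.8), (0.7, 0.7))
        dist = mendelian_offspring(mother, father, space)
        assert dist[Genotype((0.2, 0.8), (0.3, 0.7))] == 1.0

    def test_double_heterozygote_cross_matches_brute_force(self):
        """Free recombination: 9 classes = product of single-locus ratios."""
        space = GenotypeSpace([0.2, 0.6], [0.3, 0.7])
        g = Genotype((0.2, 0.6), (0.3, 0.7))
        dist = mendelian_offspring(g, g, space)
        assert np.count_nonzero(dist.proportions) == 9
        np.testing.assert_allclose(dist.proportions,
                                   brute_force_cross(g, g, space), atol=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(vals=st.lists(allele_values, min_size=4, max_size=4,
                         unique_by=lambda v: round(v, 6)))
    def test_random_cross_properties(self, vals):
        """Proportions sum to 1, match gamete enumeration, and are
        symmetric under exchanging the parents."""
        a, b, c, d = sorted(vals)
        space = GenotypeSpace([a, b], [c, d])
        mother = Genotype((a, b), (c, c))
        father = Genotype((a, a), (c, d))
        dist = mendelian_offspring(mother, father, space)
        assert dist.proportions.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(dist.proportions,
                                   brute_force_cross(mother, father, space),
                                   atol=1e-12)
        flipped = mendelian_offspring(father, mother, space)
        np.testing.assert_allclose(dist.proportions, flipped.proportions,
                                   atol=1e-12)

    def test_offspring_tensor_rows_sum_to_one(self):
        space = GenotypeSpace([0.2, 0.6], [0.4])
        delta = offspring_tensor(space)
        np.testing.assert_allclose(delta.sum(axis=0), 1.0, atol=1e-12)


def _mono_table(n: int = 1) -> PhenotypeTable:
    ones = np.ones(n)
    return PhenotypeTable(d_f=0.25 * ones, gamma_f=2.0 * ones, phi_f=ones,
                          d_m=0.25 * ones, gamma_m=2.0 * ones, phi_m=ones)


class TestBirthRates:
    def test_monomorphic_total(self):
        """Single genotype below carrying density: B = b(1-qN) S_f."""
        params = ParameterSet()
        space = GenotypeSpace([0.5], [0.5])
        state = np.array([[20.0, 0.0, 15.0, 0.0]])
        B = birth_rates(state, params, _mono_table(), offspring_tensor(space))
        assert B[0] == pytest.approx(1.0 * (1 - 0.01 * 35.0) * 20.0)

    def test_zero_when_all_females_infected_and_sterile(self):
        params = ParameterSet()
        table = _mono_table()
        table.phi_f = np.zeros(1)
        state = np.array([[0.0, 10.0, 5.0, 0.0]])
        B = birth_rates(state, params, table, np.ones((1, 1, 1)))
        assert B[0] == 0.0

    def test_zero_at_carrying_density(self):
        params = ParameterSet()
        state = np.array([[60.0, 0.0, 60.0, 0.0]])  # N = 120 > 1/q = 100
        B = birth_rates(state, params, _mono_table(), np.ones((1, 1, 1)))
        assert B[0] == 0.0

    def test_no_males_signals_degenerate(self):
        params = ParameterSet()
        state = np.array([[10.0, 0.0, 0.0, 0.0]])
        with pytest.raises(DegeneratePopulationError):
            birth_rates(state, params, _mono_table(), np.ones((1, 1, 1)))

    def test_two_fathers_equal_weights_split_cross(self):
        """One female genotype, two male genotypes with equal weight:
        offspring are the Mendelian crosses averaged equally over fathers."""
        params = ParameterSet()
        space = GenotypeSpace([0.5], [0.3, 0.7])
        table = _mono_table(space.n)
        delta = offspring_tensor(space)
        g_mm = space.index_of(Genotype((0.5, 0.5), (0.3, 0.3)))
        g_het = space.index_of(Genotype((0.5, 0.5), (0.3, 0.7)))
        g_MM = space.index_of(Genotype((0.5, 0.5), (0.7, 0.7)))
        state = np.zeros((space.n, 4))
        state[g_mm] = [12.0, 0.0, 4.0, 0.0]   # mothers all (0.3,0.3) at locus 2
        state[g_MM, 2] = 4.0                  # equal-weight (0.7,0.7) fathers
        B = birth_rates(state, params, table, delta)
        total = 1.0 * (1 - 0.01 * 20.0) * 12.0
        # father (0.3,0.3) -> all offspring (0.3,0.3); father (0.7,0.7) -> all het
        assert B[g_mm] == pytest.approx(total / 2)
        assert B[g_het] == pytest.approx(total / 2)
        assert B[g_MM] == pytest.approx(0.0)

    def test_total_births_independent_of_male_composition(self, rng):
        """Bateman's principle: male frequencies shape offspring genotypes
        but never the total birth rate."""
        params = ParameterSet()
        space = GenotypeSpace([0.5], [0.3, 0.7])
        table = _mono_table(space.n)
        delta = offspring_tensor(space)
        totals = []
        for _ in range(5):
            state = np.zeros((space.n, 4))
            state[0, 0] = 10.0  # monomorphic females
            state[:, 2] = rng.uniform(0.5, 5.0, space.n)
            N = state.sum()
            totals.append(birth_rates(state, params, table, delta).sum()
                          / (1 - 0.01 * N))
        np.testing.assert_allclose(totals, 10.0, rtol=1e-12)

    def test_births_non_negative(self, rng):
        params = ParameterSet()
        space = GenotypeSpace([0.2, 0.8], [0.5])
        table = _mono_table(space.n)
        delta = offspring_tensor(space)
        state = rng.uniform(0.0, 10.0, (space.n, 4))
        B = birth_rates(state, params, table, delta)
        assert np.all(B >= 0.0)
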