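"""The genotype-phenotype map, Gaussian fitness, mutation and recombination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pleiosim import Genotype, ModelParams, compute_phenotype, fitness, mutate, recombine
from pleiosim.core_model import fitness_array, phenotypes


class TestPhenotype:
    @pytest.mark.parametrize(
        "a, c, expected",
        [
            # identity contribution matrix passes the weights through
            ([0.5, -1, 2, 0], np.eye(4), [0.5, -1, 2, 0]),
            # all-zero contributions annihilate any weights
            ([3.0, -7.0, 1.0, 9.0], np.zeros((4, 4)), [0, 0, 0, 0]),
            # hand-computed 2x2 matrix-vector product
            ([1, 2], [[1, 0.5], [-1, 1]], [2, 1]),
        ],
    )
    def test_linear_readout(self, a, c, expected):
        z = compute_phenotype(Genotype(np.array(a, float), np.array(c, float)))
        np.testing.assert_allclose(z.z, expected)

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            Genotype(np.zeros(3), np.zeros((4, 4)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            Genotype(np.array([np.nan, 0.0]), np.zeros((2, 2)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linearity_in_weights(self, seed):
        r = np.random.default_rng(seed)
        c = r.normal(size=(3, 5))
        a1, a2 = r.normal(size=5), r.normal(size=5)
        z1 = compute_phenotype(Genotype(a1, c)).z
        z2 = compute_phenotype(Genotype(a2, c)).z
        z12 = compute_phenotype(Genotype(a1 + a2, c)).z
        np.testing.assert_allclose(z12, z1 + z2, atol=1e-12)

    def test_vectorised_map_matches_per_individual(self, rng):
        a = rng.normal(size=(7, 4))
        c = rng.normal(size=(7, 3, 4))
        z = phenotypes(a, c)
        for k in range(7):
            np.testing.assert_allclose(
                z[k], compute_phenotype(Genotype(a[k], c[k])).z
            )


class TestFitness:
    def test_at_optimum_is_one(self):
        z = np.array([0.3, -0.2, 1.0, 0.0])
        assert fitness(z, z) == 1.0

    @pytest.mark.parametrize(
        "deviation, expected",
        [
            ((1, 0, 0, 0), np.exp(-0.5)),
            ((1, 1, 1, 1), np.exp(-2.0)),
        ],
    )
    def test_closed_form(self, deviation, expected):
        opt = np.zeros(4)
        assert fitness(np.array(deviation, float), opt) == pytest.approx(expected, rel=1e-12)

    def test_bounded_and_monotone_in_deviation(self, rng):
        opt = rng.normal(size=4)
        devs = np.linspace(0, 3, 10)
        w = [fitness(opt + np.array([d, 0, 0, 0]), opt) for d in devs]
        assert all(0 < x <= 1 for x in w)
        assert np.all(np.diff(w) < 0)

    def test_multiplicative_across_traits(self, rng):
        opt = np.zeros(2)
        z = np.array([0.7, -0.4])
        w_joint = fitness(z, opt)
        w_split = fitness(z[:1], opt[:1]) * fitness(z[1:], opt[1:])
        assert w_joint == pytest.approx(w_split, rel=1e-12)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            fitness(np.zeros(3), np.zeros(4))

    def test_array_form_matches_scalar(self, rng):
        z = rng.normal(size=(6, 4))
        opt = rng.normal(size=4)
        w = fitness_array(z, opt)
        for k in range(6):
            assert w[k] == pytest.approx(fitness(z[k], opt))


class TestMutation:
    def test_zero_rates_leave_genotype_unchanged(self, rng):
        g = Genotype(rng.normal(size=4), rng.normal(size=(4, 4)))
        p = ModelParams(N=10, mu_a=0.0, mu_c=0.0)
        child = mutate(g, p, rng)
        np.testing.assert_array_equal(child.a, g.a)
        np.testing.assert_array_equal(child.c, g.c)

    def test_input_not_modified(self, rng):
        g = Genotype(np.zeros(4), np.zeros((4, 4)))
        before = g.a.copy(), g.c.copy()
        mutate(g, ModelParams(N=10, mu_a=1.0, mu_c=1.0), rng)
        np.testing.assert_array_equal(g.a, before[0])
        np.testing.assert_array_equal(g.c, before[1])

    def test_effect_distribution_variance(self, rng):
        # with mu_a = 1 every draw mutates; effect variance should be mut_var
        g = Genotype(np.zeros(1), np.zeros((1, 1)))
        p = ModelParams(N=10, n_traits=1, n_a=1, mu_a=1.0, mu_c=0.0, mut_var=0.5)
        n = 100_000
        deltas = np.array([mutate(g, p, rng).a[0] for _ in range(n)])
        # MC standard error of a sample variance of a normal: var * sqrt(2/n)
        se = 0.5 * np.sqrt(2 / n)
        assert abs(deltas.var() - 0.5) < 3 * se
        assert abs(deltas.mean()) < 3 * np.sqrt(0.5 / n)

    def test_expected_mutation_supply_at_defaults(self, rng):
        # defaults: n_a * mu_a * N = 5 expected weight-gene mutations per generation
        p = ModelParams()
        assert p.n_a * p.mu_a * p.N == pytest.approx(5.0)
        assert p.n_traits * p.n_a * p.mu_c * p.N == pytest.approx(5.0)
        g = Genotype(np.zeros(4), np.zeros((4, 4)))
        reps = 20
        count = 0
        for _ in range(reps * p.N):  # reps generations of N births
            child = mutate(g, p, rng)
            count += int(np.sum(child.a != 0.0))
        mean_per_gen = count / reps
        # Binomial(reps*N*n_a, mu_a): 3-sigma window around 5 per generation
        sigma = np.sqrt(reps * p.N * p.n_a * p.mu_a * (1 - p.mu_a)) / reps
        assert abs(mean_per_gen - 5.0) < 3 * sigma


class TestRecombination:
    def test_identical_parents_reproduce_exactly(self, rng):
        g = Genotype(rng.normal(size=4), rng.normal(size=(4, 4)))
        child = recombine(g, g.copy(), rng)
        np.testing.assert_array_equal(child.a, g.a)
        np.testing.assert_array_equal(child.c, g.c)

    def test_inheritance_closure(self, rng):
        p1 = Genotype(rng.normal(size=4), rng.normal(size=(3, 4)))
        p2 = Genotype(rng.normal(size=4), rng.normal(size=(3, 4)))
        child = recombine(p1, p2, rng)
        assert np.all((child.a == p1.a) | (child.a == p2.a))
        assert np.all((child.c == p1.c) | (child.c == p2.c))
        assert child.a.shape == p1.a.shape and child.c.shape == p1.c.shape

    def test_each_gene_is_a_fair_coin(self, rng):
        p1 = Genotype(np.zeros(4), np.zeros((4, 4)))
        p2 = Genotype(np.ones(4), np.ones((4, 4)))
        n = 5_000
        ones = 0.0
        for _ in range(n):
            child = recombine(p1, p2, rng)
            ones += child.a.sum() + child.c.sum()
        total = n * (4 + 16)
        frac = ones / total
        se = 0.5 / np.sqrt(total)
        assert abs(frac - 0.5) < 3 * se

    def test_dimension_mismatch_is_an_error(self, rng):
        p1 = Genotype(np.zeros(4), np.zeros((4, 4)))
        p2 = Genotype(np.zeros(3), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            recombine(p1, p2, rng)


class TestModelParams:
    @pytest.mark.parametrize(
        "kw",
        [dict(N=1), dict(mu_a=1.5), dict(mu_c=-0.1), dict(mut_var=0.0), dict(n_traits=0)],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)

    def test_genome_size(self):
        assert ModelParams().n_genes == 20
        assert ModelParams(n_traits=8, n_a=8).n_genes == 72
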