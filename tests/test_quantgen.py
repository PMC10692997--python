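"""(Co)variance estimation: total matrix, shuffle decomposition, midparent
regression, time-averaging and treatment comparison."""

import numpy as np
import pytest

from pleiosim import (
    EnvironmentSpec,
    ModelParams,
    additive_vcv,
    compare_treatments,
    make_fixture,
    run_replicate,
    shuffle_decompose,
    summarize_replicate,
    total_vcv,
)
from pleiosim.moran import Population
from pleiosim.quantgen import diag_mean, offdiag_mean


class TestTotalVCV:
    def test_uniform_population_has_zero_matrix(self, rng, small_params):
        pop = make_fixture("uniform", small_params, rng)
        np.testing.assert_allclose(total_vcv(pop).matrix, 0.0, atol=1e-14)

    def test_two_phenotype_hand_computation(self):
        # equally frequent phenotypes (0,0) and (2,2): variance 1, covariance 1
        a = np.array([[0.0, 0.0], [2.0, 2.0]] * 5)
        c = np.tile(np.eye(2), (10, 1, 1))
        m = total_vcv((a, c)).matrix
        np.testing.assert_allclose(m, [[1.0, 1.0], [1.0, 1.0]])

    def test_translation_invariance(self, rng):
        a = rng.normal(size=(30, 3))
        c = rng.normal(size=(30, 2, 3))
        m1 = total_vcv((a, c)).matrix
        # shift every phenotype by a constant via an extra uniform weight effect
        shift = rng.normal(size=2)
        a2 = np.hstack([a, np.ones((30, 1))])
        c2 = np.concatenate([c, np.tile(shift[:, None], (30, 1, 1))], axis=2)
        m2 = total_vcv((a2, c2)).matrix
        np.testing.assert_allclose(m1, m2, atol=1e-12)

    def test_single_individual_is_an_error(self, rng):
        with pytest.raises(ValueError):
            total_vcv((np.zeros((1, 2)), np.zeros((1, 2, 2))))

    def test_symmetric_and_psd(self, rng):
        a = rng.normal(size=(50, 4))
        c = rng.normal(size=(50, 4, 4))
        m = total_vcv((a, c)).matrix
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert np.linalg.eigvalsh(m).min() > -1e-10


class TestShuffleDecompose:
    def test_pleiotropy_plus_ld_equals_total_exactly(self, rng, small_params):
        pop = make_fixture("no_ld", small_params.with_(N=40), rng)
        total = total_vcv(pop).matrix
        pleio, ld = shuffle_decompose(pop, n_shuffles=3, rng=rng)
        np.testing.assert_allclose(pleio.matrix + ld.matrix, total, atol=1e-12)

    def test_no_ld_fixture_has_near_zero_ld_component(self, rng):
        p = ModelParams(N=500)
        pop = make_fixture("no_ld", p, rng)
        _, ld = shuffle_decompose(pop, n_shuffles=20, rng=rng)
        # independently drawn loci: LD component is pure sampling noise
        scale = np.abs(total_vcv(pop).matrix).max()
        assert np.abs(ld.matrix).max() < 0.2 * scale

    def test_perfect_coupling_covariance_is_pure_ld(self, rng):
        # identity c, a1 == a2 in {0,1} half-half: covariance 0.25, all LD
        p = ModelParams(N=400, n_traits=2, n_a=2)
        pop = make_fixture("perfect_coupling", p, rng)
        total = total_vcv(pop).matrix
        assert total[0, 1] == pytest.approx(0.25)
        pleio, ld = shuffle_decompose(pop, n_shuffles=50, rng=rng)
        # post-shuffle covariance has MC standard error ~ sqrt(Var1*Var2/N)/sqrt(S)
        se = 0.25 / np.sqrt(400) / np.sqrt(50)
        assert abs(pleio.matrix[0, 1]) < 4 * se
        assert ld.matrix[0, 1] == pytest.approx(0.25, abs=4 * se)

    def test_shuffle_preserves_allele_multisets(self, rng, small_params):
        # the permutation contract: shuffling must not change any locus's alleles
        pop = make_fixture("no_ld", small_params.with_(N=30), rng)
        a, c = pop.a.copy(), pop.c.copy()
        shuffle_decompose(pop, n_shuffles=2, rng=rng)
        np.testing.assert_array_equal(pop.a, a)  # input untouched
        np.testing.assert_array_equal(pop.c, c)

    def test_needs_at_least_one_shuffle(self, rng, small_params):
        pop = make_fixture("uniform", small_params, rng)
        with pytest.raises(ValueError):
            shuffle_decompose(pop, n_shuffles=0, rng=rng)


class TestAdditiveVCV:
    def test_fixed_c_map_is_fully_additive(self, rng):
        # shared c, variable a: offspring expectation = midparent, so h2 -> 1
        # and the additive matrix approaches the total matrix
        p = ModelParams(N=600, sexual=True)
        pop = make_fixture("fixed_c", p, rng)
        add, raw, h2 = additive_vcv(pop, n_pairs=4000, n_offspring_per_pair=20, rng=rng)
        total = total_vcv(pop).matrix
        np.testing.assert_allclose(h2, 1.0, atol=0.1)
        np.testing.assert_allclose(add.matrix, total, rtol=0.15, atol=0.02)

    def test_uniform_population_reports_missing_not_zero(self, rng, small_params):
        pop = make_fixture("uniform", small_params, rng)
        add, raw, h2 = additive_vcv(pop, n_pairs=100, rng=rng)
        assert np.all(np.isnan(add.matrix))
        assert np.all(np.isnan(h2))

    def test_raw_matrix_may_be_asymmetric_but_symmetrized_is_not(self, rng):
        p = ModelParams(N=200, sexual=True)
        pop = make_fixture("no_ld", p, rng)
        add, raw, _ = additive_vcv(pop, n_pairs=500, rng=rng)
        np.testing.assert_allclose(add.matrix, add.matrix.T, atol=1e-12)
        np.testing.assert_allclose(add.matrix, 0.5 * (raw + raw.T), atol=1e-12)


class TestSummarize:
    def _record(self, rng, n_snap=3):
        p = ModelParams(N=30)
        spec = EnvironmentSpec(pattern="correlated")
        gens = [10 * (k + 1) for k in range(n_snap)]
        return run_replicate(p, spec, 30 * gens[-1], seed=8, snapshot_gens=gens)

    def test_single_snapshot_equals_direct_estimates(self, rng):
        rec = self._record(rng, n_snap=1)
        s = summarize_replicate(rec, rng=np.random.default_rng(1))
        direct = total_vcv((rec.snapshot_a[0], rec.snapshot_c[0])).matrix
        np.testing.assert_allclose(s.matrix("total"), direct, atol=1e-12)

    def test_averaging_preserves_decomposition_identity(self, rng):
        rec = self._record(rng, n_snap=4)
        s = summarize_replicate(rec, rng=np.random.default_rng(2))
        np.testing.assert_allclose(
            s.matrix("pleiotropy") + s.matrix("LD"), s.matrix("total"), atol=1e-12
        )

    def test_tidy_frame_schema(self, rng):
        rec = self._record(rng, n_snap=2)
        df = summarize_replicate(rec, rng=np.random.default_rng(3)).to_frame()
        assert set(df.columns) == {"replicate", "label", "trait_i", "trait_j", "value"}
        assert set(df["label"]) == {"total", "pleiotropy", "LD"}


class TestCompareTreatments:
    def _summaries(self, values, label="total"):
        from pleiosim.quantgen import ReplicateSummary, VCVMatrix

        out = []
        for k, v in enumerate(values):
            m = np.full((2, 2), float(v))
            out.append(ReplicateSummary(k, {label: VCVMatrix(m, label)}))
        return out

    def test_identical_groups_ratio_one_p_one(self):
        g = self._summaries([1.0, 1.1, 0.9, 1.05])
        res = compare_treatments(g, g, "total", "offdiag_mean")
        assert res["ratio"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_separated_groups_reject_strongly(self, rng):
        a = self._summaries(rng.normal(1.0, 0.01, 50))
        b = self._summaries(rng.normal(0.0, 0.01, 50))
        res = compare_treatments(a, b, "total", "offdiag_mean")
        assert res["p"] < 1e-6

    def test_t_statistic_antisymmetric_under_swap(self, rng):
        a = self._summaries(rng.normal(1.0, 0.5, 10))
        b = self._summaries(rng.normal(0.5, 0.5, 10))
        r1 = compare_treatments(a, b, "total", "diag_mean")
        r2 = compare_treatments(b, a, "total", "diag_mean")
        assert r1["t"] == pytest.approx(-r2["t"])

    def test_degenerate_groups_report_failure(self):
        a = self._summaries([1.0, 1.0, 1.0])
        b = self._summaries([2.0, 2.0, 2.0])
        res = compare_treatments(a, b, "total", "offdiag_mean")
        assert res["error"] is not None
        assert np.isnan(res["p"])

    def test_entry_selector(self, rng):
        a = self._summaries(rng.normal(1.0, 0.1, 5))
        b = self._summaries(rng.normal(1.0, 0.1, 5))
        res = compare_treatments(a, b, "total", (0, 1))
        assert np.isfinite(res["t"])

    def test_selectors(self):
        m = np.array([[1.0, 3.0], [5.0, 2.0]])
        assert diag_mean(m) == 1.5
        assert offdiag_mean(m) == 4.0
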