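import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pseudonet import (CountTable, SparCC, SparccConfig, estimate_fractions,
                       logratio_variance, solve_basis_variances, sparcc,
                       SimulationDesign, simulate)
from pseudonet.io import ValidationError
from pseudonet.sparcc import AssociationMatrix


class TestFractions:
    def test_uniform_counts_give_uniform_fractions(self):
        f = estimate_fractions(np.array([[1, 1, 1, 1]]), pseudocount=1)
        np.testing.assert_allclose(f, 0.25)

    def test_direct_arithmetic(self):
        f = estimate_fractions(np.array([[3, 0, 1]]), pseudocount=1)
        np.testing.assert_allclose(f[0], [4 / 7, 1 / 7, 2 / 7])

    def test_rows_sum_to_one(self, rng):
        x = rng.integers(0, 50, size=(20, 10))
        f = estimate_fractions(x, pseudocount=1)
        np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-12)
        assert (f > 0).all() and (f < 1).all()


class TestLogratioVariance:
    def test_identical_columns_give_zero(self, rng):
        f = rng.dirichlet(np.ones(4), size=12)
        f[:, 1] = f[:, 0]
        f = f / f.sum(axis=1, keepdims=True)
        t = logratio_variance(f)
        assert t[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_two_point_variance(self):
        # log(f1/f2) takes values (0, 2) over two samples -> variance 2
        f = np.array([[0.5, 0.5, 0.0067, 0.0067],
                      [0.5, 0.5 * np.exp(-2), 0.0067, 0.0067]])
        f = f / f.sum(axis=1, keepdims=True)
        t = logratio_variance(f)
        assert t[0, 1] == pytest.approx(2.0, rel=1e-10)

    def test_matches_bruteforce_two_pass_variance(self, rng):
        f = np.exp(rng.normal(size=(200, 6)))
        f = f / f.sum(axis=1, keepdims=True)
        t = logratio_variance(f)
        lr = np.log(f[:, 2] / f[:, 5])
        brute = ((lr - lr.mean()) ** 2).sum() / (len(lr) - 1)
        assert t[2, 5] == pytest.approx(brute, abs=1e-10)

    def test_single_sample_errors(self):
        with pytest.raises(ValueError, match="2 samples"):
            logratio_variance(np.full((1, 4), 0.25))


class TestBasisVariances:
    def test_recovers_independent_lognormal_variances(self, rng):
        log_w = rng.normal(0.0, 1.0, size=(2000, 4))
        f = np.exp(log_w)
        f = f / f.sum(axis=1, keepdims=True)
        omega, _ = solve_basis_variances(logratio_variance(f))
        np.testing.assert_allclose(omega, 1.0, atol=0.15)

    def test_all_zero_t_gives_floor(self):
        omega, _ = solve_basis_variances(np.zeros((4, 4)))
        np.testing.assert_allclose(omega, 1e-8)

    def test_matches_independent_linear_solve(self, rng):
        # hand-built 4x4 system solved by an independent route
        t = rng.uniform(0.5, 2.0, size=(4, 4))
        t = (t + t.T) / 2
        np.fill_diagonal(t, 0.0)
        omega, _ = solve_basis_variances(t)
        m = np.ones((4, 4)) + np.eye(4) * (4 - 2)
        expected = np.linalg.solve(m, t.sum(axis=1))
        np.testing.assert_allclose(omega, np.maximum(expected, 1e-8),
                                   atol=1e-10)

    def test_fully_excluded_taxon_errors_with_name(self):
        t = np.ones((4, 4)) - np.eye(4)
        mask = ~np.eye(4, dtype=bool)
        mask[2, :] = mask[:, 2] = False
        with pytest.raises(ValidationError, match="tax2"):
            solve_basis_variances(t, mask, taxon_ids=["tax0", "tax1", "tax2", "tax3"])


class TestSparcc:
    def test_output_contract(self, small_counts):
        assoc = sparcc(small_counts)
        v = assoc.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert np.abs(v).max() <= 1.0 + 1e-12

    def test_independent_taxa_have_small_correlations(self):
        d = SimulationDesign(n_per_group=250, p=20, dc_block=(),
                            zero_inflation=0.0, seed=42)
        counts, _, _ = simulate(d)
        r = sparcc(counts).values
        off = np.abs(r - np.eye(20))
        assert off.max() < 0.15

    def test_planted_pair_is_largest_estimate(self):
        d = SimulationDesign(n_per_group=250, p=20, dc_block=(0, 1),
                            dc_correlation_a=0.8, dc_correlation_b=0.8,
                            zero_inflation=0.0, seed=7)
        counts, _, _ = simulate(d)
        r = sparcc(counts).values
        od = r.copy()
        np.fill_diagonal(od, 0.0)
        k, j = np.unravel_index(np.abs(od).argmax(), od.shape)
        assert {k, j} == {0, 1}
        assert od[k, j] > 0.5

    def test_taxon_permutation_equivariance(self, small_counts, rng):
        perm = rng.permutation(small_counts.n_taxa)
        base = sparcc(small_counts).values
        permuted = CountTable(small_counts.counts.iloc[:, perm])
        r_perm = sparcc(permuted).values
        np.testing.assert_allclose(r_perm, base[np.ix_(perm, perm)],
                                   atol=1e-10)

    def test_sample_order_invariance(self, small_counts, rng):
        perm = rng.permutation(small_counts.n_samples)
        base = sparcc(small_counts).values
        shuffled = CountTable(small_counts.counts.iloc[perm])
        np.testing.assert_allclose(sparcc(shuffled).values, base, atol=1e-10)

    def test_deterministic_without_resampling(self, small_counts):
        a = sparcc(small_counts).values
        b = sparcc(small_counts).values
        np.testing.assert_array_equal(a, b)

    def test_resampling_is_seeded(self, small_counts):
        cfg = SparccConfig(resampling_draws=5)
        a = sparcc(small_counts, cfg, random_state=3).values
        b = sparcc(small_counts, cfg, random_state=3).values
        c = sparcc(small_counts, cfg, random_state=4).values
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, c)

    def test_too_few_taxa_errors(self, rng):
        with pytest.raises(ValidationError, match="at least 4 taxa"):
            sparcc(rng.integers(1, 50, size=(6, 3)))

    def test_recovery_mae_below_tenth(self):
        d = SimulationDesign(n_per_group=500, p=20, dc_block=(0, 1, 2, 3),
                            dc_correlation_a=0.6, dc_correlation_b=0.6,
                            zero_inflation=0.0, seed=5)
        counts, _, truth = simulate(d)
        r = sparcc(counts).values
        assert np.abs(r - truth["correlation_a"]).mean() < 0.1


class TestSparccEstimator:
    def test_sklearn_interface(self, small_counts):
        est = SparCC().fit(small_counts)
        assert est.correlation_.shape == (6, 6)
        assert est.taxon_ids_ == small_counts.taxon_ids
        params = est.get_params()
        assert params["exclusion_threshold"] == 0.1
        clone_vals = SparCC(**params).fit(small_counts).correlation_
        np.testing.assert_array_equal(clone_vals, est.correlation_)


class TestAssociationMatrix:
    def test_asymmetric_rejected(self):
        v = np.eye(4)
        v[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            AssociationMatrix(list("abcd"), v)

    def test_difference_kind_bounds(self):
        v = np.zeros((4, 4))
        v[0, 1] = v[1, 0] = 2.5
        with pytest.raises(ValueError, match=r"\[-2, 2\]"):
            AssociationMatrix(list("abcd"), v, kind="difference")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_config_validation_survives_random_counts(seed):
    """sparcc never returns out-of-range correlations on random inputs."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 100, size=(8, 5))
    x[x.sum(axis=1) == 0, 0] = 1
    ct = CountTable(pd.DataFrame(x, index=[f"s{i}" for i in range(8)],
                                 columns=[f"t{j}" for j in range(5)]))
    v = sparcc(ct).values
    assert np.abs(v).max() <= 1 + 1e-12
    assert np.allclose(v, v.T)
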