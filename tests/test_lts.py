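from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from pseudonet import LTSRegression, lts_fit, lts_inference, fit_all_taxa, build_design
from pseudonet.lts import (NotAnalyzableError, h_size, small_sample_factor,
                           _objective, _ols)
from pseudonet.pseudovalue import PseudoValueMatrix


def exhaustive_objective(y, x, h):
    """Independent oracle: minimum over all h-subsets of the LTS objective."""
    n = len(y)
    best = np.inf
    for subset in combinations(range(n), h):
        idx = np.array(subset)
        if np.linalg.matrix_rank(x[idx]) < x.shape[1]:
            continue
        coef = _ols(x[idx], y[idx])
        best = min(best, _objective(x, y, coef, h))
    return best


class TestHSize:
    @pytest.mark.parametrize("n,m,c,expected", [
        (20, 3, 0.5, 12),   # floor(10) + floor(2)
        (20, 3, 1.0, 20),
        (13, 2, 0.5, 7),
        (5, 3, 0.5, 4),     # clamped to m+1
    ])
    def test_convention(self, n, m, c, expected):
        assert h_size(n, m, c) == expected

    def test_out_of_range_c(self):
        with pytest.raises(ValueError):
            h_size(20, 2, 0.3)


class TestLtsFit:
    def test_c_one_equals_ols(self, rng):
        n = 25
        x = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = rng.standard_normal(n)
        fit = lts_fit(y, x, c=1.0)
        np.testing.assert_allclose(fit["coef"], _ols(x, y), atol=1e-8)

    def test_exact_fit_with_gross_outliers(self):
        xs = np.arange(12.0)
        y = 2.0 + 3.0 * xs
        y[[2, 5, 9]] += 100.0
        x = np.column_stack([np.ones(12), xs])
        fit = lts_fit(y, x, c=0.5, random_state=0)
        np.testing.assert_allclose(fit["coef"], [2.0, 3.0], atol=1e-10)
        assert not {2, 5, 9} & set(fit["subset"])

    def test_breakdown_resistance(self, rng):
        """Corrupting n - h points arbitrarily leaves the exact fit."""
        xs = np.arange(12.0)
        y = 2.0 + 3.0 * xs
        x = np.column_stack([np.ones(12), xs])
        h = h_size(12, 2, 0.5)
        corrupt = rng.choice(12, size=12 - h, replace=False)
        y[corrupt] += rng.uniform(50, 500, size=len(corrupt))
        fit = lts_fit(y, x, c=0.5, random_state=0)
        np.testing.assert_allclose(fit["coef"], [2.0, 3.0], atol=1e-10)

    def test_objective_matches_exhaustive_oracle(self, rng):
        for rep in range(12):
            n = int(rng.integers(9, 14))
            x = np.column_stack([np.ones(n), rng.standard_normal(n)])
            y = rng.standard_normal(n)
            fit = lts_fit(y, x, c=0.5, random_state=rep)
            oracle = exhaustive_objective(y, x, fit["h"])
            assert fit["objective"] == pytest.approx(oracle, abs=1e-10)

    def test_randomized_search_beats_random_subsets(self, rng):
        n = 60
        x = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = x @ [1.0, 2.0, -1.0] + rng.standard_normal(n)
        y[:6] += 40
        fit = lts_fit(y, x, c=0.5, random_state=0)
        h = fit["h"]
        for _ in range(500):
            idx = rng.choice(n, size=h, replace=False)
            coef = _ols(x[idx], y[idx])
            assert fit["objective"] <= _objective(x, y, coef, h) + 1e-9

    def test_equivariance_shift_and_scale(self, rng):
        n = 40
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = x @ [0.5, 1.5] + rng.standard_normal(n)
        base = lts_fit(y, x, c=0.5, random_state=3)
        shifted = lts_fit(y + 10.0, x, c=0.5, random_state=3)
        scaled = lts_fit(3.0 * y, x, c=0.5, random_state=3)
        assert shifted["coef"][0] == pytest.approx(base["coef"][0] + 10, abs=1e-6)
        assert shifted["coef"][1] == pytest.approx(base["coef"][1], abs=1e-6)
        np.testing.assert_allclose(scaled["coef"], 3.0 * base["coef"], atol=1e-6)

    def test_rank_deficient_design_errors(self, rng):
        n = 20
        col = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), col, 2.0 * col])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            lts_fit(rng.standard_normal(n), x, c=0.5)


class TestInference:
    def test_clean_c1_matches_classical_ols(self, rng):
        # bounded (uniform) noise: nothing can exceed the 2.5 MAD cut
        n = 30
        x = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        y = x @ [1.0, 0.5, -0.25] + rng.uniform(-1, 1, size=n)
        raw = lts_fit(y, x, c=1.0)
        inf = lts_inference(raw, y, x)
        ref = sm.OLS(y, x).fit()
        np.testing.assert_allclose(inf["estimate"], ref.params, atol=1e-8)
        np.testing.assert_allclose(inf["std_error"], ref.bse, atol=1e-8)
        np.testing.assert_allclose(inf["p_value"], ref.pvalues, atol=1e-8)

    def test_reweighted_mode_matches_ols_when_untrimmed(self, rng):
        n = 30
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = x @ [1.0, 0.5] + rng.uniform(-1, 1, size=n)
        raw = lts_fit(y, x, c=1.0)
        inf = lts_inference(raw, y, x, se_mode="reweighted")
        ref = sm.OLS(y, x).fit()
        np.testing.assert_allclose(inf["p_value"], ref.pvalues, atol=1e-8)

    def test_type_one_error_calibrated(self, rng):
        """Null Z coefficient rejected at ~5% over many simulated taxa."""
        n = 40
        x = np.column_stack([np.ones(n),
                             np.repeat([1.0, 0.0], n // 2),
                             rng.standard_normal(n)])
        rejections = 0
        reps = 400
        for _ in range(reps):
            y = rng.standard_normal(n)
            raw = lts_fit(y, x, c=0.5, random_state=1, n_starts=60)
            inf = lts_inference(raw, y, x)
            rejections += inf["p_value"][1] < 0.05
        rate = rejections / reps
        assert 0.01 <= rate <= 0.09

    def test_power_for_planted_effect(self, rng):
        """Standardized effect 2.0 on Z at n=40 is detected essentially always."""
        n = 40
        x = np.column_stack([np.ones(n),
                             np.repeat([1.0, 0.0], n // 2),
                             rng.standard_normal(n)])
        hits = 0
        reps = 60
        for _ in range(reps):
            y = 2.0 * x[:, 1] + rng.standard_normal(n)
            raw = lts_fit(y, x, c=0.5, random_state=1, n_starts=60)
            inf = lts_inference(raw, y, x)
            hits += inf["p_value"][1] < 0.001
        assert hits / reps >= 0.95

    def test_too_few_retained_errors(self):
        x = np.column_stack([np.ones(6), np.arange(6.0)])
        y = np.array([0.0, 0.0, 0.0, 0.0, 50.0, -50.0])
        raw = lts_fit(y, x, c=0.5, random_state=0)
        with pytest.raises(NotAnalyzableError):
            lts_inference(raw, y, x)


class TestBuildDesign:
    def test_group_coding_and_intercept(self, small_meta):
        d = build_design(small_meta, "group", level_a="case")
        assert list(d.columns[:2]) == ["const", "Z"]
        assert d["Z"].tolist() == [1.0] * 5 + [0.0] * 5
        assert (d["const"] == 1.0).all()

    def test_categorical_expansion_drops_first_level(self, small_meta):
        d = build_design(small_meta, "group", covariates=["site"])
        assert "site[y]" in d.columns and "site[x]" not in d.columns

    def test_numeric_covariate_passthrough(self, small_meta):
        d = build_design(small_meta, "group", covariates=["age"])
        np.testing.assert_allclose(d["age"], small_meta["age"].astype(float))


class TestFitAllTaxa:
    def _pv(self, rng, n=24, p=6):
        theta = rng.standard_normal((n, p))
        return PseudoValueMatrix([f"s{i}" for i in range(n)],
                                 [f"t{j}" for j in range(p)], theta,
                                 n_a=n // 2, n_b=n // 2)

    def _design(self, n=24):
        idx = [f"s{i}" for i in range(n)]
        return pd.DataFrame({"const": 1.0,
                             "Z": [1.0] * (n // 2) + [0.0] * (n // 2)},
                            index=idx)

    def test_one_result_per_taxon(self, rng):
        pv = self._pv(rng)
        results, failures = fit_all_taxa(pv, self._design(), seed=0,
                                         n_starts=50)
        assert set(results["taxon"]) == set(pv.taxon_ids)
        assert not failures
        assert set(results["term"]) == {"const", "Z"}

    def test_duplicate_taxa_get_identical_results(self, rng):
        pv = self._pv(rng)
        pv.theta_tilde[:, 3] = pv.theta_tilde[:, 0]
        results, _ = fit_all_taxa(pv, self._design(), seed=0, n_starts=50)
        a = results[results.taxon == "t0"].drop(columns="taxon").reset_index(drop=True)
        b = results[results.taxon == "t3"].drop(columns="taxon").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_bitwise_deterministic(self, rng):
        pv = self._pv(rng)
        r1, _ = fit_all_taxa(pv, self._design(), seed=42, n_starts=50)
        r2, _ = fit_all_taxa(pv, self._design(), seed=42, n_starts=50)
        pd.testing.assert_frame_equal(r1, r2)

    def test_zero_variance_taxon_marked_failed(self, rng):
        pv = self._pv(rng)
        pv.theta_tilde[:, 2] = 5.0
        results, failures = fit_all_taxa(pv, self._design(), seed=0,
                                         n_starts=50)
        assert any(f["taxon"] == "t2" for f in failures)
        assert "t2" not in set(results["taxon"])


class TestLTSRegressionEstimator:
    def test_fit_predict_and_attributes(self, rng):
        n = 50
        X = rng.standard_normal((n, 2))
        y = 1.0 + X @ [2.0, -1.0] + rng.standard_normal(n) * 0.1
        y[:5] += 30
        est = LTSRegression(random_state=0).fit(X, y)
        assert est.intercept_ == pytest.approx(1.0, abs=0.1)
        np.testing.assert_allclose(est.coef_, [2.0, -1.0], atol=0.1)
        assert est.inlier_mask_.sum() >= 40
        assert not est.inlier_mask_[:5].any()
        pred = est.predict(X[5:])
        assert pred.shape == (45,)

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone
        est = LTSRegression(trim_proportion=0.75, random_state=1)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_lts_objective_never_worse_than_ols(seed):
    rng = np.random.default_rng(seed)
    n = 18
    x = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = rng.standard_normal(n)
    fit = lts_fit(y, x, c=0.5, random_state=0)
    assert fit["objective"] <= _objective(x, y, _ols(x, y), fit["h"]) + 1e-12


def test_small_sample_factor_is_one_without_trimming(rng):
    x = np.column_stack([np.ones(20), rng.standard_normal(20)])
    assert small_sample_factor(x, 1.0) == 1.0
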