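"""Least trimmed squares (LTS) regression of pseudo-values on Z and X.

LTS minimizes the sum of the h smallest squared residuals, discarding up
to n - h observations; the trimming proportion c controls h through

    h = floor(c * n) + floor((m + 1) / 2),   clamped to [m + 1, n],

the convention of the robustbase lineage.  c = 1 gives h = n and reduces
to ordinary least squares.  The optimum coincides with the OLS fit on
the best h-subset, so for small n the exact solution is found by
exhaustive enumeration over h-subsets; for larger n a seeded FAST-LTS
style search is used (random elemental starts, concentration steps,
full refinement of the best candidates).

Inference comes from the reweighting step standard for LTS: residuals
of the raw fit are standardized by the consistency-corrected raw scale,
observations within 2.5 standard deviations are retained, and classical
OLS standard errors, t- and p-values are computed on the retained set.
With nothing trimmed this reduces to textbook OLS inference.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

EXHAUSTIVE_LIMIT = 14
RESIDUAL_CUT = 2.5      # efficiency reweighting cut (classical route)
OUTLIER_CUT = 3.5       # gross-outlier identification cut (jackknife route)


class NotAnalyzableError(RuntimeError):
    """A single taxon's regression cannot produce valid inference."""


def h_size(n: int, m: int, c: float) -> int:
    """Trimmed subset size for n observations, m parameters, proportion c."""
    if not 0.5 <= c <= 1.0:
        raise ValueError("trim proportion c must lie in [0.5, 1]")
    h = int(np.floor(c * n)) + int(np.floor((m + 1) / 2))
    return int(min(max(h, m + 1), n))


def _check_rank(x: np.ndarray) -> None:
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the first column linearly dependent on its predecessors
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) < j + 1:
                raise np.linalg.LinAlgError(
                    f"design matrix rank-deficient: column {j} is collinear "
                    "with earlier columns"
                )
        raise np.linalg.LinAlgError("design matrix rank-deficient")


def _ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return coef


def _objective(x, y, coef, h) -> float:
    r2 = np.square(y - x @ coef)
    return float(np.sort(r2)[:h].sum())


def _c_steps(x, y, coef, h, n_steps) -> tuple[np.ndarray, np.ndarray]:
    """Concentration steps: refit OLS on the h smallest-residual points."""
    subset = None
    for _ in range(n_steps):
        r2 = np.square(y - x @ coef)
        new_subset = np.sort(np.argpartition(r2, h - 1)[:h])
        if subset is not None and np.array_equal(new_subset, subset):
            break
        subset = new_subset
        coef = _ols(x[subset], y[subset])
    return coef, subset


def lts_fit(y, x, c: float = 0.5, random_state: int | None = None,
            n_starts: int = 500) -> dict:
    """Raw LTS solution: coefficients, best h-subset and objective.

    For n <= 14 the optimum is exact (enumeration over h-subsets);
    otherwise 500 seeded elemental starts each get two concentration
    steps and the 10 best candidates are refined to convergence.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if n <= m:
        raise ValueError(f"need n > m, got n={n}, m={m}")
    _check_rank(x)
    h = h_size(n, m, c)

    if h == n:
        coef = _ols(x, y)
        return {"coef": coef, "subset": np.arange(n), "h": h,
                "objective": _objective(x, y, coef, h), "c": c}

    if n <= EXHAUSTIVE_LIMIT:
        best = None
        for subset in combinations(range(n), h):
            idx = np.array(subset)
            xs = x[idx]
            if np.linalg.matrix_rank(xs) < m:
                continue
            coef = _ols(xs, y[idx])
            obj = _objective(x, y, coef, h)
            if best is None or obj < best[0]:
                best = (obj, coef, idx)
        if best is None:
            raise np.linalg.LinAlgError("every h-subset is rank-deficient")
        obj, coef, _ = best
        # polish: concentration steps never increase the objective
        coef, subset = _c_steps(x, y, coef, h, 20)
        return {"coef": coef, "subset": subset, "h": h,
                "objective": _objective(x, y, coef, h), "c": c}

    rng = np.random.default_rng(random_state)
    candidates = []
    for _ in range(n_starts):
        size = m
        while True:
            idx = rng.choice(n, size=size, replace=False)
            if np.linalg.matrix_rank(x[idx]) == m:
                break
            size = min(size + 1, n)
        coef = _ols(x[idx], y[idx])
        coef, _ = _c_steps(x, y, coef, h, 2)
        candidates.append((_objective(x, y, coef, h), coef))
    candidates.sort(key=lambda t: t[0])
    best = None
    for obj, coef in candidates[:10]:
        coef, subset = _c_steps(x, y, coef, h, 10)
        obj = _objective(x, y, coef, h)
        if best is None or obj < best[0]:
            best = (obj, coef, subset)
    obj, coef, subset = best
    return {"coef": coef, "subset": subset, "h": h, "objective": obj, "c": c}


def lts_scale(objective: float, h: int, n: int) -> float:
    """Consistency-corrected raw LTS scale estimate.

    The raw sqrt(objective / h) underestimates sigma because it averages
    the central h/n mass of the residual distribution; dividing by the
    square root of the truncated second moment of the standard normal
    restores consistency.
    """
    alpha = h / n
    raw = np.sqrt(objective / h)
    if alpha >= 1.0 - 1e-12:
        return float(raw)
    q = stats.norm.ppf((1.0 + alpha) / 2.0)
    factor = np.sqrt(1.0 - 2.0 * q * stats.norm.pdf(q) / alpha)
    return float(raw / factor)


def small_sample_factor(x, c: float, n_starts: int = 100, n_sim: int = 60,
                        random_state: int | None = 0,
                        residual_pool=None) -> float:
    """Finite-sample correction for the reweighted LTS residual scale.

    The raw LTS objective selects the tightest h-subset, so at small n
    the reweighted fit both underestimates the residual scale and sits
    on an adaptively chosen central subset; naive OLS standard errors on
    the retained points are too small and type-I error is inflated.  In
    the small-sample-correction tradition of the robustbase lineage,
    the joint effect is measured by a seeded Monte Carlo run of the
    identical fitting procedure on standard-normal responses with the
    actual design matrix: the factor is the root-mean-square of the
    null t-statistics relative to the second moment of their reference
    t distribution, and multiplies the reported standard errors.
    Equals 1 when nothing is trimmed (c = 1).

    The trimming bias grows with the tail weight of the error
    distribution, so when ``residual_pool`` (standardized residuals
    from preliminary untrimmed fits) is given, null responses are
    resampled from it instead of the standard normal; the correction
    then reflects the response distribution actually being fit.
    """
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if h_size(n, m, c) == n:
        return 1.0
    if residual_pool is not None:
        residual_pool = np.asarray(residual_pool, dtype=float)
        residual_pool = residual_pool[np.isfinite(residual_pool)]
        if residual_pool.size < 2 * n:
            residual_pool = None
    rng = np.random.default_rng(random_state)
    t_sq, ref_sq = [], []
    for _ in range(n_sim):
        if residual_pool is None:
            y = rng.standard_normal(n)
        else:
            y = rng.choice(residual_pool, size=n, replace=True)
        raw = lts_fit(y, x, c=c, random_state=int(rng.integers(2 ** 31)),
                      n_starts=n_starts)
        scale = lts_scale(raw["objective"], raw["h"], n)
        if scale <= 0:
            continue
        keep = np.abs((y - x @ raw["coef"]) / scale) <= RESIDUAL_CUT
        df = int(keep.sum()) - m
        if df < 3:
            continue
        xk, yk = x[keep], y[keep]
        coef = _ols(xk, yk)
        resid = yk - xk @ coef
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(xk.T @ xk)
        t_sq.extend(np.square(coef) / np.diag(cov))
        ref_sq.extend([df / (df - 2.0)] * m)
    if not t_sq:
        return 1.0
    factor = float(np.sqrt(np.mean(t_sq) / np.mean(ref_sq)))
    return max(factor, 1.0)


def lts_inference(raw_fit: dict, y, x, term_names=None,
                  scale_factor: float = 1.0,
                  se_mode: str = "jackknife") -> dict:
    """Inference after a raw LTS fit: robust coefficients, two SE routes.

    Observations whose standardized raw-fit residuals exceed a cut are
    flagged as outliers and the coefficients are refit by OLS on the
    remainder (the reweighting step).  The standardization and the
    standard errors come in two flavours:

    ``se_mode="jackknife"`` (default) standardizes the raw-fit
    residuals by a robust estimate of their *full* spread (1.4826 x
    MAD) with a wide identification cut (3.5), so only residuals
    grossly inconsistent with the bulk are flagged and clean data are
    almost never trimmed, and evaluates the residual variance of the
    reweighted
    coefficients over *all* n observations, with n - m degrees of
    freedom.  When the response is a matrix of jackknife
    pseudo-values, their full spread is precisely the jackknife
    estimate of the statistic's sampling variance — including the
    estimation noise shared within a group — so the robust fit may
    discard grossly outlying rows from the coefficients but must not
    discard the ordinary tails from the variance.  Trimmed-subset
    standard errors are badly anticonservative for such responses.

    ``se_mode="reweighted"`` uses the classical route: the 2.5 cut on
    the consistency-corrected trimmed scale, standard errors from the
    retained observations with n_retained - m degrees of freedom,
    multiplied by ``scale_factor`` (see
    :func:`small_sample_factor`) to undo the finite-sample downward
    bias of the trimmed scale.  Appropriate when the response is
    genuinely i.i.d. with gross contamination.

    Both routes coincide with textbook OLS inference when nothing is
    trimmed.
    """
    if se_mode not in ("jackknife", "reweighted"):
        raise ValueError(f"unknown se_mode {se_mode!r}")
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float)
    n, m = x.shape
    if term_names is None:
        term_names = [f"x{j}" for j in range(m)]
    resid = y - x @ raw_fit["coef"]
    if se_mode == "jackknife":
        # identification-only trimming: standardize by the robust full
        # spread and use a cut wide enough that clean data are almost
        # never trimmed (the jackknife SE cannot account for routine
        # adaptive trimming, only for removing gross outliers)
        scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
        cut = OUTLIER_CUT
    else:
        scale = lts_scale(raw_fit["objective"], raw_fit["h"], n)
        cut = RESIDUAL_CUT
    if scale <= 0.0:
        keep = np.isclose(resid, 0.0, atol=1e-12)
    else:
        keep = np.abs(resid / scale) <= cut
    if keep.sum() < m + 2:
        raise NotAnalyzableError(
            f"only {int(keep.sum())} observations retained after "
            f"reweighting; need at least {m + 2}"
        )
    model = sm.OLS(y[keep], x[keep]).fit()
    if not np.all(model.bse > 0):
        raise NotAnalyzableError("degenerate fit: zero standard errors")
    est = np.asarray(model.params, dtype=float)
    if se_mode == "jackknife":
        resid_full = y - x @ est
        df = n - m
        sigma2 = float(resid_full @ resid_full) / df
        if sigma2 <= 0:
            raise NotAnalyzableError("degenerate fit: zero residual variance")
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(x.T @ x)))
    else:
        df = int(keep.sum()) - m
        se = np.asarray(model.bse, dtype=float) * scale_factor
    tval = est / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df)
    return {
        "terms": list(term_names),
        "estimate": np.asarray(model.params, dtype=float),
        "std_error": se,
        "t": tval,
        "p_value": pval,
        "h_used": int(raw_fit["h"]),
        "n_retained": int(keep.sum()),
        "outlier_flags": ~keep,
        "scale": scale,
    }


def build_design(meta: pd.DataFrame, group_var: str,
                 covariates: list[str] | None = None,
                 level_a=None) -> pd.DataFrame:
    """Design matrix: intercept, 0/1 group indicator Z, covariate terms.

    Z is 1 for samples at ``level_a`` (default: lexically first level).
    Numeric covariates enter as-is; a categorical covariate with k
    levels expands to k - 1 indicators against the lexically first
    level.
    """
    col = meta[group_var].astype(str)
    levels = sorted(col.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"group variable must be binary, levels: {levels}")
    if level_a is None:
        level_a = levels[0]
    z = (col == str(level_a)).astype(float)
    design = pd.DataFrame({"const": 1.0, "Z": z}, index=meta.index)
    for cov in covariates or []:
        series = meta[cov]
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.notna().all():
            design[cov] = numeric.astype(float)
        else:
            cats = sorted(series.astype(str).dropna().unique())
            for level in cats[1:]:
                design[f"{cov}[{level}]"] = (
                    series.astype(str) == level
                ).astype(float)
    return design


def fit_all_taxa(pv, design: pd.DataFrame, c: float = 0.5,
                 seed: int | None = None, n_starts: int = 500,
                 se_mode: str = "jackknife"
                 ) -> tuple[pd.DataFrame, list[dict]]:
    """Per-taxon LTS pseudo-value regressions against one shared design.

    Returns a long-format results frame (taxon, term, estimate,
    std_error, t, p_value) and a list of per-taxon failure records;
    failing taxa never abort the run.
    """
    x = design.to_numpy(dtype=float)
    terms = list(design.columns)
    theta = pv.theta_tilde
    factor = 1.0
    if se_mode == "reweighted":
        # design shared across taxa, so the finite-sample correction is
        # too; calibrate against the pooled standardized pseudo-value
        # residuals rather than a Gaussian
        pool = []
        hat = x @ np.linalg.pinv(x)
        for k in range(theta.shape[1]):
            resid = theta[:, k] - hat @ theta[:, k]
            sd = resid.std(ddof=x.shape[1])
            if sd > 0:
                pool.append(resid / sd)
        pool = np.concatenate(pool) if pool else None
        factor = small_sample_factor(x, c, random_state=seed,
                                     residual_pool=pool)
    rows, failures = [], []
    for k, taxon in enumerate(pv.taxon_ids):
        y = theta[:, k]
        try:
            if float(np.var(y)) < 1e-14:
                raise NotAnalyzableError("zero-variance response")
            raw = lts_fit(y, x, c=c, random_state=seed, n_starts=n_starts)
            inf = lts_inference(raw, y, x, terms, scale_factor=factor,
                                se_mode=se_mode)
        except (NotAnalyzableError, np.linalg.LinAlgError) as exc:
            failures.append({"taxon": taxon, "reason": str(exc)})
            continue
        for j, term in enumerate(terms):
            rows.append({
                "taxon": taxon, "term": term,
                "estimate": inf["estimate"][j],
                "std_error": inf["std_error"][j],
                "t": inf["t"][j], "p_value": inf["p_value"][j],
                "h_used": inf["h_used"], "n_retained": inf["n_retained"],
            })
    columns = ["taxon", "term", "estimate", "std_error", "t", "p_value",
               "h_used", "n_retained"]
    results = pd.DataFrame(rows, columns=columns)
    return results, failures


class LTSRegression(RegressorMixin, BaseEstimator):
    """Least trimmed squares regression with reweighted-OLS inference.

    A scikit-learn style robust regressor: ``fit`` minimizes the sum of
    the h smallest squared residuals (h set by ``trim_proportion``),
    then refits OLS on the observations within 2.5 standardized raw
    residuals.

    Parameters
    ----------
    trim_proportion : float in [0.5, 1], default 0.5
        c = 1 reduces to ordinary least squares.
    fit_intercept : bool, default True
    n_starts : int, default 500
        Elemental starts of the randomized search (n > 14 only).
    random_state : int, optional

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    se_, tvalues_, pvalues_ : per-term inference (intercept first when
        fitted), from the reweighted fit
    inlier_mask_ : boolean mask of observations retained by reweighting
    scale_ : consistency-corrected raw LTS scale
    objective_ : sum of the h smallest squared residuals of the raw fit
    """

    def __init__(self, trim_proportion: float = 0.5, fit_intercept: bool = True,
                 n_starts: int = 500, se_mode: str = "reweighted",
                 random_state: int | None = None):
        self.trim_proportion = trim_proportion
        self.fit_intercept = fit_intercept
        self.n_starts = n_starts
        self.se_mode = se_mode
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        design = np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X
        raw = lts_fit(y, design, c=self.trim_proportion,
                      random_state=self.random_state, n_starts=self.n_starts)
        factor = 1.0
        if self.se_mode == "reweighted":
            factor = small_sample_factor(design, self.trim_proportion,
                                         random_state=self.random_state)
        inf = lts_inference(raw, y, design, scale_factor=factor,
                            se_mode=self.se_mode)
        est = inf["estimate"]
        if self.fit_intercept:
            self.intercept_ = float(est[0])
            self.coef_ = est[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = est
        self.se_ = inf["std_error"]
        self.tvalues_ = inf["t"]
        self.pvalues_ = inf["p_value"]
        self.inlier_mask_ = ~inf["outlier_flags"]
        self.scale_ = inf["scale"]
        self.objective_ = raw["objective"]
        self.raw_coef_ = raw["coef"]
        self.h_ = raw["h"]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ + self.intercept_
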