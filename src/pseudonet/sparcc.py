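"""SparCC correlation estimation for compositional count data.

SparCC infers correlations between unobserved "basis" abundances from
relative-abundance data.  Writing f_ik for the fraction of taxon k in
sample i, the log-ratio variance

    T_kj = Var_i[ log(f_ik / f_ij) ]

satisfies T_kj = w_k + w_j - 2 rho_kj sqrt(w_k w_j), where w_k is the
variance of the log basis abundance of taxon k and rho_kj the basis
correlation.  Under the sparsity assumption (most pairs uncorrelated)
the basis variances solve a linear system built from row sums of T;
correlations follow by inversion of the identity above.  Pairs whose
estimated |rho| exceeds a threshold visibly violate the sparsity
assumption and are excluded from the basis solve one at a time, and the
system is re-solved, up to a fixed number of rounds.

By default fractions are the deterministic posterior mean under a
uniform Dirichlet prior (add-one pseudocounts), so the estimate is a
pure function of the counts; ``resampling_draws > 0`` instead averages
the correlation estimate over seeded Dirichlet draws of the fractions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .io import CountTable, MIN_TAXA, ValidationError

logger = logging.getLogger("pseudonet")

VARIANCE_FLOOR = 1e-8


@dataclass
class SparccConfig:
    """Tuning constants of the SparCC iteration.

    Parameters
    ----------
    exclusion_threshold : float in (0, 1)
        Correlation magnitude above which the strongest pair is dropped
        from the basis-variance solve each round.
    max_exclusion_rounds : int
        Upper bound on exclusion rounds.
    pseudocount : float > 0
        Added to every count before forming fractions.
    resampling_draws : int
        0 gives deterministic posterior-mean fractions; > 0 averages the
        correlation estimate over that many Dirichlet draws.
    """

    exclusion_threshold: float = 0.1
    max_exclusion_rounds: int = 10
    pseudocount: float = 1.0
    resampling_draws: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.exclusion_threshold < 1.0:
            raise ValueError("exclusion_threshold must be in (0, 1)")
        if self.max_exclusion_rounds < 0:
            raise ValueError("max_exclusion_rounds must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.resampling_draws < 0:
            raise ValueError("resampling_draws must be >= 0")


@dataclass
class AssociationMatrix:
    """Symmetric taxa x taxa matrix of pairwise association estimates.

    ``kind`` is "correlation" (unit diagonal, entries in [-1, 1]) or
    "difference" (an entrywise difference of two correlation matrices:
    zero diagonal, entries in [-2, 2]).
    """

    taxon_ids: list[str]
    values: np.ndarray = field(repr=False)
    kind: str = "correlation"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        p = len(self.taxon_ids)
        if v.shape != (p, p):
            raise ValueError(f"values must be {p}x{p}, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("association matrix must be symmetric")
        if self.kind == "correlation":
            if not np.allclose(np.diag(v), 1.0, atol=1e-12):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.abs(v).max() > 1 + 1e-12:
                raise ValueError("correlation entries must lie in [-1, 1]")
        elif self.kind == "difference":
            if not np.allclose(np.diag(v), 0.0, atol=1e-12):
                raise ValueError("difference matrix must have zero diagonal")
            if np.abs(v).max() > 2 + 1e-12:
                raise ValueError("difference entries must lie in [-2, 2]")
        else:
            raise ValueError(f"unknown kind {self.kind!r}")
        self.values = (v + v.T) / 2.0

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


def estimate_fractions(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Posterior-mean relative abundances with additive pseudocounts.

    Row i, column j is (count_ij + pseudocount) / (row_total_i + p * pseudocount),
    so rows sum to one and every entry is strictly positive.
    """
    x = counts.values if isinstance(counts, CountTable) else np.asarray(counts, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    p = x.shape[1]
    num = x + pseudocount
    return num / num.sum(axis=1, keepdims=True)


def _dirichlet_fractions(counts: np.ndarray, pseudocount: float,
                         rng: np.random.Generator) -> np.ndarray:
    alpha = counts + pseudocount
    g = rng.standard_gamma(alpha)
    return g / g.sum(axis=1, keepdims=True)


def logratio_variance(fractions: np.ndarray) -> np.ndarray:
    """Matrix T of variances of log(f_k / f_j) across samples.

    Uses the unbiased (n - 1) denominator.  Symmetric with zero diagonal.
    """
    f = np.asarray(fractions, dtype=float)
    n = f.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to form log-ratio variances")
    if (f <= 0).any():
        raise ValueError("fractions must be strictly positive")
    log_f = np.log(f)
    # Var(a - b) = Var(a) + Var(b) - 2 Cov(a, b), via the covariance of log f
    cov = np.cov(log_f, rowvar=False, ddof=1)
    d = np.diag(cov)
    t = d[:, None] + d[None, :] - 2.0 * cov
    t = (t + t.T) / 2.0
    np.fill_diagonal(t, 0.0)
    return np.maximum(t, 0.0)


def solve_basis_variances(t: np.ndarray, mask: np.ndarray | None = None,
                          taxon_ids=None) -> tuple[np.ndarray, bool]:
    """Solve the SparCC linear system for basis variances.

    For each taxon k, summing T_kj over included partners j under the
    sparsity assumption (rho ~ 0 for included pairs) gives

        sum_j T_kj  =  d_k * w_k + sum_j w_j

    with d_k the number of included partners; in matrix form
    (diag(d) + A) w = t_row, A the inclusion adjacency.  Negative
    solutions are clamped to a small positive floor with a warning.

    Returns
    -------
    (omega, clamped) : basis-variance vector and whether clamping fired.
    """
    t = np.asarray(t, dtype=float)
    p = t.shape[0]
    if p < MIN_TAXA:
        raise ValidationError(f"need at least {MIN_TAXA} taxa, got {p}")
    if mask is None:
        mask = ~np.eye(p, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not (mask == mask.T).all():
        raise ValueError("pair inclusion mask must be symmetric")
    mask = mask & ~np.eye(p, dtype=bool)
    degree = mask.sum(axis=1)
    if (degree == 0).any():
        k = int(np.flatnonzero(degree == 0)[0])
        name = taxon_ids[k] if taxon_ids is not None else f"#{k}"
        raise ValidationError(
            f"basis-variance system singular: taxon {name} has all pairs excluded"
        )
    m = mask.astype(float)
    np.fill_diagonal(m, degree.astype(float))
    rhs = (t * mask).sum(axis=1)
    try:
        omega = np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"basis-variance system singular: {exc}") from exc
    clamped = bool((omega < VARIANCE_FLOOR).any())
    if clamped and (omega < 0).any():
        warnings.warn(
            "negative basis variances clamped to floor", RuntimeWarning,
            stacklevel=2,
        )
    return np.maximum(omega, VARIANCE_FLOOR), clamped


def _correlation_from_t(t: np.ndarray, config: SparccConfig,
                        taxon_ids=None,
                        fixed_mask: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Exclusion iteration: basis solve -> correlations -> drop worst pair.

    With ``fixed_mask`` the exclusion iteration is skipped and the basis
    variances are solved once under the given pair-inclusion mask.
    Returns the clipped correlation matrix and the final mask.
    """
    p = t.shape[0]
    if fixed_mask is not None:
        omega, _ = solve_basis_variances(t, fixed_mask, taxon_ids)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t) / denom
        rho = np.clip(rho, -1.0, 1.0)
        rho = (rho + rho.T) / 2.0
        np.fill_diagonal(rho, 1.0)
        return rho, np.asarray(fixed_mask, dtype=bool)
    mask = ~np.eye(p, dtype=bool)
    rho = None
    for _ in range(config.max_exclusion_rounds + 1):
        omega, _ = solve_basis_variances(t, mask, taxon_ids)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        cand = np.abs(rho) * mask
        np.fill_diagonal(cand, 0.0)
        worst = cand.max()
        if worst <= config.exclusion_threshold:
            break
        k, j = np.unravel_index(int(cand.argmax()), cand.shape)
        mask[k, j] = mask[j, k] = False
        if (mask.sum(axis=1) == 0).any():
            # never fully disconnect a taxon; keep the previous estimate
            mask[k, j] = mask[j, k] = True
            break
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return rho, mask


def sparcc(counts, config: SparccConfig | None = None,
           random_state: int | None = None,
           fixed_mask: np.ndarray | None = None,
           return_mask: bool = False):
    """Estimate the SparCC correlation matrix of a count table.

    ``fixed_mask`` bypasses the exclusion iteration and solves the basis
    variances under the given pair-inclusion mask; ``return_mask``
    additionally returns the final inclusion mask (useful to freeze the
    exclusion set across jackknife re-estimates).
    """
    config = config or SparccConfig()
    if isinstance(counts, CountTable):
        taxon_ids = counts.taxon_ids
        x = counts.values.astype(float)
    else:
        x = np.asarray(counts, dtype=float)
        taxon_ids = [f"taxon_{k}" for k in range(x.shape[1])]
    if x.shape[1] < MIN_TAXA:
        raise ValidationError(f"need at least {MIN_TAXA} taxa, got {x.shape[1]}")
    if config.resampling_draws == 0:
        f = estimate_fractions(x, config.pseudocount)
        t = logratio_variance(f)
        rho, mask = _correlation_from_t(t, config, taxon_ids, fixed_mask)
    else:
        rng = np.random.default_rng(random_state)
        acc = np.zeros((x.shape[1], x.shape[1]))
        mask = None
        for _ in range(config.resampling_draws):
            f = _dirichlet_fractions(x, config.pseudocount, rng)
            t = logratio_variance(f)
            draw, mask = _correlation_from_t(t, config, taxon_ids, fixed_mask)
            acc += draw
        rho = np.clip(acc / config.resampling_draws, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
    assoc = AssociationMatrix(taxon_ids=list(taxon_ids), values=rho,
                              kind="correlation")
    if return_mask:
        return assoc, mask
    return assoc


class SparCC(BaseEstimator):
    """SparCC basis-correlation estimator with a scikit-learn interface.

    Fit on a samples x taxa count matrix; the estimated correlation
    matrix is exposed as ``correlation_`` (ndarray) and
    ``association_`` (:class:`AssociationMatrix`).

    Parameters mirror :class:`SparccConfig`.
    """

    def __init__(self, exclusion_threshold: float = 0.1,
                 max_exclusion_rounds: int = 10, pseudocount: float = 1.0,
                 resampling_draws: int = 0, random_state: int | None = None):
        self.exclusion_threshold = exclusion_threshold
        self.max_exclusion_rounds = max_exclusion_rounds
        self.pseudocount = pseudocount
        self.resampling_draws = resampling_draws
        self.random_state = random_state

    def _config(self) -> SparccConfig:
        return SparccConfig(
            exclusion_threshold=self.exclusion_threshold,
            max_exclusion_rounds=self.max_exclusion_rounds,
            pseudocount=self.pseudocount,
            resampling_draws=self.resampling_draws,
        )

    def fit(self, X, y=None):
        assoc = sparcc(X, self._config(), random_state=self.random_state)
        self.association_ = assoc
        self.correlation_ = assoc.values
        self.taxon_ids_ = assoc.taxon_ids
        self.n_features_in_ = assoc.n_taxa
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the estimated correlation matrix."""
        return self.fit(X).correlation_

    def transform(self, X=None):
        check_is_fitted(self, "correlation_")
        return self.correlation_
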