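"""q-values and differentially connected taxon calls.

q-values follow the step-up construction

    q_i = min_{j : p_j >= p_i}  pi0 * m * p_j / rank(p_j)

where pi0 is the estimated proportion of true nulls.  With
``pi0_method="fixed_one"`` (pi0 = 1) this is exactly the
Benjamini-Hochberg adjusted p-value; ``"smoother"`` estimates pi0 by
fitting a cubic smoother to pi0(lambda) = #{p > lambda} / (m (1 - lambda))
over a lambda grid and evaluating it at lambda = 0.95, clamped to (0, 1].
The smoother route is preferred above ~100 tests; below that it is noisy
and fixed_one is the safe fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)


@dataclass
class QValueResult:
    """Per-test p- and q-values plus the estimated null proportion."""

    p_values: np.ndarray = field(repr=False)
    q_values: np.ndarray = field(repr=False)
    pi0: float = 1.0
    pi0_method: str = "smoother"


def estimate_pi0_smoother(p: np.ndarray) -> float:
    """Cubic-smoother estimate of the null proportion pi0.

    pi0(lambda) is computed on a 0.05-step grid and a cubic polynomial
    smoother is evaluated at lambda = 0.95; the result is clamped to
    (0, 1].
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    pi0_lambda = np.array([(p > lam).sum() / (m * (1.0 - lam))
                           for lam in LAMBDA_GRID])
    coeffs = np.polyfit(LAMBDA_GRID, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, 0.95))
    return float(np.clip(pi0, 1e-8, 1.0))


MIN_TESTS_FOR_SMOOTHER = 100


def qvalues(p, pi0_method: str = "smoother") -> QValueResult:
    """q-values for a vector of p-values.

    ``pi0_method="fixed_one"`` gives Benjamini-Hochberg adjusted
    p-values; ``"smoother"`` scales them by the estimated pi0;
    ``"auto"`` uses the smoother for 100 or more tests and falls back
    to fixed_one below that, where the lambda-grid extrapolation is too
    noisy to trust (it can collapse to pi0 ~ 0 and declare everything
    significant).
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if pi0_method == "auto":
        pi0_method = ("smoother" if p.size >= MIN_TESTS_FOR_SMOOTHER
                      else "fixed_one")
    if pi0_method == "fixed_one":
        pi0 = 1.0
    elif pi0_method == "smoother":
        pi0 = estimate_pi0_smoother(p)
    else:
        raise ValueError(f"unknown pi0_method {pi0_method!r}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(p_values=p, q_values=q, pi0=pi0,
                        pi0_method=pi0_method)


def attach_qvalues(results: pd.DataFrame, pi0_method: str = "auto",
                   threshold: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Append q_value and dc_flag columns, per model term.

    q-values are computed within each term (one family of p tests per
    term across taxa).  Returns the augmented frame and a per-term pi0
    map.
    """
    out = results.copy()
    out["q_value"] = np.nan
    pi0_by_term: dict[str, float] = {}
    for term, block in results.groupby("term", sort=False):
        res = qvalues(block["p_value"].to_numpy(), pi0_method=pi0_method)
        out.loc[block.index, "q_value"] = res.q_values
        pi0_by_term[term] = res.pi0
    out["dc_flag"] = out["q_value"] <= threshold
    return out, pi0_by_term


def dc_taxa(results: pd.DataFrame, term: str = "Z",
            threshold: float = 0.05) -> list[str]:
    """Differentially connected taxa for one term at a q cut-off.

    Sorted by ascending q-value, ties broken by taxon id.
    """
    if results.empty:
        return []
    terms = results["term"].unique().tolist()
    if term not in terms:
        raise ValueError(f"unknown term {term!r}; available: {terms}")
    block = results[results["term"] == term]
    hits = block[block["q_value"] <= threshold]
    hits = hits.sort_values(["q_value", "taxon"], kind="stable")
    return hits["taxon"].tolist()
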