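"""End-to-end differential connectivity analysis and result accessors.

The pipeline runs five stages: (i) group-specific SparCC association
matrices and connectivity on the full data; (ii) the same for every
leave-one-out sample; (iii) jackknife pseudo-values; (iv) per-taxon
least trimmed squares regression of pseudo-values on the group indicator
Z and covariates X; (v) q-values and differentially connected (DC)
taxon calls on the Z term.  The two-timepoint mode estimates matrices
per group and timepoint, differences them (follow-up minus baseline),
and proceeds identically with the subject as the resampling unit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .fdr import attach_qvalues, dc_taxa
from .io import CountTable, ValidationError, align, group_indices
from .lts import build_design, fit_all_taxa
from .pseudovalue import (PseudoValueMatrix, assemble_pseudovalues,
                          assemble_pseudovalues_paired)
from .sparcc import SparccConfig

logger = logging.getLogger("pseudonet")


@dataclass
class AnalysisResult:
    """Everything one run produces, plus the configuration to redo it."""

    pseudo_values: PseudoValueMatrix
    results: pd.DataFrame = field(repr=False)
    failures: list = field(default_factory=list)
    pi0: dict = field(default_factory=dict)
    design: pd.DataFrame | None = field(default=None, repr=False)
    config: dict = field(default_factory=dict)

    def dc_taxa(self, term: str = "Z", threshold: float | None = None) -> list[str]:
        thr = self.config.get("dc_threshold", 0.05) if threshold is None else threshold
        return dc_taxa(self.results, term=term, threshold=thr)


def _pivot(results: pd.DataFrame, column: str, variable: str | None):
    table = results.pivot(index="taxon", columns="term", values=column)
    table = table.reindex(columns=results["term"].unique())
    table = table.loc[results["taxon"].unique()]
    if variable is None:
        return table
    if variable not in table.columns:
        raise ValueError(
            f"unknown variable {variable!r}; available terms: {list(table.columns)}"
        )
    return table[variable]


def _results_frame(obj) -> pd.DataFrame:
    if isinstance(obj, AnalysisResult):
        return obj.results
    if hasattr(obj, "results_"):
        return obj.results_
    if isinstance(obj, pd.DataFrame):
        return obj
    raise TypeError("expected an AnalysisResult, fitted estimator or frame")


def pval(result, variable: str | None = None):
    """P-value table (taxa x terms), or one term's column."""
    return _pivot(_results_frame(result), "p_value", variable)


def qval(result, variable: str | None = None):
    """Q-value table (taxa x terms), or one term's column."""
    return _pivot(_results_frame(result), "q_value", variable)


def coeff(result, variable: str | None = None):
    """Coefficient-estimate table (taxa x terms), or one term's column."""
    return _pivot(_results_frame(result), "estimate", variable)


def stderrs(result, variable: str | None = None):
    """Standard-error table (taxa x terms), or one term's column."""
    return _pivot(_results_frame(result), "std_error", variable)


class DifferentialConnectivityAnalysis(BaseEstimator):
    """Covariate-adjusted differential co-abundance network analysis.

    A fit-only estimator: ``fit(counts, meta)`` runs the whole pipeline
    and stores per-taxon regression results.  DC between the two groups
    is quantified by the coefficient on the 0/1 group indicator Z,
    adjusting for covariates.

    Parameters
    ----------
    group_var : str
        Metadata column holding the binary grouping variable.
    covariates : list of str, optional
        Metadata columns entering the regression alongside Z.
    level_a : optional
        Group level coded Z = 1 (default: lexically first level).
    trim_proportion : float in [0.5, 1], default 0.5
        LTS trimming proportion c; 1 means ordinary least squares.
    mode : {"single", "two_timepoint"}
        ``two_timepoint`` consumes long-format metadata with
        ``subject_col`` and ``time_col`` and analyzes follow-up minus
        baseline difference networks.
    subject_col, time_col, baseline : two-timepoint bookkeeping;
        ``baseline`` names the timepoint level subtracted (default
        lexically first).
    normalize : bool, default False
        Divide connectivity by p - 1 (rescales the response only).
    exclusion_threshold, max_exclusion_rounds, pseudocount,
    resampling_draws : SparCC tuning, see :class:`SparccConfig`.  The
        pipeline default is ``max_exclusion_rounds=0``: the pair
        exclusion iteration is a discrete model-selection step whose
        flips between groups and leave-one-out replicates add selection
        noise the jackknife cannot account for, measurably inflating
        type-I error of the group test.  Standalone SparCC estimation
        (:class:`~pseudonet.sparcc.SparCC`) keeps the classic iterating
        default.
    pi0_method : {"auto", "smoother", "fixed_one"}, default "auto"
        (smoother above 100 tests, Benjamini-Hochberg below)
    dc_threshold : float, default 0.05
        q-value cut-off for DC calls.
    n_starts : int, default 500
        LTS random-search starts.
    n_jobs : int, default 1
        Workers for leave-one-out network re-estimation; results are
        independent of worker count.
    random_state : int, optional

    Attributes
    ----------
    results_ : long-format frame (taxon, term, estimate, std_error, t,
        p_value, q_value, dc_flag)
    pseudo_values_ : PseudoValueMatrix
    dc_taxa_ : DC taxa for the Z term at ``dc_threshold``
    failures_ : per-taxon failure records excluded from FDR
    pi0_ : per-term estimated null proportion
    config_ : snapshot sufficient to reproduce the run
    """

    def __init__(self, group_var: str = "group", covariates=None,
                 level_a=None, trim_proportion: float = 0.5,
                 mode: str = "single", subject_col: str | None = None,
                 time_col: str | None = None, baseline=None,
                 normalize: bool = False, exclusion_threshold: float = 0.1,
                 max_exclusion_rounds: int = 0, pseudocount: float = 1.0,
                 resampling_draws: int = 0, pi0_method: str = "auto",
                 dc_threshold: float = 0.05, n_starts: int = 500,
                 se_mode: str = "jackknife", n_jobs: int = 1,
                 random_state: int | None = None):
        self.group_var = group_var
        self.covariates = covariates
        self.level_a = level_a
        self.trim_proportion = trim_proportion
        self.mode = mode
        self.subject_col = subject_col
        self.time_col = time_col
        self.baseline = baseline
        self.normalize = normalize
        self.exclusion_threshold = exclusion_threshold
        self.max_exclusion_rounds = max_exclusion_rounds
        self.pseudocount = pseudocount
        self.resampling_draws = resampling_draws
        self.pi0_method = pi0_method
        self.dc_threshold = dc_threshold
        self.n_starts = n_starts
        self.se_mode = se_mode
        self.n_jobs = n_jobs
        self.random_state = random_state

    def _sparcc_config(self) -> SparccConfig:
        return SparccConfig(
            exclusion_threshold=self.exclusion_threshold,
            max_exclusion_rounds=self.max_exclusion_rounds,
            pseudocount=self.pseudocount,
            resampling_draws=self.resampling_draws,
        )

    # -- two-timepoint restructuring -----------------------------------
    def _pair_subjects(self, counts: CountTable, meta: pd.DataFrame):
        if self.subject_col is None or self.time_col is None:
            raise ValidationError(
                "two_timepoint mode needs subject_col and time_col"
            )
        times = sorted(meta[self.time_col].astype(str).unique())
        if len(times) != 2:
            raise ValidationError(
                f"time column must have exactly 2 levels, found {times}"
            )
        t1 = str(self.baseline) if self.baseline is not None else times[0]
        if t1 not in times:
            raise ValidationError(
                f"baseline {t1!r} not among timepoints {times}"
            )
        t2 = [t for t in times if t != t1][0]
        per_time = {}
        for t in (t1, t2):
            block = meta[meta[self.time_col].astype(str) == t]
            if block[self.subject_col].duplicated().any():
                raise ValidationError(
                    f"subjects must appear exactly once per timepoint ({t})"
                )
            per_time[t] = block
        subj1 = list(per_time[t1][self.subject_col])
        subj2 = set(per_time[t2][self.subject_col])
        shared = [s for s in subj1 if s in subj2]
        if len(shared) < 8:
            raise ValidationError(
                f"only {len(shared)} subjects observed at both timepoints"
            )
        b1 = per_time[t1].set_index(self.subject_col).loc[shared]
        b2 = per_time[t2].set_index(self.subject_col).loc[shared]
        counts_t1 = counts.subset_samples(list(b1.index.map(
            dict(zip(per_time[t1][self.subject_col], per_time[t1].index)))))
        counts_t2 = counts.subset_samples(list(b2.index.map(
            dict(zip(per_time[t2][self.subject_col], per_time[t2].index)))))
        subject_meta = b1.drop(columns=[self.time_col])
        subject_meta.index = counts_t1.sample_ids
        return counts_t1, counts_t2, subject_meta

    def fit(self, counts: CountTable, meta: pd.DataFrame):
        """Run the full analysis on aligned counts and metadata."""
        t0 = time.perf_counter()
        covs = list(self.covariates) if self.covariates else []
        variables = covs + [v for v in (self.subject_col, self.time_col)
                            if self.mode == "two_timepoint" and v is not None]
        counts, meta, n_dropped = align(counts, meta, variables=variables,
                                        group_var=self.group_var
                                        if self.mode == "single" else None)
        config = self._sparcc_config()
        if self.mode == "single":
            idx_a, idx_b = group_indices(meta, self.group_var, self.level_a)
            if min(len(idx_a), len(idx_b)) < 4:
                raise ValidationError("each group needs at least 4 samples")
            logger.info("stage networks+pseudovalues: n=%d p=%d",
                        counts.n_samples, counts.n_taxa)
            pv = assemble_pseudovalues(counts, idx_a, idx_b, config,
                                       normalize=self.normalize,
                                       n_jobs=self.n_jobs)
            model_meta = meta
        elif self.mode == "two_timepoint":
            counts_t1, counts_t2, model_meta = self._pair_subjects(counts, meta)
            idx_a, idx_b = group_indices(model_meta, self.group_var,
                                         self.level_a)
            if min(len(idx_a), len(idx_b)) < 4:
                raise ValidationError("each group needs at least 4 subjects")
            logger.info("stage difference networks: subjects=%d p=%d",
                        counts_t1.n_samples, counts_t1.n_taxa)
            pv = assemble_pseudovalues_paired(counts_t1, counts_t2,
                                              idx_a, idx_b, config,
                                              normalize=self.normalize,
                                              n_jobs=self.n_jobs)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        t1 = time.perf_counter()
        logger.info("stage pseudovalues done in %.2fs", t1 - t0)
        design = build_design(model_meta, self.group_var, covs, self.level_a)
        results, failures = fit_all_taxa(pv, design, c=self.trim_proportion,
                                         seed=self.random_state,
                                         n_starts=self.n_starts,
                                         se_mode=self.se_mode)
        if results.empty:
            augmented = results.assign(q_value=np.nan, dc_flag=False)
            pi0 = {}
        else:
            augmented, pi0 = attach_qvalues(results,
                                            pi0_method=self.pi0_method,
                                            threshold=self.dc_threshold)
        logger.info("stage regression+fdr done in %.2fs (%d taxa, %d failed)",
                    time.perf_counter() - t1, counts.n_taxa, len(failures))
        self.results_ = augmented
        self.pseudo_values_ = pv
        self.failures_ = failures
        self.pi0_ = pi0
        self.design_ = design
        self.n_dropped_ = n_dropped
        self.dc_taxa_ = ([] if augmented.empty else
                         dc_taxa(augmented, "Z", self.dc_threshold))
        self.config_ = dict(self.get_params(),
                            n_samples=counts.n_samples,
                            n_taxa=counts.n_taxa,
                            n_a=pv.n_a, n_b=pv.n_b)
        return self

    def result(self) -> AnalysisResult:
        check_is_fitted(self, "results_")
        return AnalysisResult(pseudo_values=self.pseudo_values_,
                              results=self.results_,
                              failures=self.failures_, pi0=self.pi0_,
                              design=self.design_, config=self.config_)


def run_dna(counts: CountTable, meta: pd.DataFrame, group_var: str = "group",
            covariates=None, c: float = 0.5, mode: str = "single",
            config: SparccConfig | None = None, seed: int | None = None,
            **kwargs) -> AnalysisResult:
    """One-call pipeline: returns an :class:`AnalysisResult`.

    ``config`` carries the SparCC tuning (default: no exclusion
    iteration, see :class:`DifferentialConnectivityAnalysis`); remaining
    keyword arguments go to :class:`DifferentialConnectivityAnalysis`
    (e.g. ``subject_col``, ``time_col``, ``n_jobs``, ``pi0_method``).
    """
    config = config or SparccConfig(max_exclusion_rounds=0)
    est = DifferentialConnectivityAnalysis(
        group_var=group_var, covariates=covariates, trim_proportion=c,
        mode=mode, exclusion_threshold=config.exclusion_threshold,
        max_exclusion_rounds=config.max_exclusion_rounds,
        pseudocount=config.pseudocount,
        resampling_draws=config.resampling_draws, random_state=seed,
        **kwargs)
    est.fit(counts, meta)
    return est.result()


def jaccard(a, b) -> float:
    """Jaccard overlap of two sets; 1.0 when both are empty."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def sensitivity_sweep(counts: CountTable, meta: pd.DataFrame,
                      group_var: str = "group", covariates=None,
                      c_grid=(0.5, 0.75, 1.0),
                      config: SparccConfig | None = None,
                      seed: int | None = None,
                      **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run the pipeline over a grid of trimming proportions.

    Returns a long results frame with a leading ``c`` column and the
    pairwise Jaccard overlap of the DC sets across the grid.  The
    expensive network/pseudo-value stages are computed once and reused:
    c only affects the regression stage.
    """
    c_grid = list(c_grid)
    if not c_grid:
        raise ValueError("c_grid must be non-empty")
    for c in c_grid:
        if not 0.5 <= c <= 1.0:
            raise ValueError(f"trim proportion {c} outside [0.5, 1]")
    config = config or SparccConfig(max_exclusion_rounds=0)
    first = run_dna(counts, meta, group_var, covariates, c=c_grid[0],
                    config=config, seed=seed, **kwargs)
    pv = first.pseudo_values
    design = first.design
    pi0_method = kwargs.get("pi0_method", "auto")
    threshold = kwargs.get("dc_threshold", 0.05)
    blocks, dc_sets = [], {}
    for c in c_grid:
        if c == c_grid[0]:
            res = first.results
        else:
            frame, _ = fit_all_taxa(pv, design, c=c, seed=seed,
                                    n_starts=kwargs.get("n_starts", 500),
                                    se_mode=kwargs.get("se_mode", "jackknife"))
            res, _ = attach_qvalues(frame, pi0_method=pi0_method,
                                    threshold=threshold)
        blocks.append(res.assign(c=c))
        dc_sets[c] = dc_taxa(res, "Z", threshold)
    table = pd.concat(blocks, ignore_index=True)
    overlap = pd.DataFrame(
        [[jaccard(dc_sets[ci], dc_sets[cj]) for cj in c_grid] for ci in c_grid],
        index=c_grid, columns=c_grid,
    )
    return table, overlap


def save_result(result: AnalysisResult, out_dir, float_format="%.10g") -> None:
    """Write results.tsv, pseudovalues.tsv and a config.json snapshot."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.results.to_csv(out / "results.tsv", sep="\t", index=False,
                          float_format=float_format)
    pv = result.pseudo_values
    pd.DataFrame(pv.theta_tilde, index=pv.sample_ids,
                 columns=pv.taxon_ids).to_csv(
        out / "pseudovalues.tsv", sep="\t", index_label="sample_id",
        float_format=float_format)
    snapshot = {k: (v if isinstance(v, (int, float, str, bool, type(None)))
                    else list(v) if isinstance(v, (list, tuple)) else str(v))
                for k, v in result.config.items()}
    snapshot["pi0"] = result.pi0
    snapshot["failures"] = result.failures
    (out / "config.json").write_text(json.dumps(snapshot, indent=2))
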