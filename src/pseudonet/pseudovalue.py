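"""Leave-one-out network re-estimation and Tukey jackknife pseudo-values.

For a group of n_g samples with full-data connectivity theta_hat and
leave-one-out connectivities theta_hat^(-i), the pseudo-value of sample
i for taxon k is

    theta_tilde_ik = n_g * theta_hat_k - (n_g - 1) * theta_hat_k^(-i)

It quantifies the influence of sample i on taxon k's connectivity and
serves as that sample's regression response.  Pseudo-values are computed
per group: each group's network, group size and leave-one-out series are
its own, so the group contrast in the downstream regression captures
between-group connectivity differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .io import CountTable, ValidationError
from .network import ConnectivityVector, connectivity, difference_matrix
from .sparcc import SparccConfig, sparcc


@dataclass
class PseudoValueMatrix:
    """Samples x taxa jackknife pseudo-values (the regression response)."""

    sample_ids: list[str]
    taxon_ids: list[str]
    theta_tilde: np.ndarray = field(repr=False)
    n_a: int = 0
    n_b: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.theta_tilde, dtype=float)
        if v.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError("theta_tilde shape must be n_samples x n_taxa")
        if not np.isfinite(v).all():
            raise ValueError("pseudo-values must be finite")
        self.theta_tilde = v


def _group_connectivity(counts: CountTable, config: SparccConfig,
                        counts_t2: CountTable | None, normalize: bool,
                        drop: int | None = None,
                        masks: tuple | None = None):
    """Connectivity for one group, optionally with sample ``drop`` removed.

    When ``drop is None`` the full-data estimate is computed and the
    final pair-inclusion mask(s) are returned alongside; leave-one-out
    calls may pass those masks back in to solve the basis system under
    the full-data exclusion set instead of re-running the exclusion
    iteration.
    """
    m1, m2 = masks if masks is not None else (None, None)
    c1 = counts if drop is None else counts.drop_sample(drop)
    if counts_t2 is None:
        a1, m1 = sparcc(c1, config, fixed_mask=m1, return_mask=True)
        assoc = a1
    else:
        c2 = counts_t2 if drop is None else counts_t2.drop_sample(drop)
        a2, m2 = sparcc(c2, config, fixed_mask=m2, return_mask=True)
        a1, m1 = sparcc(c1, config, fixed_mask=m1, return_mask=True)
        assoc = difference_matrix(a2, a1)
    vec = connectivity(assoc, normalize=normalize, n_source=c1.n_samples)
    if masks is None:
        return vec, (m1, m2)
    return vec


def loo_connectivities(counts_g: CountTable, config: SparccConfig | None = None,
                       center_mode: str = "single",
                       counts_g_t2: CountTable | None = None,
                       normalize: bool = False,
                       n_jobs: int = 1,
                       freeze_exclusion: bool = False
                       ) -> tuple[ConnectivityVector, list[ConnectivityVector]]:
    """Full-data and leave-one-out connectivities for one group.

    In ``difference`` mode the leave-one-out unit is the subject: row i
    of the baseline and follow-up tables refer to the same subject and
    are removed together, and connectivity is computed on the
    follow-up-minus-baseline difference matrix.

    ``freeze_exclusion=True`` reuses the SparCC pair-exclusion set
    determined on the full group data for every leave-one-out
    re-estimate.  That makes the jackknifed functional smooth, but it
    also hides the exclusion-selection noise from the pseudo-value
    spread while the noise still perturbs the group estimate, which is
    anticonservative; the default re-runs the procedure as configured
    per removal.

    Returns ``(theta_full, [theta^(-0), ..., theta^(-(n_g-1))])``.
    """
    config = config or SparccConfig()
    if center_mode not in ("single", "difference"):
        raise ValueError(f"unknown center_mode {center_mode!r}")
    if center_mode == "difference":
        if counts_g_t2 is None:
            raise ValueError("difference mode needs the follow-up count table")
        if counts_g_t2.n_samples != counts_g.n_samples:
            raise ValidationError(
                "baseline and follow-up tables must pair subjects one-to-one"
            )
        if counts_g_t2.taxon_ids != counts_g.taxon_ids:
            raise ValidationError("baseline and follow-up taxa must match")
        t2 = counts_g_t2
    else:
        t2 = None
    n_g = counts_g.n_samples
    if n_g < 4:
        raise ValidationError(f"need at least 4 samples per group, got {n_g}")

    full, masks = _group_connectivity(counts_g, config, t2, normalize, None)
    if not freeze_exclusion:
        masks = (None, None)

    def one(drop):
        try:
            return _group_connectivity(counts_g, config, t2, normalize,
                                       drop, masks)
        except Exception as exc:
            sid = counts_g.sample_ids[drop] if drop is not None else "<none>"
            raise RuntimeError(
                f"network re-estimation failed with sample {sid!r} removed: {exc}"
            ) from exc

    if n_jobs == 1:
        loo = [one(i) for i in range(n_g)]
    else:
        loo = Parallel(n_jobs=n_jobs)(delayed(one)(i) for i in range(n_g))
    return full, loo


def jackknife_pseudovalues(theta_full: ConnectivityVector,
                           theta_loo: list[ConnectivityVector],
                           n_g: int | None = None) -> np.ndarray:
    """Tukey pseudo-values n_g * theta - (n_g - 1) * theta^(-i), rowwise."""
    if n_g is None:
        n_g = len(theta_loo)
    if len(theta_loo) != n_g:
        raise ValueError(
            f"expected {n_g} leave-one-out vectors, got {len(theta_loo)}"
        )
    if n_g < 2:
        raise ValueError("jackknife needs at least 2 samples")
    full = theta_full.theta_hat
    loo = np.vstack([v.theta_hat for v in theta_loo])
    return n_g * full[None, :] - (n_g - 1) * loo


def _stack(blocks, idx_a, idx_b, n_total) -> np.ndarray:
    pv_a, pv_b = blocks
    out = np.empty((n_total, pv_a.shape[1]))
    out[idx_a] = pv_a
    out[idx_b] = pv_b
    return out


def assemble_pseudovalues(counts: CountTable, idx_a: np.ndarray,
                          idx_b: np.ndarray,
                          config: SparccConfig | None = None,
                          normalize: bool = False,
                          n_jobs: int = 1,
                          freeze_exclusion: bool = False) -> PseudoValueMatrix:
    """Group-wise pseudo-values stacked back into the aligned sample order.

    Each group's full and leave-one-out networks are estimated
    independently from that group's samples only, so pseudo-values in
    one group are invariant to changes confined to the other.
    """
    config = config or SparccConfig()
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    blocks = []
    for idx in (idx_a, idx_b):
        sub = counts.subset_samples([counts.sample_ids[i] for i in idx])
        full, loo = loo_connectivities(sub, config, "single",
                                       normalize=normalize, n_jobs=n_jobs,
                                       freeze_exclusion=freeze_exclusion)
        blocks.append(jackknife_pseudovalues(full, loo, len(idx)))
    theta_tilde = _stack(blocks, idx_a, idx_b, counts.n_samples)
    return PseudoValueMatrix(sample_ids=counts.sample_ids,
                             taxon_ids=counts.taxon_ids,
                             theta_tilde=theta_tilde,
                             n_a=len(idx_a), n_b=len(idx_b))


def assemble_pseudovalues_paired(counts_t1: CountTable, counts_t2: CountTable,
                                 idx_a: np.ndarray, idx_b: np.ndarray,
                                 config: SparccConfig | None = None,
                                 normalize: bool = False,
                                 n_jobs: int = 1,
                                 freeze_exclusion: bool = False) -> PseudoValueMatrix:
    """Two-timepoint pseudo-values from difference networks, per group.

    ``counts_t1`` and ``counts_t2`` are subject-aligned (row i of each is
    the same subject); ``idx_a``/``idx_b`` partition subjects by group.
    Connectivity is computed on the t2 - t1 difference matrix and the
    leave-one-out unit is the subject (both timepoints removed together).
    The returned rows are indexed by the baseline table's sample ids.
    """
    config = config or SparccConfig()
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    blocks = []
    for idx in (idx_a, idx_b):
        ids = [counts_t1.sample_ids[i] for i in idx]
        ids2 = [counts_t2.sample_ids[i] for i in idx]
        sub1 = counts_t1.subset_samples(ids)
        sub2 = counts_t2.subset_samples(ids2)
        full, loo = loo_connectivities(sub1, config, "difference",
                                       counts_g_t2=sub2,
                                       normalize=normalize, n_jobs=n_jobs,
                                       freeze_exclusion=freeze_exclusion)
        blocks.append(jackknife_pseudovalues(full, loo, len(idx)))
    theta_tilde = _stack(blocks, idx_a, idx_b, counts_t1.n_samples)
    return PseudoValueMatrix(sample_ids=counts_t1.sample_ids,
                             taxon_ids=counts_t1.taxon_ids,
                             theta_tilde=theta_tilde,
                             n_a=len(idx_a), n_b=len(idx_b))
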