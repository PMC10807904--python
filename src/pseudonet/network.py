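"""Per-taxon connectivity scores and two-timepoint difference matrices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sparcc import AssociationMatrix


@dataclass
class ConnectivityVector:
    """Per-taxon network connectivity (degree centrality on |a_kj|).

    theta_hat[k] sums the absolute off-diagonal associations of taxon k;
    it is zero exactly when taxon k is unconnected.
    """

    taxon_ids: list[str]
    theta_hat: np.ndarray = field(repr=False)
    n_source: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.theta_hat, dtype=float)
        if v.shape != (len(self.taxon_ids),):
            raise ValueError("theta_hat length must match taxon_ids")
        if (v < 0).any():
            raise ValueError("connectivity scores must be non-negative")
        self.theta_hat = v


def connectivity(assoc: AssociationMatrix, normalize: bool = False,
                 n_source: int = 0) -> ConnectivityVector:
    """Sum of absolute off-diagonal associations per taxon.

    With ``normalize=True`` the sum is divided by (p - 1), turning the
    score into a mean absolute association; this only rescales the
    downstream regression response.
    """
    a = np.abs(assoc.values.copy())
    np.fill_diagonal(a, 0.0)
    theta = a.sum(axis=1)
    if normalize:
        theta = theta / max(assoc.n_taxa - 1, 1)
    return ConnectivityVector(taxon_ids=list(assoc.taxon_ids),
                              theta_hat=theta, n_source=n_source)


def difference_matrix(assoc_t2: AssociationMatrix,
                      assoc_t1: AssociationMatrix) -> AssociationMatrix:
    """Entrywise t2 - t1 difference of two correlation matrices."""
    if assoc_t2.taxon_ids != assoc_t1.taxon_ids:
        extra = set(assoc_t2.taxon_ids) ^ set(assoc_t1.taxon_ids)
        raise ValueError(
            f"taxon mismatch between matrices (symmetric difference: {sorted(extra)})"
        )
    if assoc_t2.kind != "correlation" or assoc_t1.kind != "correlation":
        raise ValueError("difference_matrix expects two correlation matrices")
    d = assoc_t2.values - assoc_t1.values
    np.fill_diagonal(d, 0.0)
    return AssociationMatrix(taxon_ids=list(assoc_t2.taxon_ids), values=d,
                             kind="difference")
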