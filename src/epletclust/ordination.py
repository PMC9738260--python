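"""Correlation-matrix PCA of standardized MFI matrices.

Because the input is centered and scaled per bead, this is PCA on the
sample correlation matrix: eigenvalues sum to the number of beads, and each
bead contributes unit variance.  The quantities exposed are the ones a
biplot renders: individual scores, variable coordinates (eigenvector
columns scaled by the square root of their eigenvalue, i.e. loading
arrows), and cos2 representation qualities for both.

Computation goes through the SVD of the standardized matrix rather than an
explicit eigendecomposition, for numerical stability; eigenvalue k is
(singular value k)^2 / (n - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .panel import StandardizedMatrix

__all__ = ["OrdinationError", "PCAResult", "pca", "variance_explained", "biplot_table"]

_STD_TOL = 1e-6  # tolerance for verifying the input is standardized
_EIG_FLOOR = 1e-12  # eigenvalues below this are reported as exactly 0


class OrdinationError(ValueError):
    pass


@dataclass
class PCAResult:
    """PCA decomposition; components are 1-based in all query helpers."""

    eigenvalues: np.ndarray  # descending, >= 0
    varexp: np.ndarray  # fraction of total variance per component
    scores: pd.DataFrame  # patients x components
    var_coords: pd.DataFrame  # variables x components (loading arrows)
    var_cos2: pd.DataFrame  # variables x components
    ind_cos2: pd.DataFrame  # patients x components

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def _check_dim(self, dim: int) -> None:
        if not 1 <= dim <= self.n_components:
            raise OrdinationError(
                f"component {dim} out of range 1..{self.n_components}"
            )


def pca(m: StandardizedMatrix) -> PCAResult:
    """PCA of a standardized matrix, with min(n-1, p) components.

    The eigenvector sign convention is deterministic: each eigenvector is
    flipped so that its largest-magnitude entry is positive (ties broken by
    the first such entry).
    """
    X = m.data.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise OrdinationError("PCA needs at least 2 patients")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.abs(mean).max() > _STD_TOL or np.abs(sd - 1.0).max() > _STD_TOL:
        raise OrdinationError(
            "input is not standardized (column means 0 / sample SDs 1)"
        )

    ncomp = min(n - 1, p)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = U[:, :ncomp], s[:ncomp], Vt[:ncomp]
    eigenvalues = np.clip(s**2 / (n - 1), 0.0, None)
    zero = eigenvalues < _EIG_FLOOR
    eigenvalues[zero] = 0.0

    # deterministic sign fix: largest-|entry| of each eigenvector positive
    for k in range(ncomp):
        v = Vt[k]
        idx = int(np.argmax(np.abs(v)))
        if v[idx] < 0:
            Vt[k] = -v
            U[:, k] = -U[:, k]

    scores = U * s
    scores[:, zero] = 0.0
    var_coords = Vt.T * np.sqrt(eigenvalues)
    var_coords[:, zero] = 0.0
    var_cos2 = var_coords**2

    row_d2 = (X**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ind_cos2 = np.where(row_d2[:, None] > 0, scores**2 / row_d2[:, None], 0.0)

    total = eigenvalues.sum()
    varexp = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    comp_labels = [f"PC{k + 1}" for k in range(ncomp)]
    patients, beads = m.data.index, m.data.columns
    return PCAResult(
        eigenvalues=eigenvalues,
        varexp=varexp,
        scores=pd.DataFrame(scores, index=patients, columns=comp_labels),
        var_coords=pd.DataFrame(var_coords, index=beads, columns=comp_labels),
        var_cos2=pd.DataFrame(var_cos2, index=beads, columns=comp_labels),
        ind_cos2=pd.DataFrame(ind_cos2, index=patients, columns=comp_labels),
    )


def variance_explained(r: PCAResult, dims: Iterable[int]) -> float:
    """Fraction of total variance carried by the given (1-based) components."""
    dims = list(dims)
    for d in dims:
        r._check_dim(d)
    if len(set(dims)) != len(dims):
        raise OrdinationError("duplicate component indices")
    return float(sum(r.varexp[d - 1] for d in dims))


def biplot_table(r: PCAResult, dim_i: int, dim_j: int) -> pd.DataFrame:
    """Tabulate biplot coordinates for two components.

    Variables carry their loading-arrow coordinates and summed cos2 over the
    two components; individuals carry their score coordinates and summed
    cos2.  The table is what the figures plot, ready for CSV export.
    """
    r._check_dim(dim_i)
    r._check_dim(dim_j)
    if dim_i == dim_j:
        raise OrdinationError("biplot components must differ")
    ci, cj = f"PC{dim_i}", f"PC{dim_j}"
    rows = []
    for label in r.var_coords.index:
        rows.append(
            {
                "label": label,
                "kind": "variable",
                "x": r.var_coords.at[label, ci],
                "y": r.var_coords.at[label, cj],
                "cos2_sum": r.var_cos2.at[label, ci] + r.var_cos2.at[label, cj],
            }
        )
    for label in r.scores.index:
        rows.append(
            {
                "label": label,
                "kind": "individual",
                "x": r.scores.at[label, ci],
                "y": r.scores.at[label, cj],
                "cos2_sum": r.ind_cos2.at[label, ci] + r.ind_cos2.at[label, cj],
            }
        )
    return pd.DataFrame(rows, columns=["label", "kind", "x", "y", "cos2_sum"])


def pca_summary(r: PCAResult) -> pd.DataFrame:
    """Scree-style summary: eigenvalue, variance fraction and cumulative."""
    return pd.DataFrame(
        {
            "component": np.arange(1, r.n_components + 1),
            "eigenvalue": r.eigenvalues,
            "varexp": r.varexp,
            "cumulative": np.cumsum(r.varexp),
        }
    )
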