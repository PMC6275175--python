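"""Principal component analysis of community matrices.

A thin, fully determined PCA on a samples x variables matrix (relative
abundance, excess 13C or %litter per biomarker): column-centered singular
value decomposition, axes ordered by decreasing variance, and a fixed sign
convention (the largest-magnitude loading on each axis is positive) so runs
are reproducible to the byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

MODES = ("relative_abundance", "excess_13c", "pct_litter")


@dataclass(frozen=True)
class OrdinationResult:
    """Scores, loadings and per-axis variance shares of one PCA."""

    scores: pd.DataFrame        # samples x axes
    loadings: pd.DataFrame      # variables x axes, orthonormal columns
    variance_explained_pct: np.ndarray  # sums to 100 over all axes
    column_means: np.ndarray
    column_scales: np.ndarray

    @property
    def axes(self) -> list[str]:
        return list(self.scores.columns)

    def reconstruct(self) -> np.ndarray:
        """Recover the input matrix exactly when all axes are retained."""
        return (
            self.scores.to_numpy() @ self.loadings.to_numpy().T * self.column_scales
            + self.column_means
        )


def ordinate(matrix: pd.DataFrame, scale: str = "covariance") -> OrdinationResult:
    """PCA of a samples x variables data frame.

    ``scale='covariance'`` (default) centers columns; ``'correlation'``
    additionally divides by the column standard deviation (constant columns
    are rejected in that mode).  Missing cells are an error: imputation is a
    decision for the caller, never silent.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise SchemaError("ordination needs at least 2 samples and 2 variables")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        bad = matrix.columns[np.isnan(X).any(axis=0)].tolist()
        raise SchemaError(
            f"missing values in columns {bad}: filter or impute before ordination"
        )
    means = X.mean(axis=0)
    Xc = X - means
    scales = np.ones(X.shape[1])
    if scale == "correlation":
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = matrix.columns[sd == 0].tolist()
            raise SchemaError(f"constant columns cannot be correlation-scaled: {bad}")
        Xc = Xc / sd
        scales = sd
    elif scale != "covariance":
        raise SchemaError(f"unknown scale {scale!r}")

    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|loading| entry positive on every axis
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    var = s**2
    total = var.sum()
    explained = 100.0 * var / total if total > 0 else np.zeros_like(var)
    axes = [f"PC{k + 1}" for k in range(len(s))]
    scores = pd.DataFrame(u * s, index=matrix.index, columns=axes)
    loadings = pd.DataFrame(vt.T, index=matrix.columns, columns=axes)
    return OrdinationResult(scores, loadings, explained, means, scales)
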