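"""PCA dimensionality reduction with selection by cumulative contribution.

The fit is computed through an SVD of the centred data matrix for numerical
stability; eigenvalues are those of the sample covariance (1/(n-1) scaling).
Each loading's sign is fixed so its largest-magnitude entry is positive,
which makes fits reproducible without affecting the spanned subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraMatrix

__all__ = ["PCAModel", "pca_fit", "pca_transform", "select_k_by_contribution"]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectraMatrix):
        return X.values
    return np.atleast_2d(np.asarray(X, dtype=float))


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-magnitude entry of each is positive."""
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


@dataclass
class PCAModel:
    """Fitted PCA: training mean, orthonormal loadings, descending eigenvalues."""

    mean: np.ndarray          # (d,)
    loadings: np.ndarray      # (d, k), orthonormal columns
    eigenvalues: np.ndarray   # (k,), descending, >= 0

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def pca_fit(X, k: int) -> PCAModel:
    """Fit a ``k``-component PCA on the rows of ``X``.

    ``k`` must satisfy ``1 <= k <= min(n - 1, d)``; the upper bound is the
    maximal rank of the sample covariance.
    """
    A = _as_matrix(X)
    n, d = A.shape
    kmax = min(n - 1, d)
    if not 1 <= k <= kmax:
        raise ValueError(f"k must be in [1, {kmax}] for data of shape {(n, d)}, got {k}")
    mean = A.mean(axis=0)
    _, s, Vt = np.linalg.svd(A - mean, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    loadings = _fix_signs(Vt[:k].T)
    return PCAModel(mean=mean, loadings=loadings, eigenvalues=eigenvalues[:k])


def pca_transform(model: PCAModel, X) -> np.ndarray:
    """Project rows of ``X`` onto the fitted components: ``(X - mean) @ loadings``."""
    A = _as_matrix(X)
    if A.shape[1] != model.mean.size:
        raise ValueError(
            f"data has {A.shape[1]} columns, model expects {model.mean.size}"
        )
    return (A - model.mean) @ model.loadings


def full_eigenvalues(X) -> np.ndarray:
    """All sample-covariance eigenvalues of ``X`` (descending), for k-selection."""
    A = _as_matrix(X)
    n = A.shape[0]
    s = np.linalg.svd(A - A.mean(axis=0), compute_uv=False)
    return s**2 / (n - 1)


def select_k_by_contribution(eigenvalues, threshold: float) -> int:
    """Smallest ``k`` whose leading eigenvalues reach the contribution threshold.

    Returns the smallest ``k`` with ``sum(ev[:k]) / sum(ev) >= threshold``;
    eigenvalues must be nonnegative and sorted descending.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.ndim != 1 or ev.size == 0:
        raise ValueError("eigenvalues must be a nonempty 1-D array")
    if np.any(ev < 0):
        raise ValueError("eigenvalues must be >= 0")
    if np.any(np.diff(ev) > 0):
        raise ValueError("eigenvalues must be sorted descending")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    total = ev.sum()
    if total == 0:
        raise ValueError("all eigenvalues are zero; contribution undefined")
    ratios = np.cumsum(ev) / total
    return int(np.argmax(ratios >= threshold - 1e-15)) + 1
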