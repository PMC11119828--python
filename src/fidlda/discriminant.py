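"""Discriminant feature extractors: LDA, direct-LDA variant, and its fuzzy form.

The classical within/between/total scatter matrices are

    St = sum_i (x_i - xbar)(x_i - xbar)^T
    Sb = sum_j n_j (xbar_j - xbar)(xbar_j - xbar)^T
    Sw = sum_j sum_{i in class j} (x_i - xbar_j)(x_i - xbar_j)^T

so that St = Sb + Sw.  Classical LDA maximises the generalized Rayleigh
quotient and needs Sw invertible, which is why it runs after PCA here.

The improved direct variant (IDLDA) avoids inverting Sw.  It
eigendecomposes Sw = Uw Dw^2 Uw^T, builds the reweighting
D = max(Dw) I - Dw (directions of LOW within-class scatter get the LARGEST
weight, and the single worst direction is annihilated rather than the whole
null space being discarded), diagonalizes D Uw^T Sb Uw D = F S^2 F^T, and
keeps the range-space columns Fr: W = Uw D Fr.

The fuzzy form (FIDLDA) runs the identical chain on fuzzy scatter matrices
in which sample i contributes to every class j with weight u_ij^m, where the
membership u_ij is the fuzzy-c-means formula with centers fixed at the crisp
class means:

    u_ij = [ sum_k ( ||x_i - v_j|| / ||x_i - v_k|| )^(2/(m-1)) ]^(-1)

With crisp (0/1) memberships the fuzzy scatter matrices reduce exactly to
the crisp ones, so FIDLDA degenerates to IDLDA -- the key structural
relationship, and one of the package's acceptance properties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "ScatterSet", "FuzzyMembershipMatrix", "DiscriminantModel",
    "scatter_matrices", "fuzzy_memberships", "fuzzy_scatter_matrices",
    "lda_fit", "idlda_fit", "fidlda_fit", "transform", "class_means",
]

#: Relative eigenvalue tolerance for the range/null split of Sb.
RANK_TOL = 1e-10


@dataclass
class ScatterSet:
    """Total, between-class and within-class scatter matrices."""

    total: np.ndarray
    between: np.ndarray
    within: np.ndarray
    fuzzy: bool = False


@dataclass
class FuzzyMembershipMatrix:
    """Fuzzy-c-means memberships with fixed centers.

    ``U[i, j]`` is the degree to which sample ``i`` belongs to class ``j``;
    each row is nonnegative and sums to 1.
    """

    U: np.ndarray          # (n, c)
    m: float               # fuzzy weight index, > 1
    centers: np.ndarray    # (c, d)


@dataclass
class DiscriminantModel:
    """A fitted linear discriminant projection.

    ``W`` has one column per retained discriminant vector (at most c - 1);
    features are computed as ``X @ W`` with no re-centering, because the
    PCA stage upstream already centres the scores.
    """

    method: str                 # 'lda' | 'idlda' | 'fidlda'
    W: np.ndarray               # (d, r)
    eigenvalues: np.ndarray     # (r,), descending
    train_mean: np.ndarray      # (d,)
    class_means: np.ndarray     # (c, d)
    classes: np.ndarray         # (c,)
    m: float | None = None
    memberships: FuzzyMembershipMatrix | None = field(default=None, repr=False)

    @property
    def r(self) -> int:
        return self.W.shape[1]


def _check_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).ravel()
    if y.size != X.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} labels")
    return X, y


def class_means(X, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (classes, class means, class counts); every class must be nonempty."""
    X, y = _check_xy(X, y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    means = np.stack([X[y == cls].mean(axis=0) for cls in classes])
    return classes, means, counts


def scatter_matrices(X, y) -> ScatterSet:
    """Crisp total/between/within scatter matrices of labelled data."""
    X, y = _check_xy(X, y)
    classes, means, counts = class_means(X, y)
    xbar = X.mean(axis=0)
    Xc = X - xbar
    St = Xc.T @ Xc
    Mc = means - xbar
    Sb = (Mc * counts[:, None]).T @ Mc
    Sw = np.zeros_like(St)
    for cls, mu in zip(classes, means):
        D = X[y == cls] - mu
        Sw += D.T @ D
    return ScatterSet(total=St, between=Sb, within=Sw, fuzzy=False)


def fuzzy_memberships(X, centers, m: float, n_iter: int = 0) -> FuzzyMembershipMatrix:
    """Fuzzy-c-means memberships of rows of ``X`` to fixed ``centers``.

    By default the centers stay fixed (at the crisp class means, when called
    from the fuzzy discriminant fit).  ``n_iter`` > 0 additionally runs that
    many fuzzy-c-means update rounds (centers from u^m-weighted means, then
    memberships recomputed), for experimentation; the returned ``centers``
    are the final ones.

    A sample coinciding with one or more centers gets a crisp row split
    uniformly among the coincident centers (the limit of the formula).
    """
    if m <= 1:
        raise ValueError(f"fuzzy weight index m must be > 1, got {m}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] < 2:
        raise ValueError("need at least 2 centers")
    if centers.shape[1] != X.shape[1]:
        raise ValueError(
            f"centers have {centers.shape[1]} columns, data has {X.shape[1]}"
        )
    cdist = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    iu = np.triu_indices(centers.shape[0], k=1)
    if np.any(cdist[iu] == 0):
        raise ValueError("duplicate cluster centers")

    U = _membership_rows(X, centers, m)
    for _ in range(n_iter):
        W = U ** m
        centers = (W.T @ X) / W.sum(axis=0)[:, None]
        U = _membership_rows(X, centers, m)
    return FuzzyMembershipMatrix(U=U, m=float(m), centers=centers)


def _membership_rows(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    dist = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)  # (n, c)
    p = 2.0 / (m - 1.0)
    U = np.zeros_like(dist)
    zero_rows = np.any(dist == 0, axis=1)
    if np.any(~zero_rows):
        d = dist[~zero_rows]
        # w_j = (d_min / d_j)^p in (0, 1]; normalizing gives u without overflow
        w = (d.min(axis=1, keepdims=True) / d) ** p
        U[~zero_rows] = w / w.sum(axis=1, keepdims=True)
    for i in np.flatnonzero(zero_rows):
        hits = dist[i] == 0
        U[i, hits] = 1.0 / hits.sum()
    return U


def fuzzy_scatter_matrices(X, y, memberships: FuzzyMembershipMatrix) -> ScatterSet:
    """Fuzzy scatter matrices with per-sample, per-class weights ``u_ij^m``.

    The grand mean and the class means are computed crisply from ``(X, y)``;
    only the contribution weights are fuzzy.
    """
    X, y = _check_xy(X, y)
    classes, means, _ = class_means(X, y)
    U = np.asarray(memberships.U, dtype=float)
    if U.shape != (X.shape[0], classes.size):
        raise ValueError(
            f"membership matrix has shape {U.shape}, expected {(X.shape[0], classes.size)}"
        )
    W = U ** memberships.m
    xbar = X.mean(axis=0)
    d = X.shape[1]
    Sft = np.zeros((d, d))
    Sfb = np.zeros((d, d))
    Sfw = np.zeros((d, d))
    Xt = X - xbar
    for j, mu in enumerate(means):
        wj = W[:, j]
        Sft += (Xt * wj[:, None]).T @ Xt
        db = mu - xbar
        Sfb += wj.sum() * np.outer(db, db)
        Xw = X - mu
        Sfw += (Xw * wj[:, None]).T @ Xw
    return ScatterSet(total=Sft, between=Sfb, within=Sfw, fuzzy=True)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def lda_fit(X, y, r: int | None = None, ridge: float = 0.0) -> DiscriminantModel:
    """Classical LDA: top eigenvectors of the generalized problem Sb w = l Sw w.

    ``Sw`` must be invertible; run PCA first on high-dimensional spectra or
    pass ``ridge`` > 0 to add ``ridge * trace(Sw)/d * I``.
    """
    X, y = _check_xy(X, y)
    classes, means, _ = class_means(X, y)
    sc = scatter_matrices(X, y)
    Sw = sc.within
    if ridge > 0:
        Sw = Sw + ridge * np.trace(Sw) / Sw.shape[0] * np.eye(Sw.shape[0])
    try:
        evals, evecs = scipy.linalg.eigh(sc.between, Sw)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "within-class scatter matrix is singular; reduce dimensionality "
            "with PCA first or pass ridge > 0"
        ) from exc
    order = np.argsort(evals, kind="stable")[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank_b = int(np.sum(evals > max(evals.max(), 0) * RANK_TOL)) if evals.max() > 0 else 0
    if rank_b == 0:
        raise ValueError("between-class scatter matrix has rank 0")
    max_r = min(rank_b, classes.size - 1)
    if r is None:
        r = max_r
    if not 1 <= r <= max_r:
        raise ValueError(f"r must be in [1, {max_r}], got {r}")
    W = evecs[:, :r]
    # unit-norm columns: the standard normalization of eigenvectors of Sw^-1 Sb
    W = _fix_signs(W / np.linalg.norm(W, axis=0))
    return DiscriminantModel(method="lda", W=W, eigenvalues=evals[:r],
                             train_mean=X.mean(axis=0), class_means=means,
                             classes=classes)


def _direct_lda(Sb: np.ndarray, Sw: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    """Shared chain of the direct-LDA variants.

    Eigendecompose Sw = Uw Dw^2 Uw^T, weight directions by
    D = max(Dw) I - Dw, diagonalize D Uw^T Sb Uw D, and keep the
    range-space columns.  Returns (W, eigenvalues), eigenvalues descending.
    """
    w_evals, Uw = np.linalg.eigh(Sw)
    Dw = np.sqrt(np.clip(w_evals, 0.0, None))
    delta = Dw.max()
    Ddelta = delta - Dw  # diagonal of the reweighting matrix
    if delta == 0 or np.all(Ddelta <= delta * 1e-12):
        raise ValueError(
            "within-class scatter is spherical: the reweighting max(Dw) I - Dw "
            "vanishes in every direction and the projection is degenerate"
        )
    M = (Ddelta[:, None] * (Uw.T @ Sb @ Uw)) * Ddelta[None, :]
    M = (M + M.T) / 2.0
    sig2, F = np.linalg.eigh(M)
    order = np.argsort(sig2, kind="stable")[::-1]
    sig2, F = sig2[order], F[:, order]
    if sig2[0] <= 0:
        raise ValueError("between-class scatter has rank 0 after reweighting")
    r = int(np.sum(sig2 > sig2[0] * RANK_TOL))
    r = min(r, c - 1)
    W = Uw @ (Ddelta[:, None] * F[:, :r])
    return _fix_signs(W), sig2[:r]


def idlda_fit(X, y) -> DiscriminantModel:
    """Improved direct LDA on crisp scatter matrices."""
    X, y = _check_xy(X, y)
    classes, means, _ = class_means(X, y)
    sc = scatter_matrices(X, y)
    W, evals = _direct_lda(sc.between, sc.within, classes.size)
    return DiscriminantModel(method="idlda", W=W, eigenvalues=evals,
                             train_mean=X.mean(axis=0), class_means=means,
                             classes=classes)


def fidlda_fit(X, y, m: float = 1.6,
               memberships: FuzzyMembershipMatrix | None = None) -> DiscriminantModel:
    """Fuzzy improved direct LDA.

    Memberships default to the fuzzy-c-means formula with centers fixed at
    the crisp class means; pass ``memberships`` to override (e.g. with crisp
    indicators, which reproduces :func:`idlda_fit` exactly, or with
    FCM-iterated memberships).
    """
    X, y = _check_xy(X, y)
    classes, means, _ = class_means(X, y)
    if memberships is None:
        memberships = fuzzy_memberships(X, means, m)
    sc = fuzzy_scatter_matrices(X, y, memberships)
    W, evals = _direct_lda(sc.between, sc.within, classes.size)
    return DiscriminantModel(method="fidlda", W=W, eigenvalues=evals,
                             train_mean=X.mean(axis=0), class_means=means,
                             classes=classes, m=memberships.m,
                             memberships=memberships)


def transform(model: DiscriminantModel, X) -> np.ndarray:
    """Project rows of ``X`` into the discriminant space: ``X @ W``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"data has {X.shape[1]} columns, model expects {model.W.shape[0]}"
        )
    return X @ model.W
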