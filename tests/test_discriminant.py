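"""Scatter matrices, fuzzy memberships and the three discriminant extractors.

The oracles here are deliberately independent of the library code paths:
per-sample Python loops for the scatter sums, elementwise evaluation of the
membership formula, and an explicit dense matrix chain for the direct-LDA
variants.
"""

import numpy as np
import pytest
import scipy.linalg

from conftest import random_labeled_instance
from fidlda.discriminant import (
    FuzzyMembershipMatrix, class_means, fidlda_fit, fuzzy_memberships,
    fuzzy_scatter_matrices, idlda_fit, lda_fit, scatter_matrices, transform,
)


# ---------------------------------------------------------------- oracles

def loop_scatter(X, y):
    """Per-sample loop over the classical scatter definitions."""
    classes = np.unique(y)
    xbar = X.mean(axis=0)
    St = sum(np.outer(x - xbar, x - xbar) for x in X)
    Sb = np.zeros_like(St)
    Sw = np.zeros_like(St)
    for cls in classes:
        rows = X[y == cls]
        mu = rows.mean(axis=0)
        Sb += len(rows) * np.outer(mu - xbar, mu - xbar)
        for x in rows:
            Sw += np.outer(x - mu, x - mu)
    return St, Sb, Sw


def loop_fuzzy_scatter(X, y, U, m):
    """Per-sample, per-class loop over the fuzzy scatter definitions."""
    classes = np.unique(y)
    xbar = X.mean(axis=0)
    means = {cls: X[y == cls].mean(axis=0) for cls in classes}
    d = X.shape[1]
    Sft = np.zeros((d, d)); Sfb = np.zeros((d, d)); Sfw = np.zeros((d, d))
    for j, cls in enumerate(classes):
        for i, x in enumerate(X):
            w = U[i, j] ** m
            Sft += w * np.outer(x - xbar, x - xbar)
            Sfb += w * np.outer(means[cls] - xbar, means[cls] - xbar)
            Sfw += w * np.outer(x - means[cls], x - means[cls])
    return Sft, Sfb, Sfw


def membership_oracle(X, centers, m):
    """Direct elementwise evaluation of the fuzzy-c-means formula."""
    n, c = X.shape[0], centers.shape[0]
    U = np.zeros((n, c))
    for i in range(n):
        d = [np.linalg.norm(X[i] - centers[k]) for k in range(c)]
        for j in range(c):
            U[i, j] = 1.0 / sum((d[j] / d[k]) ** (2 / (m - 1)) for k in range(c))
    return U


def direct_lda_oracle(Sb, Sw):
    """Explicit dense-matrix chain of the direct-LDA construction."""
    w2, Uw = np.linalg.eigh(Sw)
    Dw = np.diag(np.sqrt(np.clip(w2, 0, None)))
    delta = Dw.max()
    Dd = delta * np.eye(Sw.shape[0]) - Dw
    M = Dd @ Uw.T @ Sb @ Uw @ Dd
    s2, F = np.linalg.eigh((M + M.T) / 2)
    order = np.argsort(s2)[::-1]
    s2, F = s2[order], F[:, order]
    r = int(np.sum(s2 > s2[0] * 1e-10))
    return Uw @ Dd @ F[:, :r], s2[:r]


def align_signs(A, B):
    """Flip columns of B to the sign that best matches A."""
    flips = np.where(np.sum(A * B, axis=0) < 0, -1.0, 1.0)
    return B * flips


# ------------------------------------------------------- crisp scatter

class TestScatterMatrices:
    def test_coincident_class_means_give_zero_between(self, rng):
        blob = rng.normal(size=(6, 3))
        X = np.vstack([blob, blob])
        y = np.repeat([0, 1], 6)
        sc = scatter_matrices(X, y)
        assert np.allclose(sc.between, 0.0, atol=1e-10)
        assert np.allclose(sc.within, sc.total, atol=1e-8)

    def test_conservation_identity(self, rng):
        for _ in range(20):
            X, y = random_labeled_instance(rng, n_per_class=4, d=5, c=3)
            sc = scatter_matrices(X, y)
            assert np.allclose(sc.total, sc.between + sc.within, atol=1e-8)

    def test_matches_loop_oracle(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        sc = scatter_matrices(X, y)
        St, Sb, Sw = loop_scatter(X, y)
        assert np.allclose(sc.total, St, atol=1e-10)
        assert np.allclose(sc.between, Sb, atol=1e-10)
        assert np.allclose(sc.within, Sw, atol=1e-10)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            scatter_matrices(rng.normal(size=(5, 2)), np.zeros(5))


# ------------------------------------------------------- memberships

class TestFuzzyMemberships:
    def test_sample_at_center_is_crisp(self, rng):
        centers = rng.normal(size=(3, 2))
        fm = fuzzy_memberships(centers[1][None, :], centers, m=1.6)
        assert np.allclose(fm.U[0], [0.0, 1.0, 0.0])

    def test_equidistant_sample_uniform(self):
        centers = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        fm = fuzzy_memberships(np.zeros((1, 2)), centers, m=2.0)
        assert np.allclose(fm.U[0], 0.25, atol=1e-12)

    def test_matches_formula_oracle(self, rng):
        X = rng.normal(size=(12, 2))
        centers = rng.normal(size=(3, 2)) * 3
        fm = fuzzy_memberships(X, centers, m=1.6)
        assert np.allclose(fm.U, membership_oracle(X, centers, 1.6), atol=1e-12)
        assert np.allclose(fm.U.sum(axis=1), 1.0, atol=1e-10)

    def test_invariant_under_rotation_and_translation(self, rng):
        X = rng.normal(size=(10, 3))
        centers = rng.normal(size=(4, 3)) * 2
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shift = rng.normal(size=3)
        a = fuzzy_memberships(X, centers, m=1.8).U
        b = fuzzy_memberships(X @ Q + shift, centers @ Q + shift, m=1.8).U
        assert np.allclose(a, b, atol=1e-9)

    def test_fcm_iteration_moves_centers(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=10, d=2, c=3)
        centers = class_means(X, y)[1]
        fm0 = fuzzy_memberships(X, centers, m=2.0)
        fm5 = fuzzy_memberships(X, centers, m=2.0, n_iter=5)
        assert not np.allclose(fm0.centers, fm5.centers)
        assert np.allclose(fm5.U.sum(axis=1), 1.0, atol=1e-10)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        centers = rng.normal(size=(2, 2))
        with pytest.raises(ValueError, match="m"):
            fuzzy_memberships(X, centers, m=1.0)
        dup = np.vstack([centers[0], centers[0]])
        with pytest.raises(ValueError, match="duplicate"):
            fuzzy_memberships(X, dup, m=1.6)


# ------------------------------------------------------- fuzzy scatter

class TestFuzzyScatter:
    def test_crisp_memberships_reduce_to_crisp_scatter(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=5, d=4, c=3)
        U = np.eye(3)[y]
        fm = FuzzyMembershipMatrix(U=U, m=1.6, centers=class_means(X, y)[1])
        fsc = fuzzy_scatter_matrices(X, y, fm)
        sc = scatter_matrices(X, y)
        assert np.allclose(fsc.between, sc.between, atol=1e-10)
        assert np.allclose(fsc.within, sc.within, atol=1e-10)

    def test_uniform_memberships_match_loop(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=4, d=3, c=3)
        U = np.full((12, 3), 1 / 3)
        fm = FuzzyMembershipMatrix(U=U, m=1.0, centers=class_means(X, y)[1])
        fsc = fuzzy_scatter_matrices(X, y, fm)
        Sft, Sfb, Sfw = loop_fuzzy_scatter(X, y, U, 1.0)
        assert np.allclose(fsc.total, Sft, atol=1e-10)
        assert np.allclose(fsc.between, Sfb, atol=1e-10)
        assert np.allclose(fsc.within, Sfw, atol=1e-10)

    def test_random_memberships_match_loop(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=5, d=3, c=2)
        U = rng.uniform(size=(10, 2))
        U /= U.sum(axis=1, keepdims=True)
        fm = FuzzyMembershipMatrix(U=U, m=1.6, centers=class_means(X, y)[1])
        fsc = fuzzy_scatter_matrices(X, y, fm)
        Sft, Sfb, Sfw = loop_fuzzy_scatter(X, y, U, 1.6)
        assert np.allclose(fsc.total, Sft, atol=1e-10)
        assert np.allclose(fsc.between, Sfb, atol=1e-10)
        assert np.allclose(fsc.within, Sfw, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=4, d=3, c=2)
        fm = FuzzyMembershipMatrix(U=np.full((8, 3), 1 / 3), m=1.6,
                                   centers=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            fuzzy_scatter_matrices(X, y, fm)


# ------------------------------------------------------- LDA

class TestLDA:
    def test_two_isotropic_classes_direction(self, rng):
        mu = np.array([4.0, 2.0])
        X = np.vstack([rng.normal(size=(200, 2)), mu + rng.normal(size=(200, 2))])
        y = np.repeat([0, 1], 200)
        model = lda_fit(X, y)
        w = model.W[:, 0]
        cos = abs(w @ mu) / np.linalg.norm(w) / np.linalg.norm(mu)
        assert cos > 0.99

    def test_five_classes_in_six_dims_give_four_vectors(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=10, d=6, c=5)
        model = lda_fit(X, y)
        assert model.W.shape == (6, 4)
        assert model.eigenvalues.shape == (4,)

    def test_matches_generalized_eigenproblem_oracle(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=8, d=4, c=3)
        model = lda_fit(X, y)
        from fidlda.discriminant import scatter_matrices as sm
        sc = sm(X, y)
        evals = scipy.linalg.eigh(sc.between, sc.within, eigvals_only=True)[::-1]
        assert np.allclose(model.eigenvalues, evals[:2], atol=1e-8)
        # each retained column solves Sb w = lambda Sw w
        for lam, w in zip(model.eigenvalues, model.W.T):
            assert np.allclose(sc.between @ w, lam * sc.within @ w, atol=1e-8)

    def test_singular_within_scatter_advises(self):
        # 3 samples in 4-D: Sw cannot be invertible
        X = np.array([[1.0, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0]])
        y = np.array([0, 0, 1])
        with pytest.raises(ValueError, match="PCA|ridge"):
            lda_fit(X, y)


# ------------------------------------------------------- IDLDA / FIDLDA

class TestDirectLDA:
    def hand_instance(self):
        """Within scatter exactly diag(4, 1); class means (0,0) and (3,1)."""
        s2 = np.sqrt(2.0)
        s05 = np.sqrt(0.5)
        X = np.array([[s2, 0.0], [-s2, 0.0], [3.0, 1.0 + s05], [3.0, 1.0 - s05]])
        y = np.array([0, 0, 1, 1])
        return X, y

    def test_hand_built_two_dim_instance(self):
        X, y = self.hand_instance()
        sc = scatter_matrices(X, y)
        assert np.allclose(sc.within, np.diag([4.0, 1.0]), atol=1e-12)
        model = idlda_fit(X, y)
        # the axis of largest within-scatter is annihilated: W ∝ (0, 1)
        assert model.W.shape == (2, 1)
        assert np.allclose(model.W[:, 0], [0.0, 1.0], atol=1e-10)
        # explicit chain oracle agrees
        Wo, s2o = direct_lda_oracle(sc.between, sc.within)
        assert np.allclose(align_signs(model.W, Wo), model.W, atol=1e-8)
        assert np.allclose(model.eigenvalues, s2o, atol=1e-8)

    def test_idlda_matches_matrix_chain_oracle(self, rng):
        for _ in range(10):
            c = int(rng.integers(2, 6))
            d = int(rng.integers(c, 9))
            X, y = random_labeled_instance(rng, n_per_class=5, d=d, c=c)
            model = idlda_fit(X, y)
            sc = scatter_matrices(X, y)
            Wo, s2o = direct_lda_oracle(sc.between, sc.within)
            r = min(Wo.shape[1], c - 1)
            assert model.W.shape[1] == r
            assert np.allclose(model.eigenvalues, s2o[:r], atol=1e-8 * max(1, s2o[0]))
            assert np.allclose(align_signs(model.W, Wo[:, :r]), model.W, atol=1e-7)

    def test_diagonalization_contract(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=6, d=6, c=4)
        for fit in (idlda_fit, lambda X, y: fidlda_fit(X, y, m=1.6)):
            model = fit(X, y)
            if model.method == "fidlda":
                Sb = fuzzy_scatter_matrices(X, y, model.memberships).between
            else:
                Sb = scatter_matrices(X, y).between
            P = model.W.T @ Sb @ model.W
            off = P - np.diag(np.diag(P))
            assert np.max(np.abs(off)) < 1e-8 * max(1.0, np.max(np.diag(P)))
            diag = np.diag(P)
            assert np.all(diag > 0)
            assert np.all(np.diff(diag) <= 1e-8 * diag[0])
            assert np.allclose(diag, model.eigenvalues, rtol=1e-8)

    def test_five_classes_six_dims_four_vectors(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=10, d=6, c=5)
        assert idlda_fit(X, y).r == 4
        assert fidlda_fit(X, y, m=1.6).r == 4

    def test_fidlda_with_crisp_memberships_equals_idlda(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=6, d=5, c=3)
        U = np.eye(3)[y]
        fm = FuzzyMembershipMatrix(U=U, m=1.6, centers=class_means(X, y)[1])
        a = idlda_fit(X, y)
        b = fidlda_fit(X, y, memberships=fm)
        assert np.max(np.abs(a.W - align_signs(a.W, b.W))) < 1e-8

    def test_fidlda_matches_matrix_chain_oracle(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=6, d=4, c=3)
        model = fidlda_fit(X, y, m=1.6)
        fsc = fuzzy_scatter_matrices(X, y, model.memberships)
        Wo, s2o = direct_lda_oracle(fsc.between, fsc.within)
        r = model.r
        assert np.allclose(model.eigenvalues, s2o[:r], atol=1e-8 * max(1, s2o[0]))
        assert np.allclose(align_signs(model.W, Wo[:, :r]), model.W, atol=1e-7)

    def test_spherical_within_scatter_rejected(self):
        # two classes whose pooled within-scatter is exactly isotropic
        a = np.array([[1.0, 0.0], [-1.0, 0.0]])
        b = np.array([[5.0, 1.0], [5.0, -1.0]])
        X = np.vstack([a, b])
        y = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="spherical|degenerate"):
            idlda_fit(X, y)

    def test_transform_is_matrix_product(self, rng):
        X, y = random_labeled_instance(rng, n_per_class=6, d=5, c=3)
        model = idlda_fit(X, y)
        Q = rng.normal(size=(7, 5))
        assert np.allclose(transform(model, Q), Q @ model.W, atol=1e-12)
        assert np.allclose(transform(model, np.zeros((2, 5))), 0.0)
        with pytest.raises(ValueError):
            transform(model, rng.normal(size=(3, 4)))
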