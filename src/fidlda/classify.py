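"""KNN classification, stratified holdout splitting, and experiment grids.

The KNN here is deliberately hand-specified rather than delegated, because
its tie-breaking is part of the package contract and must be deterministic:

* distance ties at the K-th neighbour: stable sort by (distance, training
  index);
* vote ties: among the tied classes, the one whose nearest member (within
  the K neighbours) is closest to the query wins; residual ties go to the
  smallest class label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import decomposition, discriminant

__all__ = [
    "SplitSpec", "stratified_split", "KNNModel", "knn_fit", "knn_predict",
    "accuracy", "evaluate_method", "k_grid", "m_grid", "split_experiment",
    "DEFAULT_K_GRID", "DEFAULT_M_GRID",
]

DEFAULT_K_GRID = (1, 3, 5, 7, 9, 11, 13)
DEFAULT_M_GRID = tuple(np.round(np.arange(1.2, 5.0 + 1e-9, 0.2), 1))


@dataclass(frozen=True)
class SplitSpec:
    """Stratified holdout specification: samples per class in training, and a seed."""

    n_train_per_class: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train_per_class < 1:
            raise ValueError("n_train_per_class must be >= 1")


def stratified_split(y, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class split of sample indices into (train_idx, test_idx).

    Exactly ``spec.n_train_per_class`` indices per class go to training,
    drawn without replacement by one seeded shuffle per class (classes are
    visited in sorted label order, consuming a single random stream, so the
    split is deterministic for a fixed seed).
    """
    y = np.asarray(y).ravel()
    rng = np.random.default_rng(spec.seed)
    train_parts, test_parts = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size <= spec.n_train_per_class:
            raise ValueError(
                f"class {cls} has {idx.size} samples; needs more than "
                f"{spec.n_train_per_class} to leave a test remainder"
            )
        perm = rng.permutation(idx.size)
        train_parts.append(idx[perm[: spec.n_train_per_class]])
        test_parts.append(idx[perm[spec.n_train_per_class:]])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


@dataclass
class KNNModel:
    """Stored training features/labels plus the neighbourhood size K."""

    train_features: np.ndarray
    train_labels: np.ndarray
    K: int


def knn_fit(features, labels, K: int) -> KNNModel:
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels).ravel()
    if labels.size != features.shape[0]:
        raise ValueError("features and labels disagree on the number of samples")
    if not 1 <= K <= features.shape[0]:
        raise ValueError(f"K must be in [1, {features.shape[0]}], got {K}")
    return KNNModel(train_features=features, train_labels=labels, K=K)


def knn_predict(model: KNNModel, queries) -> np.ndarray:
    """Majority vote over the K nearest training points (Euclidean)."""
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    if Q.shape[1] != model.train_features.shape[1]:
        raise ValueError(
            f"queries have {Q.shape[1]} features, model expects "
            f"{model.train_features.shape[1]}"
        )
    dists = np.linalg.norm(Q[:, None, :] - model.train_features[None, :, :], axis=2)
    out = np.empty(Q.shape[0], dtype=model.train_labels.dtype)
    for i, row in enumerate(dists):
        nn = np.argsort(row, kind="stable")[: model.K]  # stable: index breaks dist ties
        votes = model.train_labels[nn]
        classes, counts = np.unique(votes, return_counts=True)
        tied = classes[counts == counts.max()]
        if tied.size == 1:
            out[i] = tied[0]
        else:
            # closest member within the K neighbours decides; then smallest label
            best = min(
                sorted(tied),
                key=lambda cls: row[nn[votes == cls]].min(),
            )
            out[i] = best
    return out


def accuracy(predicted, truth) -> float:
    """Fraction of correct predictions."""
    predicted = np.asarray(predicted).ravel()
    truth = np.asarray(truth).ravel()
    if predicted.size != truth.size:
        raise ValueError("predicted and truth lengths differ")
    return float(np.mean(predicted == truth))


def _fit_method(train_scores, y_train, method: str, m: float):
    if method == "lda":
        return discriminant.lda_fit(train_scores, y_train)
    if method == "idlda":
        return discriminant.idlda_fit(train_scores, y_train)
    if method == "fidlda":
        return discriminant.fidlda_fit(train_scores, y_train, m=m)
    raise ValueError(f"unknown method {method!r}; choose lda, idlda or fidlda")


def evaluate_method(train_scores, y_train, test_scores, y_test, method: str,
                    K: int, m: float = 1.6) -> float:
    """Fit one extractor on training scores and report KNN test accuracy."""
    model = _fit_method(train_scores, y_train, method, m)
    f_train = discriminant.transform(model, train_scores)
    f_test = discriminant.transform(model, test_scores)
    knn = knn_fit(f_train, y_train, K)
    return accuracy(knn_predict(knn, f_test), y_test)


def k_grid(train_scores, y_train, test_scores, y_test, method: str,
           K_values=DEFAULT_K_GRID, m: float = 1.6) -> dict[int, float]:
    """Test accuracy of one extractor for each K (extractor fitted once)."""
    model = _fit_method(train_scores, y_train, method, m)
    f_train = discriminant.transform(model, train_scores)
    f_test = discriminant.transform(model, test_scores)
    result = {}
    for K in K_values:
        knn = knn_fit(f_train, y_train, int(K))
        result[int(K)] = accuracy(knn_predict(knn, f_test), y_test)
    return result


def m_grid(train_scores, y_train, test_scores, y_test,
           m_values=DEFAULT_M_GRID, K: int = 9) -> dict[float, float]:
    """Fuzzy-extractor test accuracy for each fuzzy weight index m."""
    result = {}
    for m in m_values:
        if m <= 1:
            raise ValueError(f"fuzzy weight index m must be > 1, got {m}")
        result[float(m)] = evaluate_method(
            train_scores, y_train, test_scores, y_test, "fidlda", K, m=float(m)
        )
    return result


def split_experiment(spectra_values, y, specs, methods=("lda", "idlda", "fidlda"),
                     pca_k: int = 6, K: int = 9, m: float = 1.6,
                     preprocessor=None) -> pd.DataFrame:
    """Accuracy table over several training/test split sizes.

    Rows are (n_train, n_test) pairs, columns the extraction methods.  For
    every split: fit the preprocessor (if any) and PCA on the training part
    only, project both parts, then fit/evaluate each extractor.
    """
    from .spectra import SpectraMatrix

    y = np.asarray(y).ravel()
    rows = []
    index = []
    for spec in specs:
        tr, te = stratified_split(y, spec)
        Xtr, Xte = spectra_values[tr], spectra_values[te]
        if preprocessor is not None:
            wl = np.arange(Xtr.shape[1], dtype=float)
            sm_tr = SpectraMatrix(Xtr, wl)
            sm_te = SpectraMatrix(Xte, wl)
            preprocessor.fit(sm_tr)
            Xtr = preprocessor.transform(sm_tr).values
            Xte = preprocessor.transform(sm_te).values
        pca = decomposition.pca_fit(Xtr, pca_k)
        s_tr = decomposition.pca_transform(pca, Xtr)
        s_te = decomposition.pca_transform(pca, Xte)
        row = {
            method: evaluate_method(s_tr, y[tr], s_te, y[te], method, K, m=m)
            for method in methods
        }
        rows.append(row)
        index.append((tr.size, te.size))
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["n_train", "n_test"]))
    return table
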