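"""End-to-end pipeline: split -> preprocess -> PCA -> discriminant -> KNN -> report.

The report is a plain dict (JSON-serialisable) carrying every effective
parameter, the seed, per-class accuracies and the confusion counts, so a
published run is self-describing and exactly reproducible.  Timestamps go to
the log stream only, never into the report, which keeps reports byte-stable
under a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields

import numpy as np

from . import classify, decomposition, discriminant, preprocess
from .spectra import SpectraMatrix

__all__ = ["RunConfig", "run_pipeline", "save_model", "load_model"]

logger = logging.getLogger("fidlda")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    method: str = "fidlda"            # lda | idlda | fidlda
    preprocessing: str = "sg"         # see preprocess.METHODS
    sg_window: int = 11
    sg_polyorder: int = 2
    sg_deriv: int = 0
    pca_k: int | None = 6
    pca_threshold: float | None = None
    m: float = 1.6
    K: int = 9
    n_train_per_class: int = 55
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("lda", "idlda", "fidlda"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.preprocessing not in preprocess.METHODS:
            raise ValueError(f"unknown preprocessing {self.preprocessing!r}")
        if (self.pca_k is None) == (self.pca_threshold is None):
            raise ValueError("exactly one of pca_k and pca_threshold must be set")
        if self.m <= 1:
            raise ValueError("fuzzy weight index m must be > 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.n_train_per_class < 1:
            raise ValueError("n_train_per_class must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build a config from a mapping, rejecting unknown keys."""
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig, spectra: SpectraMatrix) -> dict:
    """Execute the full discrimination pipeline on labelled spectra.

    Stages: stratified split, preprocessor fitted on the training split,
    PCA fitted on the preprocessed training split, discriminant extractor
    fitted on training scores, KNN on discriminant features.  Returns the
    JSON-ready report.
    """
    if spectra.labels is None:
        raise ValueError("pipeline: spectra must carry class labels")
    y = spectra.labels

    logger.info("split: %d samples, %d train per class, seed %d",
                spectra.n_samples, config.n_train_per_class, config.seed)
    tr, te = classify.stratified_split(
        y, classify.SplitSpec(config.n_train_per_class, config.seed))
    sm_tr = SpectraMatrix(spectra.values[tr], spectra.wavelengths, y[tr])
    sm_te = SpectraMatrix(spectra.values[te], spectra.wavelengths, y[te])

    logger.info("preprocess: %s", config.preprocessing)
    try:
        prep = preprocess.make_preprocessor(
            config.preprocessing, window=config.sg_window,
            polyorder=config.sg_polyorder, deriv=config.sg_deriv)
        prep.fit(sm_tr)
        Xtr = prep.transform(sm_tr).values
        Xte = prep.transform(sm_te).values
    except ValueError as exc:
        raise ValueError(f"preprocess: {exc}") from exc

    if config.pca_k is not None:
        k = config.pca_k
    else:
        ev = decomposition.full_eigenvalues(Xtr)
        k = decomposition.select_k_by_contribution(ev, config.pca_threshold)
    logger.info("pca: k = %d", k)
    try:
        pca = decomposition.pca_fit(Xtr, k)
    except ValueError as exc:
        raise ValueError(f"pca: {exc}") from exc
    s_tr = decomposition.pca_transform(pca, Xtr)
    s_te = decomposition.pca_transform(pca, Xte)

    logger.info("discriminant: %s", config.method)
    try:
        model = classify._fit_method(s_tr, y[tr], config.method, config.m)
    except ValueError as exc:
        raise ValueError(f"discriminant: {exc}") from exc
    f_tr = discriminant.transform(model, s_tr)
    f_te = discriminant.transform(model, s_te)

    logger.info("knn: K = %d", config.K)
    try:
        knn = classify.knn_fit(f_tr, y[tr], config.K)
    except ValueError as exc:
        raise ValueError(f"knn: {exc}") from exc
    pred = classify.knn_predict(knn, f_te)
    y_te = y[te]

    classes = [int(c) for c in np.unique(y)]
    confusion = {
        str(t): {str(p): int(np.sum((y_te == t) & (pred == p))) for p in classes}
        for t in classes
    }
    per_class = {
        str(t): float(np.mean(pred[y_te == t] == t)) for t in classes
    }
    report = {
        "config": asdict(config),
        "pca_k_effective": int(k),
        "n_discriminant_vectors": int(model.r),
        "discriminant_eigenvalues": [float(v) for v in model.eigenvalues],
        "n_train": int(tr.size),
        "n_test": int(te.size),
        "classes": classes,
        "per_class_accuracy": per_class,
        "confusion": confusion,
        "overall_accuracy": classify.accuracy(pred, y_te),
    }
    logger.info("overall accuracy: %.4f", report["overall_accuracy"])
    return report


def save_model(path, model: discriminant.DiscriminantModel) -> None:
    """Serialize a fitted discriminant model to a JSON key-value file."""
    payload = {
        "method": model.method,
        "W": model.W.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "train_mean": model.train_mean.tolist(),
        "class_means": model.class_means.tolist(),
        "classes": [int(c) for c in model.classes],
        "m": model.m,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> discriminant.DiscriminantModel:
    """Load a discriminant model saved by :func:`save_model`."""
    with open(path) as fh:
        payload = json.load(fh)
    return discriminant.DiscriminantModel(
        method=payload["method"],
        W=np.array(payload["W"], dtype=float),
        eigenvalues=np.array(payload["eigenvalues"], dtype=float),
        train_mean=np.array(payload["train_mean"], dtype=float),
        class_means=np.array(payload["class_means"], dtype=float),
        classes=np.array(payload["classes"]),
        m=payload.get("m"),
    )
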