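"""Spectral pretreatments: SNV, MSC, Savitzky-Golay filtering, mean centering.

All preprocessors share a scikit-learn-like ``fit``/``transform`` surface so
they can be chained.  The stateless ones (SNV, SG) ignore ``fit``; the
stateful ones (MSC reference spectrum, MC column means) estimate their
statistics on the training split only and apply them unchanged to test
spectra -- the standard hygiene that keeps the holdout honest.

Conventions, stated so tests can be exact:

* SNV uses the sample (n-1) standard deviation.
* MSC regresses each spectrum on the training-mean reference by ordinary
  least squares, ``x ~ a + b * ref``, and returns ``(x - a) / b``.
* SG edge handling fits the edge polynomials ('interp' mode), preserving the
  full wavelength grid.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraMatrix

__all__ = [
    "snv", "SNV", "MSC", "SavitzkyGolay", "MeanCenter", "Chain",
    "make_preprocessor", "METHODS",
]


def snv(spectra: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: standardize each spectrum to mean 0, sd 1.

    Removes per-spectrum baseline offsets and multiplicative scatter.  Raises
    ``ValueError`` naming the row index if a spectrum is constant.
    """
    X = spectra.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"SNV undefined for constant spectrum at row {bad[0]}")
    return spectra.with_values((X - mu) / sd)


class _Preprocessor:
    """Base fit/transform surface; ``fit`` returns ``self``."""

    def fit(self, spectra: SpectraMatrix) -> "_Preprocessor":
        return self

    def transform(self, spectra: SpectraMatrix) -> SpectraMatrix:  # pragma: no cover
        raise NotImplementedError

    def fit_transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        return self.fit(spectra).transform(spectra)


class SNV(_Preprocessor):
    """Stateless wrapper around :func:`snv`."""

    kind = "snv"

    def transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        return snv(spectra)


class MSC(_Preprocessor):
    """Multiplicative scatter correction against the training-mean spectrum."""

    kind = "msc"

    def __init__(self) -> None:
        self.reference_: np.ndarray | None = None

    def fit(self, spectra: SpectraMatrix) -> "MSC":
        self.reference_ = spectra.values.mean(axis=0)
        return self

    def transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        if self.reference_ is None:
            raise RuntimeError("MSC must be fitted before transforming")
        ref = self.reference_
        if spectra.n_wavelengths != ref.size:
            raise ValueError(
                f"spectra have {spectra.n_wavelengths} wavelengths, reference has {ref.size}"
            )
        ref_c = ref - ref.mean()
        denom = ref_c @ ref_c
        if denom == 0:
            raise ValueError("MSC reference spectrum is constant")
        X = spectra.values
        # OLS of each row on [1, ref]: b = cov(ref, x) / var(ref)
        b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
        bad = np.flatnonzero(np.abs(b) < 1e-12)
        if bad.size:
            raise ValueError(f"MSC slope below tolerance for spectrum at row {bad[0]}")
        a = X.mean(axis=1) - b * ref.mean()
        return spectra.with_values((X - a[:, None]) / b[:, None])


class SavitzkyGolay(_Preprocessor):
    """Savitzky-Golay least-squares polynomial smoothing (optionally differentiating).

    Defaults: window 11, polyorder 2, deriv 0.
    """

    kind = "sg"

    def __init__(self, window: int = 11, polyorder: int = 2, deriv: int = 0) -> None:
        if window % 2 == 0 or window < 1:
            raise ValueError(f"window must be a positive odd integer, got {window}")
        if polyorder >= window:
            raise ValueError(f"polyorder ({polyorder}) must be < window ({window})")
        if deriv < 0 or deriv > polyorder:
            raise ValueError(f"deriv ({deriv}) must be in [0, polyorder]")
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv

    def transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        if self.window > spectra.n_wavelengths:
            raise ValueError(
                f"window ({self.window}) exceeds spectrum length ({spectra.n_wavelengths})"
            )
        out = savgol_filter(spectra.values, self.window, self.polyorder,
                            deriv=self.deriv, axis=1, mode="interp")
        return spectra.with_values(out)


class MeanCenter(_Preprocessor):
    """Column-wise subtraction of the training mean spectrum."""

    kind = "mc"

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None

    def fit(self, spectra: SpectraMatrix) -> "MeanCenter":
        self.mean_ = spectra.values.mean(axis=0)
        return self

    def transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        if self.mean_ is None:
            raise RuntimeError("MeanCenter must be fitted before transforming")
        if spectra.n_wavelengths != self.mean_.size:
            raise ValueError(
                f"spectra have {spectra.n_wavelengths} wavelengths, "
                f"stored mean has {self.mean_.size}"
            )
        return spectra.with_values(spectra.values - self.mean_)


class Chain(_Preprocessor):
    """Ordered composition of preprocessors.

    Fitting step ``k`` uses the output of steps ``1..k-1`` applied to the
    training data, so stateful steps see the data they will actually receive.
    """

    kind = "chain"

    def __init__(self, steps: list[_Preprocessor]) -> None:
        if not steps:
            raise ValueError("chain needs at least one step")
        self.steps = list(steps)

    def fit(self, spectra: SpectraMatrix) -> "Chain":
        current = spectra
        for step in self.steps:
            current = step.fit(current).transform(current)
        return self

    def transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        current = spectra
        for step in self.steps:
            current = step.transform(current)
        return current


#: CLI method names and their factories.
METHODS = ("snv", "msc", "sg", "mc", "sg+snv", "sg+msc", "none")


def make_preprocessor(method: str, window: int = 11, polyorder: int = 2,
                      deriv: int = 0) -> _Preprocessor:
    """Build a preprocessor from its CLI name (e.g. ``'sg+snv'``)."""
    def sg() -> SavitzkyGolay:
        return SavitzkyGolay(window=window, polyorder=polyorder, deriv=deriv)

    factories = {
        "snv": SNV,
        "msc": MSC,
        "sg": sg,
        "mc": MeanCenter,
        "sg+snv": lambda: Chain([sg(), SNV()]),
        "sg+msc": lambda: Chain([sg(), MSC()]),
        "none": lambda: Chain([_Identity()]),
    }
    if method not in factories:
        raise ValueError(f"unknown preprocessing method {method!r}; choose from {METHODS}")
    return factories[method]()


class _Identity(_Preprocessor):
    kind = "identity"

    def transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        return spectra
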