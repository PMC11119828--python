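"""Synthetic NIR spectra generator.

Emulates a reflectance-mode acquisition of dried plant material in the
900-1700 nm band: each class is a sum of Gaussian absorption bands (the
defaults sit on the C-H/O-H/N-H overtone regions near 1354 nm, 1400-1470 nm
and 1652 nm that dominate tea-like samples), and each individual spectrum is
distorted by a multiplicative scatter slope, an additive baseline offset and
white noise.  The multiplicative + additive distortion is deliberate: it is
exactly the effect SNV and MSC are designed to remove, so the preprocessing
stage is meaningfully exercised.

The default configuration is the packaged five-class benchmark: 80 samples
per class on a 400-point grid, with the five classes differing only in band
DEPTH RATIOS (their depth vectors sit in a plane orthogonal to the common
template) and arranged as two deliberately close pairs plus one reference
class.  Because the multiplicative scatter occupies the overall-scale axis,
class identity must be read from the shape ratios, which is the structure
that separates the three discriminant extractors downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectraMatrix

__all__ = ["SyntheticConfig", "generate", "benchmark_config"]

#: (center nm, width nm) of the default absorption bands.
DEFAULT_BAND_POSITIONS = ((1354.0, 30.0), (1440.0, 30.0), (1652.0, 30.0))

#: Per-class band depths, in absorbance units.  All five classes share the
#: same three bands; their depth vectors sit in a plane orthogonal to the
#: mean template (0.9, 0.7, 0.5), so class identity is carried by band-shape
#: ratios rather than overall absorbance scale -- the scale axis is occupied
#: by the multiplicative scatter that every sample carries.  Classes 1/2 and
#: classes 3/4 form two deliberately close pairs.
DEFAULT_CLASS_AMPLITUDES = (
    (0.9000, 0.7000, 0.5000),
    (0.9307, 0.6605, 0.5000),
    (0.9402, 0.6679, 0.4725),
    (0.9159, 0.7123, 0.4542),
    (0.9343, 0.6886, 0.4542),
)


def _default_class_bands() -> list[list[tuple[float, float, float]]]:
    return [
        [(center, width, amp)
         for (center, width), amp in zip(DEFAULT_BAND_POSITIONS, amps)]
        for amps in DEFAULT_CLASS_AMPLITUDES
    ]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic acquisition.

    Attributes
    ----------
    n_classes, n_per_class : int
        Number of varieties and samples per variety (defaults 5 and 80).
    wavelengths : ndarray
        Strictly increasing nm grid (default 400 points over [900, 1700]).
    class_bands : list of list of (center, width, amplitude)
        Gaussian absorption bands per class, one list per class.
    scatter_slope_sd : float
        SD of the per-sample multiplicative slope (dimensionless).
    baseline_sd : float
        SD of the per-sample additive baseline offset (absorbance units).
    noise_sd : float
        SD of the i.i.d. white noise (absorbance units).
    seed : int
        Seed of the single random stream consumed by :func:`generate`.
    """

    n_classes: int = 5
    n_per_class: int = 80
    wavelengths: np.ndarray = field(default_factory=lambda: np.linspace(900.0, 1700.0, 400))
    class_bands: list = field(default_factory=_default_class_bands)
    scatter_slope_sd: float = 0.06
    baseline_sd: float = 0.02
    noise_sd: float = 0.01
    seed: int = 42

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be a strictly increasing 1-D grid")
        if len(self.class_bands) != self.n_classes:
            raise ValueError(
                f"class_bands has {len(self.class_bands)} entries for {self.n_classes} classes"
            )
        for j, bands in enumerate(self.class_bands):
            for center, width, amp in bands:
                if width < 0:
                    raise ValueError(f"class_bands[{j}]: negative width {width}")
                if amp < 0:
                    raise ValueError(f"class_bands[{j}]: negative amplitude {amp}")
        for name in ("scatter_slope_sd", "baseline_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def class_template(config: SyntheticConfig, j: int) -> np.ndarray:
    """Noise-free absorbance template of class ``j`` on the config grid."""
    wl = np.asarray(config.wavelengths, dtype=float)
    template = np.zeros_like(wl)
    for center, width, amp in config.class_bands[j]:
        template += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return template


def generate(config: SyntheticConfig) -> SpectraMatrix:
    """Draw a labelled synthetic spectra set.

    One ``numpy`` Generator seeded with ``config.seed`` is consumed in a
    fixed order -- all slopes, then all offsets, then the noise matrix -- so
    the draw is bit-reproducible and changing, say, ``noise_sd`` perturbs
    only the noise term for a given seed.

    Spectrum ``i`` of class ``j`` is
    ``template_j * (1 + slope_i) + offset_i + noise_i`` with
    ``slope_i ~ N(0, scatter_slope_sd)`` and ``offset_i ~ N(0, baseline_sd)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    wl = np.asarray(config.wavelengths, dtype=float)
    n = config.n_classes * config.n_per_class

    slopes = rng.normal(0.0, config.scatter_slope_sd, size=n)
    offsets = rng.normal(0.0, config.baseline_sd, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, wl.size))

    values = np.empty((n, wl.size))
    labels = np.empty(n, dtype=int)
    for j in range(config.n_classes):
        template = class_template(config, j)
        sl = slice(j * config.n_per_class, (j + 1) * config.n_per_class)
        values[sl] = template[None, :] * (1.0 + slopes[sl, None]) + offsets[sl, None]
        labels[sl] = j
    values += noise
    return SpectraMatrix(values=values, wavelengths=wl, labels=labels)


def benchmark_config(seed: int = 42) -> SyntheticConfig:
    """The packaged five-class overlapping benchmark configuration."""
    return SyntheticConfig(seed=seed)
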