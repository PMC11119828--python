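"""Core spectral data container and its CSV interchange format.

A :class:`SpectraMatrix` holds an ``n x d`` absorbance matrix together with a
strictly increasing wavelength axis in nanometres and, optionally, one integer
class label per sample.  Every stage of the pipeline consumes and produces
this container.

The on-disk format is a plain CSV with header ``label,wl_1,...,wl_d`` where
``wl_i`` are the wavelengths printed as numbers, followed by one row per
sample (class label, then ``d`` absorbance values).  Floats are written with
``repr`` so a write/read cycle is lossless.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectraMatrix", "read_spectra", "write_spectra"]


@dataclass
class SpectraMatrix:
    """Absorbance spectra with a wavelength axis and optional labels.

    Parameters
    ----------
    values : ndarray, shape (n, d)
        Absorbance values, one spectrum per row.  Must be finite.
    wavelengths : ndarray, shape (d,)
        Strictly increasing wavelength axis in nm.
    labels : ndarray of int, shape (n,), optional
        Class label per sample.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        n, d = self.values.shape
        if n < 1 or d < 2:
            raise ValueError(f"need at least 1 spectrum and 2 wavelengths, got shape {(n, d)}")
        if self.wavelengths.shape != (d,):
            raise ValueError(
                f"wavelength axis length {self.wavelengths.size} does not match {d} columns"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("absorbance values must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels).ravel()
            if self.labels.shape != (n,):
                raise ValueError(f"expected {n} labels, got {self.labels.size}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "SpectraMatrix":
        """Return a copy carrying new absorbance values on the same axis."""
        return SpectraMatrix(values=np.asarray(values, dtype=float),
                             wavelengths=self.wavelengths.copy(),
                             labels=None if self.labels is None else self.labels.copy())


def write_spectra(path, spectra: SpectraMatrix) -> None:
    """Write a :class:`SpectraMatrix` to CSV (header ``label,wl_1,...``)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label"] + [repr(float(w)) for w in spectra.wavelengths])
        labels = spectra.labels
        if labels is None:
            labels = np.zeros(spectra.n_samples, dtype=int)
        for lab, row in zip(labels, spectra.values):
            writer.writerow([int(lab)] + [repr(float(v)) for v in row])


def read_spectra(path) -> SpectraMatrix:
    """Read a spectra CSV written by :func:`write_spectra`.

    Raises
    ------
    ValueError
        On ragged rows, non-numeric cells or a non-increasing wavelength
        header; the message names the offending line number (1-based).
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 3 or header[0].strip().lower() != "label":
            raise ValueError(f"{path}: line 1: expected header 'label,wl_1,...,wl_d'")
        try:
            wavelengths = np.array([float(w) for w in header[1:]])
        except ValueError:
            raise ValueError(f"{path}: line 1: non-numeric wavelength in header") from None
        if not np.all(np.diff(wavelengths) > 0):
            raise ValueError(f"{path}: line 1: header wavelengths are not strictly increasing")
        d = wavelengths.size
        labels: list[int] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec:
                continue
            if len(rec) != d + 1:
                raise ValueError(
                    f"{path}: line {lineno}: expected {d + 1} fields, got {len(rec)}"
                )
            try:
                labels.append(int(rec[0]))
                rows.append([float(v) for v in rec[1:]])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-numeric cell") from None
        if not rows:
            raise ValueError(f"{path}: no sample rows")
        return SpectraMatrix(values=np.array(rows), wavelengths=wavelengths,
                             labels=np.array(labels, dtype=int))
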