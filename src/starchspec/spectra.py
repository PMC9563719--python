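"""ROI mean-spectrum extraction and standard normal variate preprocessing.

Each sample contributes one spectrum: the per-band arithmetic mean over a
fixed, axis-aligned region of interest (default 100 x 100 pixels, centred in
the frame). SNV then removes per-spectrum multiplicative scatter and additive
offset by standardising every spectrum to zero mean and unit (n-1) standard
deviation across its bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cube_io import Hypercube

__all__ = ["SpectrumTable", "extract_roi", "mean_spectrum", "snv"]


@dataclass
class SpectrumTable:
    """n_samples x n_bands reflectance matrix with wavelength labels."""

    X: np.ndarray
    wavelengths: np.ndarray = field(repr=False)
    sample_ids: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bands)")
        if self.X.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"column count {self.X.shape[1]} does not match wavelength count {self.wavelengths.size}"
            )
        if self.X.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match number of sample ids")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{w:.2f}" for w in self.wavelengths]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumTable":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise ValueError("spectrum CSV must start with a sample_id column")
        wl = np.array([float(c) for c in df.columns[1:]])
        return cls(df.iloc[:, 1:].to_numpy(float), wl, list(df["sample_id"].astype(str)))


def extract_roi(cube: Hypercube, center: tuple[int, int] | None = None, size: int = 100) -> Hypercube:
    """Cut a ``size x size`` sub-cube.

    Indexing is 0-based half-open: the ROI covers rows ``[r0, r0+size)`` and
    likewise for columns. With ``center=None`` the ROI is centred in the
    frame, ``r0 = floor((rows - size) / 2)``; an explicit ``center`` pixel
    places ``r0 = center_row - size // 2``.
    """
    if size < 1:
        raise ValueError("ROI size must be >= 1")
    if size > cube.rows or size > cube.cols:
        raise ValueError(f"ROI of {size}x{size} does not fit in a {cube.rows}x{cube.cols} frame")
    if center is None:
        r0 = (cube.rows - size) // 2
        c0 = (cube.cols - size) // 2
    else:
        r0 = int(center[0]) - size // 2
        c0 = int(center[1]) - size // 2
    if r0 < 0 or c0 < 0 or r0 + size > cube.rows or c0 + size > cube.cols:
        raise ValueError(f"ROI [{r0}:{r0 + size}, {c0}:{c0 + size}] exceeds the {cube.rows}x{cube.cols} frame")
    return Hypercube(cube.data[r0 : r0 + size, c0 : c0 + size, :], cube.wavelengths)


def mean_spectrum(roi: Hypercube) -> np.ndarray:
    """Per-band arithmetic mean over all ROI pixels (length n_bands)."""
    if roi.rows == 0 or roi.cols == 0:
        raise ValueError("empty ROI")
    return roi.data.reshape(-1, roi.bands).mean(axis=0, dtype=np.float64)


def _snv_matrix(X: np.ndarray, sample_ids: list[str] | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        name = sample_ids[flat[0]] if sample_ids else f"row {flat[0]}"
        raise ValueError(f"SNV undefined for constant spectrum (sample {name})")
    return (X - mu) / sd


def snv(table: SpectrumTable | np.ndarray) -> SpectrumTable | np.ndarray:
    """Standard normal variate: standardise each spectrum (row) to mean 0 and
    sample (n-1) standard deviation 1 across its bands.

    Accepts a :class:`SpectrumTable` or a bare matrix and returns the same
    kind. Constant spectra are rejected with the offending sample named.
    """
    if isinstance(table, SpectrumTable):
        return SpectrumTable(_snv_matrix(table.X, table.sample_ids), table.wavelengths, table.sample_ids)
    return _snv_matrix(np.atleast_2d(table))
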