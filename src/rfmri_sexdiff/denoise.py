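"""Nuisance regression, temporal filtering and spatial smoothing.

The discovery pipeline regresses the Friston-24 motion expansion, aCompCor
components and linear/quadratic trends from every voxel, then band-pass
filters 0.01-0.1 Hz (skipped for the fALFF input, which needs the full
spectrum). A global-signal column turns this into the GSR robustness
variant. Smoothing is Gaussian and, in the study pipeline, applied to the
derived metric maps rather than the 4D series.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .cohort import BoldImage

__all__ = [
    "NuisanceDesign",
    "friston24",
    "compcor",
    "detrend_columns",
    "global_signal",
    "build_nuisance_design",
    "nuisance_regress",
    "bandpass",
    "smooth",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass
class NuisanceDesign:
    """Named T x k nuisance regressor matrix."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix columns must match names")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def check_rank(self) -> None:
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("nuisance design is rank deficient")

    def hstack(self, other: "NuisanceDesign") -> "NuisanceDesign":
        if other.n_timepoints != self.n_timepoints:
            raise ValueError("timepoint mismatch")
        return NuisanceDesign(
            np.hstack([self.matrix, other.matrix]), self.names + other.names
        )


def friston24(motion: np.ndarray) -> NuisanceDesign:
    """24-parameter motion expansion: 6 params, their one-lag backward
    differences (first row zero), and the squares of both sets."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be (T, 6)")
    if motion.shape[0] < 3:
        raise ValueError("need at least 3 timepoints")
    diff = np.vstack([np.zeros(6), np.diff(motion, axis=0)])
    mat = np.hstack([motion, diff, motion**2, diff**2])
    names = (
        [f"mot{i}" for i in range(6)]
        + [f"mot{i}_d" for i in range(6)]
        + [f"mot{i}_sq" for i in range(6)]
        + [f"mot{i}_d_sq" for i in range(6)]
    )
    return NuisanceDesign(mat, names)


def compcor(bold: BoldImage, noise_mask: np.ndarray, k: int = 5) -> NuisanceDesign:
    """Anatomical-CompCor style components from a noise compartment.

    The noise-mask voxel time series are variance-normalized and the top-k
    principal component time series returned, each scaled to unit variance.
    """
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if not noise_mask.any():
        raise ValueError("noise mask is empty")
    T = bold.n_timepoints
    if k >= T:
        raise ValueError("k must be smaller than the number of timepoints")
    if k == 0:
        return NuisanceDesign(np.empty((T, 0)), [])
    X = bold.data[noise_mask]  # (V, T)
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    X = X[sd > 0]
    if X.shape[0] == 0:
        raise ValueError("all noise-mask voxels have zero variance")
    X = X / X.std(axis=1, keepdims=True)
    # PCA over time via the T x T covariance (cheaper than a full SVD)
    C = X.T @ X
    evals, evecs = np.linalg.eigh(C)
    comps = evecs[:, ::-1][:, :k]
    comps = comps / comps.std(axis=0, keepdims=True)
    return NuisanceDesign(comps, [f"compcor{i + 1}" for i in range(comps.shape[1])])


def detrend_columns(T: int) -> NuisanceDesign:
    """Intercept plus centred linear and quadratic trend regressors."""
    t = np.linspace(-1.0, 1.0, T)
    mat = np.column_stack([np.ones(T), t, t**2 - (t**2).mean()])
    return NuisanceDesign(mat, ["intercept", "linear", "quadratic"])


def global_signal(bold: BoldImage) -> NuisanceDesign:
    gs = bold.in_mask().mean(axis=0)
    return NuisanceDesign(gs[:, None], ["gs"])


def build_nuisance_design(
    bold: BoldImage,
    motion: np.ndarray,
    noise_mask: np.ndarray | None = None,
    n_compcor: int = 5,
    gsr: bool = False,
) -> NuisanceDesign:
    """Assemble the discovery design (Friston-24 + CompCor + trends), with an
    optional global-signal column for the GSR robustness variant."""
    design = detrend_columns(bold.n_timepoints).hstack(friston24(motion))
    if noise_mask is not None and n_compcor > 0:
        design = design.hstack(compcor(bold, noise_mask, n_compcor))
    if gsr:
        design = design.hstack(global_signal(bold))
    design.check_rank()
    return design


def nuisance_regress(bold: BoldImage, design: NuisanceDesign) -> BoldImage:
    """Per-voxel OLS residuals against the nuisance design."""
    X = design.matrix
    if X.shape[0] != bold.n_timepoints:
        raise ValueError("design rows must equal the number of timepoints")
    design.check_rank()
    Y = bold.in_mask().T  # (T, V)
    Q, R = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    del R
    out = np.zeros_like(bold.data)
    out[bold.mask] = resid.T
    return dataclasses.replace(bold, data=out)


def bandpass(bold: BoldImage, low: float = 0.01, high: float = 0.1) -> BoldImage:
    """Ideal frequency-domain band-pass filter; the DC term is removed."""
    nyq = 1.0 / (2.0 * bold.tr)
    if not (0 <= low < high <= nyq + 1e-12):
        raise ValueError("invalid band")
    T = bold.n_timepoints
    freqs = np.fft.rfftfreq(T, d=bold.tr)
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    Y = bold.in_mask()
    spec = np.fft.rfft(Y, axis=-1)
    spec[:, ~keep] = 0.0
    out = np.zeros_like(bold.data)
    out[bold.mask] = np.fft.irfft(spec, n=T, axis=-1)
    return dataclasses.replace(bold, data=out)


def smooth(
    arr: np.ndarray, fwhm: float = 6.0, voxel_size: float = 3.0
) -> np.ndarray:
    """Gaussian smoothing of a 3D map or 4D series (per volume), FWHM in mm."""
    if voxel_size <= 0:
        raise ValueError("voxel size must be positive")
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm == 0:
        return np.array(arr, copy=True)
    sigma = fwhm * FWHM_TO_SIGMA / voxel_size
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        return ndimage.gaussian_filter(arr, sigma)
    if arr.ndim == 4:
        return ndimage.gaussian_filter(arr, (sigma, sigma, sigma, 0.0))
    raise ValueError("expected a 3D or 4D array")
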