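"""Spectral conditioning chain: baseline removal, denoising, normalization,
and a variance-stabilizing transform.

The chain mirrors standard chemometric practice for hybrid Raman/LIBS data:
Raman spectra carry a broad fluorescence background that must be estimated
and subtracted (asymmetric least squares), LIBS spectra get a constant
offset subtraction; both are then smoothed (Savitzky-Golay), scaled to unit
total intensity (removing multiplicative shot-to-shot plasma fluctuation),
and square-root transformed to stabilize the noise variance.  The fixed
order is baseline -> denoise -> normalize -> transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .axes import SpectralAxis

logger = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "Spectrum",
    "estimate_baseline",
    "denoise",
    "normalize",
    "transform",
    "preprocess_spectrum",
    "preprocess_matrix",
]


class Modality(str, Enum):
    raman = "raman"
    libs = "libs"
    hybrid = "hybrid"


@dataclass(frozen=True)
class Spectrum:
    """A single acquisition: axis, intensities, modality, and provenance."""

    axis: SpectralAxis
    intensities: np.ndarray
    modality: Modality
    label: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", y)
        object.__setattr__(self, "modality", Modality(self.modality))
        if y.shape != (len(self.axis),):
            raise ValueError(
                f"intensities length {y.shape} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))


def estimate_baseline(
    spectrum: Spectrum,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    n_iter: int = 10,
) -> np.ndarray:
    """Asymmetric-least-squares baseline (Eilers-Boelens style).

    Minimizes ``sum_i w_i (y_i - z_i)^2 + smoothness * sum_i (d2 z)_i^2``
    with asymmetric weights re-estimated each iteration: points above the
    current baseline (peaks) get weight ``asymmetry``, points below get
    ``1 - asymmetry``, so the fit hugs the lower envelope of the signal.

    Parameters
    ----------
    smoothness : float
        Second-difference penalty weight; larger -> stiffer baseline.
    asymmetry : float in (0, 1)
        Weight for points above the baseline; small values make peaks
        nearly invisible to the fit.
    """
    y = spectrum.intensities
    if y.size < 10:
        raise ValueError("baseline estimation needs at least 10 channels")
    if not (0.0 < asymmetry < 1.0):
        raise ValueError(f"asymmetry must be in (0, 1), got {asymmetry}")
    n = y.size
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = smoothness * (d2.T @ d2)
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        W = sparse.diags(w, format="csc")
        z = spsolve((W + penalty).tocsc(), w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def denoise(spectrum: Spectrum, window: int = 11, order: int = 3) -> Spectrum:
    """Savitzky-Golay polynomial smoothing.

    A window of ``window`` channels is fit with a degree-``order``
    polynomial at each position; polynomial inputs of degree <= order pass
    through unchanged.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= order:
        raise ValueError(f"window ({window}) must exceed order ({order})")
    if window > len(spectrum.axis):
        raise ValueError("window exceeds spectrum length")
    return spectrum.with_intensities(savgol_filter(spectrum.intensities, window, order))


def normalize(spectrum: Spectrum) -> Spectrum:
    """Scale to unit total intensity (sum = 1).

    Removes the global multiplicative shot-to-shot fluctuation of plasma
    emission; invariant to positive rescaling of the input.
    """
    total = spectrum.intensities.sum()
    if total <= 0:
        raise ValueError("cannot normalize a spectrum with non-positive total intensity")
    return spectrum.with_intensities(spectrum.intensities / total)


def transform(spectrum: Spectrum) -> Spectrum:
    """Channel-wise square root (variance stabilization).

    Negative residuals left over from baseline subtraction are clipped to
    zero (with a logged warning) before the root is taken; the map is
    monotone so channel ordering is preserved.
    """
    y = spectrum.intensities
    if np.any(y < 0):
        logger.warning(
            "clipping %d negative intensities to zero before sqrt transform",
            int(np.sum(y < 0)),
        )
        y = np.clip(y, 0.0, None)
    return spectrum.with_intensities(np.sqrt(y))


def preprocess_spectrum(
    spectrum: Spectrum,
    baseline_smoothness: float = 1e5,
    baseline_asymmetry: float = 0.01,
    sg_window: int = 11,
    sg_order: int = 3,
    skip_baseline: bool = False,
    skip_denoise: bool = False,
    skip_normalize: bool = False,
    skip_transform: bool = False,
    transform_kind: str = "sqrt",
) -> Spectrum:
    """Full conditioning chain for one spectrum.

    Raman spectra get the asymmetric-least-squares fluorescence baseline
    removed; LIBS spectra get their per-spectrum minimum subtracted as a
    constant offset.  ``transform_kind`` is ``sqrt`` (default), ``log1p``
    or ``identity``.
    """
    s = spectrum
    if not skip_baseline:
        if s.modality is Modality.raman:
            base = estimate_baseline(s, baseline_smoothness, baseline_asymmetry)
            s = s.with_intensities(s.intensities - base)
        else:
            s = s.with_intensities(s.intensities - s.intensities.min())
    if not skip_denoise:
        s = denoise(s, sg_window, sg_order)
    if not skip_normalize:
        s = s.with_intensities(np.clip(s.intensities, 0.0, None))
        s = normalize(s)
    if not skip_transform:
        if transform_kind == "sqrt":
            s = transform(s)
        elif transform_kind == "log1p":
            s = s.with_intensities(np.log1p(np.clip(s.intensities, 0.0, None)))
        elif transform_kind != "identity":
            raise ValueError(f"unknown transform {transform_kind!r}")
    return s


def preprocess_matrix(matrix: np.ndarray, axis: SpectralAxis, modality, **kwargs) -> np.ndarray:
    """Apply :func:`preprocess_spectrum` to every row of a spectra matrix."""
    out = np.empty_like(np.asarray(matrix, dtype=float))
    for i in range(out.shape[0]):
        s = Spectrum(axis, matrix[i], modality)
        out[i] = preprocess_spectrum(s, **kwargs).intensities
    return out
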