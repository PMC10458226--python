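"""Peak detection, Lorentzian line fitting, and interfering-line subtraction.

In simultaneous acquisition the strong atomic lines of the plasma (notably
the Na feature at 588.9 nm) spill into the Raman spectral window, showing
up around 1816 cm^-1 on the shift axis.  The remedy is to fit a Lorentzian
profile (plus a constant local background) over a narrow window around the
line and subtract the fitted line from the spectrum, leaving the Raman
bands untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .simulate import PeakModel, PeakShape
from .preprocess import Spectrum

__all__ = ["FittedLine", "detect_peaks", "fit_lorentzian", "subtract_line"]


@dataclass(frozen=True)
class FittedLine:
    """A Lorentzian fitted over a window of the axis."""

    model: PeakModel
    window: tuple[float, float]
    residual_rms: float
    background: float = 0.0

    def __post_init__(self):
        lo, hi = self.window
        if not (lo <= self.model.center <= hi):
            raise ValueError(
                f"fitted center {self.model.center} outside window [{lo}, {hi}]"
            )
        if not np.isfinite(self.residual_rms):
            raise ValueError("residual_rms must be finite")


def detect_peaks(spectrum: Spectrum, min_prominence: float = 0.05) -> list[float]:
    """Local maxima with prominence >= ``min_prominence`` x max intensity.

    Centers are refined to sub-channel precision by a 3-point parabolic
    interpolation through the maximum and its neighbours; returned sorted
    ascending in axis units.
    """
    y = spectrum.intensities
    if y.size == 0:
        raise ValueError("cannot detect peaks in an empty spectrum")
    span = float(y.max() - y.min())
    if span <= 0:
        return []
    idx, _ = find_peaks(y, prominence=min_prominence * span)
    x = spectrum.axis.values
    centers = []
    for i in idx:
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            centers.append(float(np.interp(i + delta, np.arange(x.size), x)))
        else:
            centers.append(float(x[i]))
    return sorted(centers)


def _lorentz_bg(x, center, fwhm, amplitude, background):
    half = fwhm / 2.0
    return amplitude * half**2 / ((x - center) ** 2 + half**2) + background


def fit_lorentzian(spectrum: Spectrum, window: tuple[float, float],
                   max_iter: int = 5000) -> FittedLine:
    """Nonlinear least-squares Lorentzian fit over ``window``.

    The model is a Lorentzian (center, FWHM, height) plus a constant local
    background.  Initialization comes from :func:`detect_peaks` restricted
    to the window; a window that contains no detectable peak is an error.
    """
    lo, hi = window
    mask = (spectrum.axis.values >= lo) & (spectrum.axis.values <= hi)
    if mask.sum() < 7:
        raise ValueError(f"window [{lo}, {hi}] contains fewer than 7 channels")
    x = spectrum.axis.values[mask]
    y = spectrum.intensities[mask]
    sub = Spectrum(type(spectrum.axis)(spectrum.axis.kind, x,
                                       spectrum.axis.excitation_nm),
                   y, spectrum.modality)
    candidates = [c for c in detect_peaks(sub, min_prominence=0.1) if lo <= c <= hi]
    if not candidates:
        raise ValueError(f"no peak in window [{lo}, {hi}]")
    bg0 = float(y.min())
    c0 = candidates[int(np.argmax([y[np.argmin(np.abs(x - c))] for c in candidates]))]
    a0 = float(y.max() - bg0)
    w0 = max((hi - lo) / 10.0, 2.0 * float(np.mean(np.diff(x))))
    try:
        popt, _ = curve_fit(
            _lorentz_bg, x, y, p0=[c0, w0, a0, bg0],
            bounds=([lo, 1e-12, 0.0, -np.inf], [hi, hi - lo, np.inf, np.inf]),
            maxfev=max_iter,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Lorentzian fit did not converge in window [{lo}, {hi}]: {exc}")
    center, fwhm, amplitude, background = (float(v) for v in popt)
    resid = y - _lorentz_bg(x, *popt)
    model = PeakModel(center, fwhm, amplitude, PeakShape.lorentzian)
    return FittedLine(model, (float(lo), float(hi)), float(np.sqrt(np.mean(resid**2))),
                      background)


def subtract_line(spectrum: Spectrum, line: FittedLine) -> Spectrum:
    """Remove a fitted line from the spectrum.

    Only the Lorentzian term is subtracted (the constant local background
    stays); results are clipped at zero.  Channels outside the fit window
    are returned bit-for-bit untouched.
    """
    x = spectrum.axis.values
    lo, hi = line.window
    if not (x[0] <= line.model.center <= x[-1]):
        raise ValueError(
            f"fitted line at {line.model.center} lies outside the spectrum axis "
            f"[{x[0]}, {x[-1]}]"
        )
    y = spectrum.intensities.copy()
    mask = (x >= lo) & (x <= hi)
    y[mask] = np.clip(y[mask] - line.model(x[mask]), 0.0, None)
    return spectrum.with_intensities(y)
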