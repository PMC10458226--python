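"""Spectral-axis representation and wavelength <-> Raman-shift conversion.

A hybrid Raman/LIBS instrument records both modalities on one spectrometer:
LIBS lines live on an absolute wavelength axis (nm) while Raman bands are
expressed as the Stokes shift (cm^-1) relative to the excitation laser line.
The two are linked by the standard identity

    shift [cm^-1] = 1e7 * (1/lambda_0 - 1/lambda),   lambda in nm,

with lambda_0 the excitation wavelength (532 nm for the instrument modelled
here).  All conversions use the vacuum-wavelength convention; no
air-refractive-index correction is applied (a sub-0.02% effect, irrelevant
at the ~0.33 nm channel width of a compact spectrometer).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "AxisKind",
    "SpectralAxis",
    "wavelength_to_shift",
    "shift_to_wavelength",
    "overlap_interval",
    "libs_axis_default",
    "raman_axis_default",
    "DEFAULT_EXCITATION_NM",
]

#: Excitation wavelength of the continuous-wave Raman laser, nm.
DEFAULT_EXCITATION_NM = 532.0

#: Native instrument grids: LIBS 2000 uniform wavelength channels over
#: 350-625 nm; Raman 600 uniform shift channels over 750-2800 cm^-1.
LIBS_RANGE_NM = (350.0, 625.0)
LIBS_CHANNELS = 2000
RAMAN_RANGE_CM1 = (750.0, 2800.0)
RAMAN_CHANNELS = 600


class AxisKind(str, Enum):
    wavelength_nm = "wavelength_nm"
    raman_shift_cm1 = "raman_shift_cm1"


def wavelength_to_shift(lambda_nm, excitation_nm: float = DEFAULT_EXCITATION_NM):
    """Convert absolute wavelength (nm) to Stokes Raman shift (cm^-1).

    Only the Stokes side (lambda >= excitation) is supported; anti-Stokes
    input raises ``ValueError``.  Accepts scalars or arrays.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    if excitation_nm <= 0 or not np.isfinite(excitation_nm):
        raise ValueError(f"excitation_nm must be finite and positive, got {excitation_nm}")
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0):
        raise ValueError("wavelengths must be finite and positive")
    if np.any(lam < excitation_nm):
        bad = float(np.min(lam))
        raise ValueError(
            f"anti-Stokes wavelength {bad} nm is below the excitation line "
            f"({excitation_nm} nm); only Stokes shifts are supported"
        )
    shift = 1e7 * (1.0 / excitation_nm - 1.0 / lam)
    return shift if shift.ndim else float(shift)


def shift_to_wavelength(shift_cm1, excitation_nm: float = DEFAULT_EXCITATION_NM):
    """Convert Stokes Raman shift (cm^-1) to absolute wavelength (nm).

    Exact inverse of :func:`wavelength_to_shift`.  The shift must be below
    the pole 1e7/excitation_nm (where the scattered wavelength diverges).
    """
    s = np.asarray(shift_cm1, dtype=float)
    if excitation_nm <= 0 or not np.isfinite(excitation_nm):
        raise ValueError(f"excitation_nm must be finite and positive, got {excitation_nm}")
    if not np.all(np.isfinite(s)) or np.any(s < 0):
        raise ValueError("shifts must be finite and non-negative")
    pole = 1e7 / excitation_nm
    if np.any(s >= pole):
        raise ValueError(
            f"shift {float(np.max(s))} cm^-1 is at or beyond the physical "
            f"limit 1e7/excitation = {pole:.1f} cm^-1"
        )
    lam = 1.0 / (1.0 / excitation_nm - s / 1e7)
    return lam if lam.ndim else float(lam)


@dataclass(frozen=True)
class SpectralAxis:
    """One modality's channel grid.

    Parameters
    ----------
    kind : AxisKind
        ``wavelength_nm`` (LIBS) or ``raman_shift_cm1`` (Raman).
    values : ndarray
        Strictly increasing, finite channel positions in the axis units.
    excitation_nm : float
        Excitation wavelength; required to map a shift axis onto the
        instrument's common wavelength scale.
    """

    kind: AxisKind
    values: np.ndarray
    excitation_nm: float = DEFAULT_EXCITATION_NM

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "kind", AxisKind(self.kind))
        if vals.ndim != 1:
            raise ValueError("axis values must be a 1-D vector")
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("axis values must be finite")
        if vals.size > 1 and not np.all(np.diff(vals) > 0):
            raise ValueError("axis values must be strictly increasing")
        if self.kind is AxisKind.raman_shift_cm1:
            if vals.size and np.any(vals < 0):
                raise ValueError("Raman-shift values must be non-negative")
            if self.excitation_nm is None or self.excitation_nm <= 0:
                raise ValueError("a shift axis requires a positive excitation_nm")

    def __len__(self) -> int:
        return self.values.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def to_wavelength_nm(self) -> np.ndarray:
        """Channel positions on the absolute wavelength scale (nm)."""
        if self.kind is AxisKind.wavelength_nm:
            return self.values.copy()
        return np.asarray(shift_to_wavelength(self.values, self.excitation_nm))


def overlap_interval(libs_axis: SpectralAxis, raman_axis: SpectralAxis) -> tuple[float, float] | None:
    """Wavelength interval (nm) where the two modalities share the detector.

    Maps the Raman shift span onto the wavelength scale via the excitation
    line and intersects it with the LIBS span.  Returns ``None`` when the
    spans do not meet (an empty overlap is a valid configuration, not an
    error).
    """
    if libs_axis.kind is not AxisKind.wavelength_nm:
        raise ValueError("libs_axis must be wavelength-kind")
    if raman_axis.kind is not AxisKind.raman_shift_cm1:
        raise ValueError("raman_axis must be raman-shift-kind")
    lo_l, hi_l = libs_axis.span
    lo_r = shift_to_wavelength(raman_axis.values[0], raman_axis.excitation_nm)
    hi_r = shift_to_wavelength(raman_axis.values[-1], raman_axis.excitation_nm)
    lo, hi = max(lo_l, lo_r), min(hi_l, hi_r)
    if lo > hi:
        return None
    return (float(lo), float(hi))


def libs_axis_default() -> SpectralAxis:
    """The instrument's native LIBS grid: 2000 channels over 350-625 nm."""
    return SpectralAxis(AxisKind.wavelength_nm, np.linspace(*LIBS_RANGE_NM, LIBS_CHANNELS))


def raman_axis_default(excitation_nm: float = DEFAULT_EXCITATION_NM) -> SpectralAxis:
    """The native Raman grid: 600 channels over 750-2800 cm^-1."""
    return SpectralAxis(
        AxisKind.raman_shift_cm1, np.linspace(*RAMAN_RANGE_CM1, RAMAN_CHANNELS), excitation_nm
    )
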