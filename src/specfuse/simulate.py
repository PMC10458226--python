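"""Synthetic hybrid Raman/LIBS data generator.

Real food spectra from hybrid instruments are rarely public, so the
analysis chain is exercised on a generator that emulates the statistical
structure such instruments produce:

* **LIBS**: Lorentzian atomic/molecular emission lines on a 2000-channel
  wavelength grid (350-625 nm) — the CN band (388.2 nm), Ca ionic
  (393.4 nm) and atomic (422.7 nm) lines, the C2 swan band (516.2 nm) and
  the Na D feature (588.9 nm) — over a constant offset, with strong
  elemental lines dominating the molecular bands.
* **Raman**: Gaussian bands on a 600-channel shift grid (750-2800 cm^-1
  relative to 532 nm excitation) — lipid-type bands for the cheese-like
  family (890/1287/1432/1670 cm^-1), phenolic-acid bands for the
  coffee-like family (1440/1570/1650 cm^-1) — over a smooth cubic
  fluorescence background.

Classes within a family share peak positions and differ only in per-peak
amplitude multipliers, mimicking foods whose dominant features are visibly
similar.  Complementarity is built in: half the classes carry their
identity mostly in the LIBS multipliers, the other half mostly in the
Raman multipliers, so that fusing the modalities demonstrably helps.
Within-class variation comes from a global multiplicative shot-to-shot
(plasma) fluctuation, a per-peak relative jitter, and additive detector
noise.  In simultaneous acquisition mode the Na emission line additionally
leaks into the Raman spectrum at its shift-equivalent position
(~1816 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .axes import (
    SpectralAxis, libs_axis_default, raman_axis_default,
    wavelength_to_shift, DEFAULT_EXCITATION_NM,
)
from .preprocess import Spectrum, Modality
from .fuse import SpectralDataset

__all__ = [
    "PeakShape", "PeakModel", "ClassProfile", "AcquisitionMode", "SimConfig",
    "generate_dataset", "ps_fixture", "class_profile_table",
    "LIBS_PEAK_TABLE", "RAMAN_BAND_TABLES",
]


class PeakShape(str, Enum):
    lorentzian = "lorentzian"
    gaussian = "gaussian"


class AcquisitionMode(str, Enum):
    sequential = "sequential"
    simultaneous = "simultaneous"


@dataclass(frozen=True)
class PeakModel:
    """A single spectral feature: Lorentzian emission line or Gaussian band.

    ``amplitude`` is the peak height (not area); the evaluated profile is
    symmetric about ``center`` and reaches half its maximum exactly at
    ``center +/- fwhm/2``.
    """

    center: float
    fwhm: float
    amplitude: float
    shape: PeakShape

    def __post_init__(self):
        object.__setattr__(self, "shape", PeakShape(self.shape))
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        half = self.fwhm / 2.0
        if self.shape is PeakShape.lorentzian:
            return self.amplitude * half**2 / ((x - self.center) ** 2 + half**2)
        # Gaussian parameterized by FWHM: exp(-4 ln2 (x-c)^2 / fwhm^2)
        return self.amplitude * np.exp(-4.0 * np.log(2.0) * (x - self.center) ** 2 / self.fwhm**2)


# Canonical line/band tables.  LIBS positions in nm: CN violet band head,
# Ca II / Ca I resonance lines, C2 swan band head, Na D doublet
# (unresolved at 0.33 nm).  Base amplitudes put the elemental Ca/Na lines
# well above the molecular bands, as observed in organic targets.
LIBS_FWHM_NM = 0.7
RAMAN_FWHM_CM1 = 12.0

LIBS_PEAK_TABLE: tuple[tuple[str, float, float], ...] = (
    ("CN", 388.2, 45.0),
    ("Ca_II", 393.4, 100.0),
    ("Ca_I", 422.7, 80.0),
    ("C2", 516.2, 35.0),
    ("Na", 588.9, 90.0),
)

RAMAN_BAND_TABLES: dict[str, tuple[tuple[str, float, float], ...]] = {
    # lipid-dominated family: phospholipid headgroup, CH2 twist,
    # CH2 scissoring, C=C stretch
    "cheese16": (
        ("phospholipid_head", 890.0, 50.0),
        ("CH2_twist", 1287.0, 60.0),
        ("CH2_scissor", 1432.0, 100.0),
        ("C=C_stretch", 1670.0, 70.0),
    ),
    # phenolic-acid family: CH3 deformation, two C=C stretches
    "coffee7": (
        ("CH3_deform", 1440.0, 100.0),
        ("C=C_1570", 1570.0, 60.0),
        ("C=C_1650", 1650.0, 65.0),
    ),
}

_FAMILY_CLASSES = {"cheese16": 16, "coffee7": 7}


@dataclass(frozen=True)
class ClassProfile:
    """Generative description of one class: shared peak tables plus the
    per-peak amplitude multipliers that encode class identity."""

    class_id: str
    libs_peaks: tuple[PeakModel, ...]
    raman_peaks: tuple[PeakModel, ...]
    libs_multipliers: np.ndarray
    raman_multipliers: np.ndarray

    def __post_init__(self):
        lm = np.asarray(self.libs_multipliers, dtype=float)
        rm = np.asarray(self.raman_multipliers, dtype=float)
        object.__setattr__(self, "libs_multipliers", lm)
        object.__setattr__(self, "raman_multipliers", rm)
        if lm.shape != (len(self.libs_peaks),) or rm.shape != (len(self.raman_peaks),):
            raise ValueError("one multiplier per peak is required")
        if np.any(lm <= 0) or np.any(rm <= 0):
            raise ValueError("multipliers must be positive")


@dataclass
class SimConfig:
    """Conditions of a simulated acquisition campaign.

    Defaults reproduce the study design emulated here: 100 replicate
    spectra per class, 16-class cheese-like or 7-class coffee-like
    families, sequential acquisition.  Noise parameters: ``noise_sd`` is
    the additive per-channel detector noise (default 1% of the largest
    peak amplitude), ``fluctuation_sd`` the log-normal sigma of the global
    multiplicative shot-to-shot plasma fluctuation, ``peak_jitter_sd`` the
    log-normal sigma of independent per-peak relative amplitude jitter
    within a class (shot-to-shot plasma chemistry / sampling-spot
    variation; this is what survives area normalization and sets the
    within-class difficulty).
    """

    family: str = "cheese16"
    n_classes: Optional[int] = None
    replicates_per_class: int = 100
    noise_sd: Optional[float] = None          # None -> 1% of max peak amplitude
    fluctuation_sd: float = 0.10
    between_sd_strong: float = 0.15
    # Family-resolved calibration (None -> per-family default): the weak-group
    # sigma must grow with the number of classes sharing it, the Raman sigmas
    # are scaled up because Raman carries fewer, broader bands, and the
    # within-class jitter shrinks slightly for the crowded 16-class family.
    peak_jitter_sd: Optional[float] = None    # cheese16: 0.035, coffee7: 0.045
    between_sd_weak: Optional[float] = None   # cheese16: 0.15,  coffee7: 0.08
    raman_sd_scale: Optional[float] = None    # cheese16: 1.3,   coffee7: 2.0
    complementarity_fraction: float = 0.5
    raman_baseline_coeffs: tuple = (0.30, -0.15, 0.10, -0.05)  # cubic in scaled axis, x max band
    libs_offset: float = 2.0
    mode: AcquisitionMode = AcquisitionMode.sequential
    seed: int = 0
    profiles: Optional[Sequence[ClassProfile]] = None  # required for family="custom"

    def __post_init__(self):
        self.mode = AcquisitionMode(self.mode)
        if self.family not in (*_FAMILY_CLASSES, "custom"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "custom":
            if self.profiles is None:
                raise ValueError("custom family requires explicit ClassProfiles")
            self.n_classes = len(self.profiles)
        else:
            fixed = _FAMILY_CLASSES[self.family]
            if self.n_classes is None:
                self.n_classes = fixed
            elif self.n_classes != fixed:
                raise ValueError(
                    f"family {self.family!r} fixes n_classes = {fixed}, got {self.n_classes}"
                )
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.replicates_per_class < 0:
            raise ValueError("replicates_per_class must be >= 0")
        if self.peak_jitter_sd is None:
            self.peak_jitter_sd = {"cheese16": 0.035, "coffee7": 0.045}.get(self.family, 0.04)
        if self.between_sd_weak is None:
            self.between_sd_weak = {"cheese16": 0.15, "coffee7": 0.08}.get(self.family, 0.08)
        if self.raman_sd_scale is None:
            self.raman_sd_scale = {"cheese16": 1.3, "coffee7": 2.0}.get(self.family, 2.0)


def _base_peaks(family: str) -> tuple[tuple[PeakModel, ...], tuple[PeakModel, ...]]:
    libs = tuple(
        PeakModel(center, LIBS_FWHM_NM, amp, PeakShape.lorentzian)
        for _, center, amp in LIBS_PEAK_TABLE
    )
    raman = tuple(
        PeakModel(center, RAMAN_FWHM_CM1, amp, PeakShape.gaussian)
        for _, center, amp in RAMAN_BAND_TABLES[family]
    )
    return libs, raman


def class_profile_table(
    family: str,
    seed: int = 0,
    between_sd_strong: float = 0.15,
    between_sd_weak: float = 0.08,
    complementarity_fraction: float = 0.5,
    raman_sd_scale: float = 2.0,
) -> list[ClassProfile]:
    """Frozen per-class amplitude multipliers for a dataset family.

    Multipliers are log-normal around 1.  The first
    ``complementarity_fraction`` of the classes are "LIBS-informative"
    (sigma = ``between_sd_strong`` in LIBS, ``between_sd_weak`` in Raman);
    the rest are Raman-informative with the sigmas swapped.  Deterministic
    given ``seed``.
    """
    if family == "custom":
        raise ValueError("custom family: supply ClassProfiles explicitly to SimConfig")
    if family not in _FAMILY_CLASSES:
        raise ValueError(f"unknown family {family!r}")
    n_classes = _FAMILY_CLASSES[family]
    libs_peaks, raman_peaks = _base_peaks(family)
    rng = np.random.default_rng(seed)
    n_libs_strong = int(round(complementarity_fraction * n_classes))
    profiles = []
    for c in range(n_classes):
        libs_sd, raman_sd = (
            (between_sd_strong, between_sd_weak)
            if c < n_libs_strong
            else (between_sd_weak, between_sd_strong)
        )
        lm = rng.lognormal(0.0, libs_sd, size=len(libs_peaks))
        rm = rng.lognormal(0.0, raman_sd_scale * raman_sd, size=len(raman_peaks))
        profiles.append(ClassProfile(f"{family}_class{c:02d}", libs_peaks, raman_peaks, lm, rm))
    return profiles


def _class_templates(profile: ClassProfile, config: SimConfig,
                     libs_axis: SpectralAxis, raman_axis: SpectralAxis):
    """Noise-free per-class peak sums (no baseline, unit fluctuation)."""
    libs = np.zeros(len(libs_axis))
    for m, peak in zip(profile.libs_multipliers, profile.libs_peaks):
        libs += m * peak(libs_axis.values)
    raman = np.zeros(len(raman_axis))
    for m, peak in zip(profile.raman_multipliers, profile.raman_peaks):
        raman += m * peak(raman_axis.values)
    if config.mode is AcquisitionMode.simultaneous:
        raman += _na_leak_line(profile).__call__(raman_axis.values)
    return libs, raman


def _na_line_index(profile: ClassProfile) -> int:
    centers = [p.center for p in profile.libs_peaks]
    return int(np.argmin(np.abs(np.asarray(centers) - 588.9)))


def _na_leak_line(profile: ClassProfile,
                  excitation_nm: float = DEFAULT_EXCITATION_NM) -> PeakModel:
    """The Na emission line mapped onto the Raman-shift axis.

    Width converts via the local derivative d(shift)/d(lambda) = 1e7/lambda^2.
    """
    i = _na_line_index(profile)
    na = profile.libs_peaks[i]
    center = wavelength_to_shift(na.center, excitation_nm)
    fwhm = na.fwhm * 1e7 / na.center**2
    amp = na.amplitude * profile.libs_multipliers[i]
    return PeakModel(center, fwhm, amp, PeakShape.lorentzian)


def _raman_baseline(config: SimConfig, raman_axis: SpectralAxis) -> np.ndarray:
    x = (raman_axis.values - raman_axis.values[0]) / (
        raman_axis.values[-1] - raman_axis.values[0]
    )
    coeffs = np.asarray(config.raman_baseline_coeffs, dtype=float)
    poly = sum(c * x**k for k, c in enumerate(coeffs))
    if config.family == "custom":
        max_band = max((p.amplitude for p in config.profiles[0].raman_peaks), default=1.0)
    else:
        max_band = max(amp for _, _, amp in RAMAN_BAND_TABLES[config.family])
    # shift so the background stays positive, scale to ~30% of largest band
    poly = poly - poly.min() + 0.1
    return max_band * poly


def generate_dataset(config: SimConfig) -> tuple[SpectralDataset, SpectralDataset]:
    """Simulate a full paired campaign: one LIBS and one Raman dataset.

    Row ``i`` of both outputs belongs to the same simulated specimen spot
    (the same per-replicate multiplier draws feed both modalities'
    shared factors where physically shared).  Pure function of
    ``config.seed``.
    """
    libs_axis = libs_axis_default()
    raman_axis = raman_axis_default()
    if config.family == "custom":
        profiles = list(config.profiles)
    else:
        profiles = class_profile_table(
            config.family, config.seed,
            config.between_sd_strong, config.between_sd_weak,
            config.complementarity_fraction, config.raman_sd_scale,
        )
        profiles = profiles[: config.n_classes]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F3C]))
    n_total = config.n_classes * config.replicates_per_class
    libs_mat = np.empty((n_total, len(libs_axis)))
    raman_mat = np.empty((n_total, len(raman_axis)))
    labels = np.empty(n_total, dtype=object)
    all_amps = [p.amplitude for prof in profiles for p in (*prof.libs_peaks, *prof.raman_peaks)]
    max_amp = max(all_amps) if all_amps else 1.0
    noise_sd = config.noise_sd if config.noise_sd is not None else 0.01 * max_amp
    raman_base = _raman_baseline(config, raman_axis)
    row = 0
    for prof in profiles:
        na_leak = (_na_leak_line(prof)
                   if config.mode is AcquisitionMode.simultaneous else None)
        libs_profiles = np.stack([p(libs_axis.values) / max(p.amplitude, 1e-300)
                                  for p in prof.libs_peaks]) if prof.libs_peaks else None
        raman_profiles = np.stack([p(raman_axis.values) / max(p.amplitude, 1e-300)
                                   for p in prof.raman_peaks]) if prof.raman_peaks else None
        # mean-one lognormals so class means converge to the clean template
        mu_f = -0.5 * config.fluctuation_sd**2
        mu_j = -0.5 * config.peak_jitter_sd**2
        for _ in range(config.replicates_per_class):
            g_libs = rng.lognormal(mu_f, config.fluctuation_sd)
            g_raman = rng.lognormal(mu_f, config.fluctuation_sd)
            j_libs = rng.lognormal(mu_j, config.peak_jitter_sd, size=len(prof.libs_peaks))
            j_raman = rng.lognormal(mu_j, config.peak_jitter_sd, size=len(prof.raman_peaks))
            libs_y = np.full(len(libs_axis), config.libs_offset)
            if libs_profiles is not None:
                amps = np.array([p.amplitude for p in prof.libs_peaks])
                libs_y += g_libs * (amps * prof.libs_multipliers * j_libs) @ libs_profiles
            raman_y = np.asarray(raman_base, dtype=float).copy() if np.ndim(raman_base) else np.full(len(raman_axis), float(raman_base))
            if raman_profiles is not None:
                amps = np.array([p.amplitude for p in prof.raman_peaks])
                raman_y += g_raman * (amps * prof.raman_multipliers * j_raman) @ raman_profiles
            if na_leak is not None:
                # the leak scales with the same plasma shot as the LIBS Na line
                i_na = _na_line_index(prof)
                raman_y += g_libs * j_libs[i_na] * na_leak(raman_axis.values)
            libs_y += rng.normal(0.0, noise_sd, size=len(libs_axis))
            raman_y += rng.normal(0.0, noise_sd, size=len(raman_axis))
            libs_mat[row] = libs_y
            raman_mat[row] = raman_y
            labels[row] = prof.class_id
            row += 1
    libs_ds = SpectralDataset(libs_mat, labels.copy(), Modality.libs, libs_axis)
    raman_ds = SpectralDataset(raman_mat, labels.copy(), Modality.raman, raman_axis)
    return libs_ds, raman_ds


# Polystyrene validation bands: ring breathing, C-C stretch, ring C=C
# stretch (cm^-1); LIBS shows the CN and C2 molecular bands plus a trace
# Na contamination line.
PS_RAMAN_BANDS = ((984.0, 60.0), (1158.0, 40.0), (1584.0, 100.0))
PS_LIBS_LINES = ((388.2, 60.0), (516.2, 45.0), (588.9, 80.0))


def ps_fixture(mode: AcquisitionMode | str = AcquisitionMode.sequential
               ) -> tuple[Spectrum, Spectrum]:
    """Noise-free polystyrene validation pair ``(raman, libs)``.

    Gaussian Raman bands at 984/1158/1584 cm^-1 and Lorentzian LIBS lines
    at 388.2/516.2/588.9 nm on the native grids.  In simultaneous mode the
    Na line is additionally injected into the Raman spectrum at its
    shift-equivalent position (~1816 cm^-1).
    """
    mode = AcquisitionMode(mode)
    raman_axis = raman_axis_default()
    libs_axis = libs_axis_default()
    raman_y = np.zeros(len(raman_axis))
    for center, amp in PS_RAMAN_BANDS:
        raman_y += PeakModel(center, RAMAN_FWHM_CM1, amp, PeakShape.gaussian)(raman_axis.values)
    libs_y = np.zeros(len(libs_axis))
    for center, amp in PS_LIBS_LINES:
        libs_y += PeakModel(center, LIBS_FWHM_NM, amp, PeakShape.lorentzian)(libs_axis.values)
    if mode is AcquisitionMode.simultaneous:
        na_center, na_amp = PS_LIBS_LINES[-1]
        shift_center = wavelength_to_shift(na_center)
        shift_fwhm = LIBS_FWHM_NM * 1e7 / na_center**2
        raman_y += PeakModel(shift_center, shift_fwhm, na_amp, PeakShape.lorentzian)(raman_axis.values)
    raman = Spectrum(raman_axis, raman_y, Modality.raman, label="PS",
                     meta={"mode": mode.value})
    libs = Spectrum(libs_axis, libs_y, Modality.libs, label="PS",
                    meta={"mode": mode.value})
    return raman, libs
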