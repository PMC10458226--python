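"""Data-fusion strategies for paired LIBS/Raman acquisitions.

Two complementary strategies are provided:

* **early fusion** (:func:`fuse_early`): the full preprocessed spectra of
  both modalities are assembled into one hybrid vector per specimen
  (2000 LIBS + 600 Raman = 2600 channels on the native grids) *before* any
  feature selection, which then operates jointly on the combined vector.
* **late fusion** (:func:`fuse_late`): each modality is filtered and
  selected independently; only the surviving channels are concatenated, so
  the fused width equals the sum of the per-modality mask sizes.

An optional overlap coaddition (:func:`coadd_overlap`) additionally sums
the two signals on a common wavelength grid inside the spectral interval
where the modalities share the detector; off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .axes import SpectralAxis, overlap_interval
from .preprocess import Modality

__all__ = ["CompositeAxis", "SpectralDataset", "fuse_early", "fuse_late", "coadd_overlap"]


@dataclass(frozen=True)
class CompositeAxis:
    """Per-channel provenance of a hybrid vector: origin modality and the
    channel's native coordinate (nm for LIBS, cm^-1 for Raman)."""

    origins: np.ndarray  # array of "libs" / "raman" strings
    coords: np.ndarray   # native axis value of each channel
    excitation_nm: float = 532.0

    def __post_init__(self):
        object.__setattr__(self, "origins", np.asarray(self.origins, dtype=object))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.origins.shape != self.coords.shape:
            raise ValueError("origins and coords must have equal length")

    def __len__(self) -> int:
        return self.origins.size

    def block(self, modality: str) -> np.ndarray:
        """Boolean mask of the channels originating from ``modality``."""
        return self.origins == modality


@dataclass(frozen=True)
class SpectralDataset:
    """A labelled matrix of spectra: one row per acquisition.

    ``axis`` is the shared :class:`SpectralAxis` for single-modality data
    or a :class:`CompositeAxis` for hybrid data.
    """

    matrix: np.ndarray
    labels: np.ndarray
    modality: Modality
    axis: SpectralAxis | CompositeAxis

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        lab = np.asarray(self.labels)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "modality", Modality(self.modality))
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x channels)")
        if lab.shape != (m.shape[0],):
            raise ValueError(
                f"label count {lab.shape} does not match row count {m.shape[0]}"
            )
        if m.size and not np.all(np.isfinite(m)):
            raise ValueError("dataset contains non-finite values")
        if self.axis is not None and len(self.axis) != m.shape[1]:
            raise ValueError(
                f"axis length {len(self.axis)} does not match channel count {m.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]

    def with_matrix(self, matrix: np.ndarray, axis=None) -> "SpectralDataset":
        return replace(self, matrix=np.asarray(matrix, dtype=float),
                       axis=self.axis if axis is None else axis)


def _check_paired(libs: SpectralDataset, raman: SpectralDataset) -> None:
    if libs.n_samples != raman.n_samples:
        raise ValueError(
            f"row counts differ: LIBS {libs.n_samples} vs Raman {raman.n_samples}"
        )
    mismatch = np.nonzero(libs.labels != raman.labels)[0]
    if mismatch.size:
        i = int(mismatch[0])
        raise ValueError(
            f"label mismatch at row {i}: LIBS {libs.labels[i]!r} vs Raman {raman.labels[i]!r}"
        )


def fuse_early(libs: SpectralDataset, raman: SpectralDataset) -> SpectralDataset:
    """Assemble one hybrid vector per specimen: LIBS block then Raman block.

    Rows must be paired (same specimen, identical labels).  The composite
    axis records each channel's origin modality and native coordinate so
    downstream selection can still be done per block.
    """
    _check_paired(libs, raman)
    hybrid = np.hstack([libs.matrix, raman.matrix])
    origins = np.concatenate(
        [np.full(libs.n_channels, "libs", dtype=object),
         np.full(raman.n_channels, "raman", dtype=object)]
    )
    coords = np.concatenate([
        libs.axis.values if libs.n_channels else np.empty(0),
        raman.axis.values if raman.n_channels else np.empty(0),
    ])
    excitation = getattr(raman.axis, "excitation_nm", 532.0)
    axis = CompositeAxis(origins, coords, excitation)
    return SpectralDataset(hybrid, libs.labels.copy(), Modality.hybrid, axis)


def fuse_late(masks_and_matrices: Sequence[tuple]) -> tuple[np.ndarray, "object"]:
    """Concatenate per-modality *selected* feature blocks.

    Parameters
    ----------
    masks_and_matrices : sequence of (FeatureMask, SpectralDataset)
        Each mask indexes its own dataset's channels; datasets must hold
        paired rows in the same order.

    Returns
    -------
    (matrix, mask) : the fused feature matrix (width = sum of mask sizes)
        and a combined :class:`~specfuse.select.FeatureMask` whose
        provenance records (modality, native channel index) per column.
    """
    from .select import FeatureMask  # local import to avoid a cycle

    if not masks_and_matrices:
        raise ValueError("need at least one (mask, dataset) pair")
    datasets = [ds for _, ds in masks_and_matrices]
    n = datasets[0].n_samples
    for a, b in zip(datasets, datasets[1:]):
        _check_paired_labels(a, b)
    blocks, origin = [], []
    for mask, ds in masks_and_matrices:
        idx = np.asarray(mask.indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= ds.n_channels):
            raise ValueError(
                f"mask index out of range for {ds.modality.value} "
                f"({ds.n_channels} channels)"
            )
        blocks.append(ds.matrix[:, idx])
        origin.extend((ds.modality.value, int(j)) for j in idx)
    fused = np.hstack(blocks) if blocks else np.empty((n, 0))
    total = fused.shape[1]
    combined = FeatureMask(
        indices=np.arange(total), provenance="manual", source_dims=total,
        channel_origin=tuple(origin),
    )
    return fused, combined


def _check_paired_labels(a: SpectralDataset, b: SpectralDataset) -> None:
    if a.n_samples != b.n_samples:
        raise ValueError("datasets have different row counts")
    mismatch = np.nonzero(a.labels != b.labels)[0]
    if mismatch.size:
        raise ValueError(f"label mismatch at row {int(mismatch[0])}")


def coadd_overlap(libs: SpectralDataset, raman: SpectralDataset,
                  n_grid: int = 200) -> SpectralDataset:
    """Sum the two signals on a common wavelength grid inside the overlap.

    Sensitivity-analysis variant: both modalities are linearly interpolated
    onto ``n_grid`` wavelength points spanning the overlap interval and
    added channel-wise.  Returns an empty-width dataset when the spans do
    not overlap.
    """
    _check_paired(libs, raman)
    interval = overlap_interval(libs.axis, raman.axis)
    if interval is None:
        return SpectralDataset(np.empty((libs.n_samples, 0)), libs.labels.copy(),
                               Modality.hybrid,
                               CompositeAxis(np.empty(0, object), np.empty(0)))
    grid = np.linspace(interval[0], interval[1], n_grid)
    lam_libs = libs.axis.values
    lam_raman = raman.axis.to_wavelength_nm()
    out = np.empty((libs.n_samples, n_grid))
    for i in range(libs.n_samples):
        out[i] = (np.interp(grid, lam_libs, libs.matrix[i])
                  + np.interp(grid, lam_raman, raman.matrix[i]))
    axis = CompositeAxis(np.full(n_grid, "coadd", dtype=object), grid,
                         getattr(raman.axis, "excitation_nm", 532.0))
    return SpectralDataset(out, libs.labels.copy(), Modality.hybrid, axis)
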