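"""Readers/writers for spectral tables, run configuration, and the
end-to-end pipeline orchestrator.

The primary interchange layout is a **wide** CSV: comment lines carry the
axis metadata (``# axis=wavelength_nm`` or ``raman_shift_cm1``,
``# excitation_nm=532``, ``# modality=...``), the header row is ``label``
followed by the axis values, and each subsequent row is one spectrum.  A
**long** layout (sample_id, axis_value, intensity, label) is supported for
single spectra and tidy-tools interoperability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .axes import SpectralAxis, AxisKind
from .preprocess import Modality, preprocess_matrix
from .fuse import SpectralDataset, fuse_early
from .simulate import SimConfig, AcquisitionMode, generate_dataset
from .select import FeatureMask
from .classify import PipelineConfig, CVResult, repeated_cv, summarize_many

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_dataset", "write_dataset", "read_mask",
           "write_mask", "run_pipeline"]


def write_dataset(dataset: SpectralDataset, path) -> None:
    """Write a single-modality dataset in the wide CSV layout."""
    path = Path(path)
    axis = dataset.axis
    if not isinstance(axis, SpectralAxis):
        raise ValueError("only single-modality datasets round-trip through wide CSV")
    with open(path, "w") as fh:
        fh.write(f"# modality={dataset.modality.value}\n")
        fh.write(f"# axis={axis.kind.value}\n")
        if axis.kind is AxisKind.raman_shift_cm1:
            fh.write(f"# excitation_nm={axis.excitation_nm:g}\n")
        fh.write("label," + ",".join(f"{v:.6f}" for v in axis.values) + "\n")
        for label, row in zip(dataset.labels, dataset.matrix):
            fh.write(str(label) + "," + ",".join(f"{v:.10g}" for v in row) + "\n")


def read_dataset(path, layout: str = "wide") -> SpectralDataset:
    """Read a spectral table; validates finiteness and axis ordering.

    An unsorted axis is auto-sorted with a warning; NaN/inf intensities
    raise with the offending row named.
    """
    path = Path(path)
    if layout not in ("wide", "long"):
        raise ValueError(f"unknown layout {layout!r}")
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    if layout == "long":
        df = pd.read_csv(path, comment="#")
        required = {"sample_id", "axis_value", "intensity", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"long layout needs columns {sorted(required)}")
        return _long_to_dataset(df, meta)
    header = lines[body_start].rstrip("\n").split(",")
    if header[0] != "label":
        raise ValueError("wide layout: first header column must be 'label'")
    axis_vals = np.array([float(v) for v in header[1:]])
    df = pd.read_csv(path, comment="#", skiprows=body_start + 1,
                     header=None, names=header)
    labels = df["label"].to_numpy()
    matrix = df.iloc[:, 1:].to_numpy(dtype=float)
    bad = np.nonzero(~np.all(np.isfinite(matrix), axis=1))[0]
    if bad.size:
        raise ValueError(f"non-finite intensity in data row {int(bad[0])}")
    order = np.argsort(axis_vals)
    if not np.array_equal(order, np.arange(axis_vals.size)):
        logger.warning("axis not sorted in %s; auto-sorting", path)
        axis_vals = axis_vals[order]
        matrix = matrix[:, order]
    kind = AxisKind(meta.get("axis", "wavelength_nm"))
    excitation = float(meta.get("excitation_nm", 532.0))
    axis = SpectralAxis(kind, axis_vals, excitation)
    modality = Modality(meta.get("modality",
                                 "raman" if kind is AxisKind.raman_shift_cm1 else "libs"))
    return SpectralDataset(matrix, labels, modality, axis)


def _long_to_dataset(df: pd.DataFrame, meta: dict) -> SpectralDataset:
    if not np.all(np.isfinite(df["intensity"].to_numpy(dtype=float))):
        bad = int(np.nonzero(~np.isfinite(df["intensity"].to_numpy(dtype=float)))[0][0])
        raise ValueError(f"non-finite intensity in long-layout row {bad}")
    wide = df.pivot_table(index="sample_id", columns="axis_value",
                          values="intensity", sort=True)
    labels = df.groupby("sample_id")["label"].first().loc[wide.index].to_numpy()
    kind = AxisKind(meta.get("axis", "wavelength_nm"))
    excitation = float(meta.get("excitation_nm", 532.0))
    axis = SpectralAxis(kind, wide.columns.to_numpy(dtype=float), excitation)
    modality = Modality(meta.get("modality",
                                 "raman" if kind is AxisKind.raman_shift_cm1 else "libs"))
    return SpectralDataset(wide.to_numpy(dtype=float), labels, modality, axis)


def write_mask(mask: FeatureMask, path) -> None:
    pd.DataFrame({"index": mask.indices,
                  "provenance": mask.provenance}).to_csv(path, index=False)


def read_mask(path, source_dims: int) -> FeatureMask:
    df = pd.read_csv(path)
    prov = str(df["provenance"].iloc[0]) if len(df) else "manual"
    return FeatureMask(df["index"].to_numpy(dtype=int), prov, source_dims)


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: dict = field(default_factory=dict)   # kwargs of preprocess_spectrum
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    inputs: tuple = ("raman", "libs", "fusion1", "fusion2")
    folds: int = 10
    sessions: int = 10
    seed_base: int = 1
    outdir: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.sessions < 1:
            raise ValueError("sessions must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        bad = set(self.inputs) - {"raman", "libs", "fusion1", "fusion2"}
        if bad:
            raise ValueError(f"unknown input settings: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["mode"] = self.sim.mode.value
        d["sim"].pop("profiles", None)
        return json.loads(json.dumps(d))  # normalize tuples to lists

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig(**d["sim"])
        if "pipeline" in d:
            d["pipeline"] = PipelineConfig(**d["pipeline"])
        if "inputs" in d:
            d["inputs"] = tuple(d["inputs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _preprocessed_inputs(config: RunConfig) -> dict[str, SpectralDataset]:
    """Simulate, preprocess (with line subtraction if simultaneous), fuse."""
    from .peaks import fit_lorentzian, subtract_line
    from .preprocess import Spectrum
    from .axes import wavelength_to_shift

    libs, raman = generate_dataset(config.sim)
    logger.info("simulate: %d LIBS x %d ch, %d Raman x %d ch",
                libs.n_samples, libs.n_channels, raman.n_samples, raman.n_channels)
    if config.sim.mode is AcquisitionMode.simultaneous:
        # remove the Na emission leak from each Raman spectrum (raw space)
        target = wavelength_to_shift(588.9, raman.axis.excitation_nm)
        window = (target - 60.0, target + 60.0)
        cleaned = raman.matrix.copy()
        for i in range(raman.n_samples):
            s = Spectrum(raman.axis, cleaned[i], Modality.raman)
            try:
                line = fit_lorentzian(s, window)
                cleaned[i] = subtract_line(s, line).intensities
            except (ValueError, RuntimeError):
                pass  # no detectable leak in this spectrum
        raman = raman.with_matrix(cleaned)
        logger.info("subtract-line: Na leak removed around %.1f cm^-1", target)
    raman_p = raman.with_matrix(
        preprocess_matrix(raman.matrix, raman.axis, Modality.raman, **config.preprocess))
    libs_p = libs.with_matrix(
        preprocess_matrix(libs.matrix, libs.axis, Modality.libs, **config.preprocess))
    logger.info("preprocess: done (baseline/denoise/normalize/transform)")
    out: dict[str, SpectralDataset] = {}
    for name in config.inputs:
        if name == "raman":
            out[name] = raman_p
        elif name == "libs":
            out[name] = libs_p
        else:
            out[name] = fuse_early(libs_p, raman_p)
    return out


def run_pipeline(config: RunConfig) -> dict[str, CVResult]:
    """Full orchestration: simulate -> preprocess -> fuse -> evaluate.

    Returns one :class:`CVResult` per configured input setting
    (``raman``, ``libs``, ``fusion1`` = per-modality selection then
    concatenation, ``fusion2`` = joint selection on the hybrid vector).
    Writes summary tables, per-session confusion matrices, and a JSON
    manifest when ``config.outdir`` is set.
    """
    datasets = _preprocessed_inputs(config)
    seeds = list(range(config.seed_base, config.seed_base + config.sessions))
    results: dict[str, CVResult] = {}
    for name, ds in datasets.items():
        cfg = dataclasses.replace(
            config.pipeline, strategy="late" if name == "fusion1" else "single")
        logger.info("evaluate %s: %d x %d", name, ds.n_samples, ds.n_channels)
        results[name] = repeated_cv(ds, cfg, k=config.folds,
                                    sessions=config.sessions, seeds=seeds)
        logger.info("evaluate %s: macro %.2f%% (%.2f)", name,
                    100 * results[name].mean_accuracy,
                    100 * results[name].sd_accuracy)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summarize_many(results).to_csv(outdir / "summary.csv")
        for name, res in results.items():
            for s, cm in enumerate(res.confusions):
                pd.DataFrame(cm, index=res.classes, columns=res.classes).to_csv(
                    outdir / f"confusion_{name}_session{s}.csv")
        manifest = {"package_version": __version__, "seeds": seeds,
                    "config": config.to_dict()}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return results
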