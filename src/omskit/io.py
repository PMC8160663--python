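"""File formats, run configuration, and the end-to-end pipeline.

Spectra travel as a single flat CSV: metadata columns first (id, batch,
sample, position, replicate, time, role, and reference targets prefixed
``y_``), then one column per wavelength with the numeric axis value as
header.  The run configuration is a strict (unknown keys rejected) YAML
document with one block per stage; a single seed drives every stochastic
step, so identical configs produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import calibrate, channels, design, preprocess, simulate

__all__ = [
    "read_spectra",
    "write_spectra",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

_META_ORDER = list(simulate.META_COLUMNS)


def write_spectra(sset: simulate.SpectraSet, path) -> None:
    meta = sset.meta.copy()
    cols = [c for c in _META_ORDER if c in meta.columns]
    cols += [c for c in meta.columns if c.startswith("y_")]
    frame = meta[cols].copy()
    spec = pd.DataFrame(sset.X, columns=[f"{v:.10g}" for v in sset.axis])
    pd.concat([frame.reset_index(drop=True), spec], axis=1).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_spectra(path) -> simulate.SpectraSet:
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty spectra file: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"spectra file has no measurements: {path}")
    meta_cols, axis_vals, axis_cols = [], [], []
    for c in df.columns:
        if c in _META_ORDER or c.startswith("y_"):
            meta_cols.append(c)
            continue
        try:
            axis_vals.append(float(c))
            axis_cols.append(c)
        except ValueError as exc:
            raise ValueError(f"unrecognized column {c!r} in {path}") from exc
    if "id" not in meta_cols:
        raise ValueError("mandatory metadata column 'id' is missing")
    axis = np.asarray(axis_vals)
    if len(axis) > 1:
        d = np.diff(axis)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength axis columns are not monotone")
    meta = df[meta_cols].copy()
    for c in _META_ORDER:
        if c not in meta.columns:
            meta[c] = np.nan if c == "time" else ("train" if c == "role" else 0)
    return simulate.SpectraSet(axis=axis, X=df[axis_cols].to_numpy(float), meta=meta)


# ---------------------------------------------------------------------------
# Run configuration


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignBlock(_Strict):
    designation: str
    ranges: list[tuple[float, float]]
    directions: list[str] | None = None


class BandBlock(_Strict):
    center: float
    fwhm: float
    amplitude: float


class SimulateBlock(_Strict):
    components: list[list[BandBlock]]
    scatter_amplitude: float = 0.0
    scatter_exponent: float = 1.0
    noise_replicate: float = 0.0
    noise_position: float = 0.0
    noise_sample: float = 0.0
    n_positions: int = 1
    n_replicates: int = 1
    axis_start: float = 400.0
    axis_stop: float = 1100.0
    axis_step: float = 5.0


class ChannelsBlock(_Strict):
    target: str
    population_size: int = 16
    generations: int = 15
    n_restarts: int = 1
    n_channels_min: int = 2
    n_channels_max: int = 3
    width_min: float = 10.0
    width_max: float = 80.0
    shape: str = "boxcar"


class CalibrateBlock(_Strict):
    model_type: str = "mlr"
    n_lv: int | None = None
    levels: list[str] = Field(default_factory=lambda: ["sample"])


class RunConfig(_Strict):
    seed: int
    out_dir: str
    design: DesignBlock
    simulate: SimulateBlock
    channels: ChannelsBlock
    calibrate: CalibrateBlock = CalibrateBlock()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, log=None) -> dict[str, str]:
    """Design -> simulate -> channel optimization -> calibration -> validation.

    Writes design.csv, spectra.csv, channels.json, validation.csv to
    ``out_dir`` and returns {artifact: sha256-prefix}; a structured log
    line (timestamp, stage, key=value) is emitted per stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines: list[str] = []

    def _log(stage: str, **kv) -> None:
        stamp = _time.strftime("%Y-%m-%dT%H:%M:%S")
        msg = f"{stamp} {stage} " + " ".join(f"{k}={v}" for k, v in kv.items())
        lines.append(msg)
        if log is not None:
            log(msg)

    spec = design.parse_designation(config.design.designation)
    scheme = design.scheme_from_spec(spec)
    mapping = design.FactorMapping(
        bounds=tuple(tuple(r) for r in config.design.ranges),
        directions=tuple(config.design.directions)
        if config.design.directions
        else None,
    )
    conc = design.to_concentrations(scheme, mapping)
    design_path = out / "design.csv"
    design.write_design(scheme, design_path, conc)
    _log("design", designation=spec.designation, n_samples=scheme.n_samples)

    sb = config.simulate
    comps = [
        simulate.ComponentSpectrum(
            tuple(simulate.GaussianBand(b.center, b.fwhm, b.amplitude) for b in bands)
        )
        for bands in sb.components
    ]
    axis = np.arange(sb.axis_start, sb.axis_stop + sb.axis_step / 2, sb.axis_step)
    sset = simulate.mixture_spectra(
        conc,
        comps,
        scatter=simulate.ScatterModel(sb.scatter_amplitude, sb.scatter_exponent),
        noise=simulate.NoiseHierarchy(
            sample=sb.noise_sample,
            position=sb.noise_position,
            replicate=sb.noise_replicate,
        ),
        seed=config.seed,
        axis=axis,
        n_positions=sb.n_positions,
        n_replicates=sb.n_replicates,
        roles=scheme.roles,
    )
    spectra_path = out / "spectra.csv"
    write_spectra(sset, spectra_path)
    _log("simulate", n_measurements=sset.n_measurements, seed=config.seed)

    cb = config.channels
    ga = channels.GAParams(
        population_size=cb.population_size,
        generations=cb.generations,
        n_restarts=cb.n_restarts,
        n_channels=(cb.n_channels_min, cb.n_channels_max),
        width_bounds=(cb.width_min, cb.width_max),
        shape=cb.shape,
        seed=config.seed,
    )
    mb = config.calibrate
    result = channels.ga_optimize(
        sset, cb.target, ga, model_type=mb.model_type, n_lv=mb.n_lv
    )
    channels_path = out / "channels.json"
    channels_path.write_text(
        json.dumps(
            {
                "channels": [
                    {"center": c.center, "width": c.width, "shape": c.shape}
                    for c in result.chromosome.channels
                ],
                "rmsec": result.rmsec,
                "rmsecv": result.rmsecv,
            },
            indent=2,
        )
    )
    _log("channels", n=len(result.chromosome.channels), rmsecv=f"{result.rmsecv:.6g}")

    R = channels.apply_channels(sset, list(result.chromosome.channels))
    y = sset.target(cb.target)
    hierarchy = {
        lvl: _level_labels(sset, lvl) for lvl in mb.levels
    }
    report = calibrate.nested_validation(
        R,
        y,
        hierarchy,
        model_type=mb.model_type,
        n_lv=mb.n_lv,
        test_mask=sset.meta["role"].to_numpy() == "test",
    )
    validation_path = out / "validation.csv"
    report.to_frame().to_csv(validation_path, index=False)
    _log(
        "validate",
        rmsec=f"{report.rmsec:.6g}",
        loocv=f"{report.loocv:.6g}",
        rmsep="" if report.rmsep is None else f"{report.rmsep:.6g}",
    )

    hashes = {
        p.name: _hash_file(p)
        for p in (design_path, spectra_path, channels_path, validation_path)
    }
    _log("artifacts", **hashes)
    (out / "run.log").write_text("\n".join(lines) + "\n")
    return hashes


def _level_labels(sset: simulate.SpectraSet, level: str) -> np.ndarray:
    """Composite segment labels so finer levels nest inside coarser ones."""
    order = ["batch", "sample", "position", "replicate"]
    if level not in order:
        raise ValueError(f"unknown hierarchy level {level!r}")
    keys = order[: order.index(level) + 1]
    return (
        sset.meta[keys].astype(str).agg("/".join, axis=1).to_numpy()
    )
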