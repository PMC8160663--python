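"""Seeded synthetic-spectra generators.

Everything downstream (preprocessing, channel optimization, calibration,
kinetics, trajectory monitoring) can be exercised on data produced here:
Beer-Lambert mixture spectra with Gaussian component bands, a
wavelength-dependent scatter baseline emulating particle-size effects,
hierarchical measurement noise (replicate within position within sample
within batch), multiplicative intensity turbulence for process series,
two-class spectra for discrimination, and dissolution profiles drawn from
the release-kinetics model.

Every generator is a pure function of its parameters and a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics

__all__ = [
    "GaussianBand",
    "ComponentSpectrum",
    "ScatterModel",
    "NoiseHierarchy",
    "SpectraSet",
    "DissolutionBatch",
    "default_axis",
    "mixture_spectra",
    "process_series",
    "two_class_spectra",
    "dissolution_batches",
]

#: Visible / short-wave NIR working region, 1 nm step.
DEFAULT_AXIS_NM = (400.0, 1100.0, 1.0)

META_COLUMNS = ("id", "batch", "sample", "position", "replicate", "time", "role")


def default_axis() -> np.ndarray:
    lo, hi, step = DEFAULT_AXIS_NM
    return np.arange(lo, hi + step / 2, step)


@dataclass(frozen=True)
class GaussianBand:
    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("band FWHM must be > 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("band amplitude must be finite")


@dataclass(frozen=True)
class ComponentSpectrum:
    """Pure-component absorptivity as a sum of Gaussian bands."""

    bands: tuple[GaussianBand, ...]

    def epsilon(self, axis: np.ndarray) -> np.ndarray:
        eps = np.zeros_like(axis, dtype=float)
        for b in self.bands:
            eps += b.amplitude * np.exp(
                -4.0 * np.log(2.0) * ((axis - b.center) / b.fwhm) ** 2
            )
        return eps


@dataclass(frozen=True)
class ScatterModel:
    """Smooth wavelength-dependent baseline a * (lambda/lambda_min)^-p.

    ``particle_size_proxy`` in [0, 1] mimics the homogenization degree:
    smaller particles (proxy -> 1) scatter with a stronger wavelength
    dependence and higher amplitude.  This is an emulation, not
    light-scattering physics.
    """

    amplitude: float = 0.0
    exponent: float = 1.0
    particle_size_proxy: float = 0.0

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ValueError("scatter exponent must be >= 0")
        if not 0.0 <= self.particle_size_proxy <= 1.0:
            raise ValueError("particle_size_proxy must be in [0, 1]")

    def baseline(self, axis: np.ndarray) -> np.ndarray:
        a_eff = self.amplitude * (1.0 + self.particle_size_proxy)
        p_eff = self.exponent * (1.0 + 2.0 * self.particle_size_proxy)
        return a_eff * (axis / axis[0]) ** (-p_eff)


@dataclass(frozen=True)
class NoiseHierarchy:
    """Additive Gaussian noise sds per hierarchy level.

    Batch/sample/position effects are scalar offsets shared by the whole
    spectrum of the group; replicate noise is per-channel i.i.d.  The
    multiplicative sd applies only to time series (process turbulence).
    """

    batch: float = 0.0
    sample: float = 0.0
    position: float = 0.0
    replicate: float = 0.0
    multiplicative: float = 0.0

    def __post_init__(self) -> None:
        for name in ("batch", "sample", "position", "replicate", "multiplicative"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise sd {name} must be >= 0")


NOISELESS = NoiseHierarchy()


@dataclass
class SpectraSet:
    """Measurements x channels matrix with axis and hierarchical metadata.

    ``meta`` carries id / batch / sample / position / replicate / time /
    role columns plus reference values prefixed ``y_``.  ``col_blocks``
    optionally tags each column with a block label after multi-block
    augmentation.
    """

    axis: np.ndarray
    X: np.ndarray
    meta: pd.DataFrame
    col_blocks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (measurements x channels)")
        d = np.diff(self.axis)
        if len(self.axis) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavelength axis must be strictly monotone")
        if self.X.shape[1] != len(self.axis):
            raise ValueError(
                f"X has {self.X.shape[1]} columns but axis has {len(self.axis)}"
            )
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("metadata rows must match measurement rows")

    @property
    def n_measurements(self) -> int:
        return self.X.shape[0]

    @property
    def target_names(self) -> list[str]:
        return [c for c in self.meta.columns if c.startswith("y_")]

    def target(self, name: str) -> np.ndarray:
        key = name if name.startswith("y_") else f"y_{name}"
        return self.meta[key].to_numpy(dtype=float)

    def with_X(self, X: np.ndarray, axis: np.ndarray | None = None) -> "SpectraSet":
        return SpectraSet(
            axis=self.axis if axis is None else axis,
            X=X,
            meta=self.meta.copy(),
            col_blocks=self.col_blocks,
        )

    def subset(self, mask: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            axis=self.axis,
            X=self.X[mask],
            meta=self.meta.loc[mask].reset_index(drop=True),
            col_blocks=self.col_blocks,
        )


def _meta_frame(n: int, **columns) -> pd.DataFrame:
    base = {
        "id": np.arange(n),
        "batch": np.zeros(n, dtype=int),
        "sample": np.zeros(n, dtype=int),
        "position": np.zeros(n, dtype=int),
        "replicate": np.zeros(n, dtype=int),
        "time": np.full(n, np.nan),
        "role": np.array(["train"] * n, dtype=object),
    }
    base.update(columns)
    return pd.DataFrame(base)


def mixture_spectra(
    concentrations: np.ndarray,
    components: list[ComponentSpectrum],
    scatter: ScatterModel = ScatterModel(),
    noise: NoiseHierarchy = NOISELESS,
    seed: int | None = None,
    axis: np.ndarray | None = None,
    n_positions: int = 1,
    n_replicates: int = 1,
    roles: np.ndarray | None = None,
    target_names: list[str] | None = None,
) -> SpectraSet:
    """Beer-Lambert forward model: A = C @ E + baseline + noise.

    One design row (a *sample*) yields n_positions * n_replicates
    measurement rows with hierarchical noise effects.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    C = np.asarray(concentrations, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if not components:
        raise ValueError("component list must not be empty")
    if C.shape[1] != len(components):
        raise ValueError(
            f"{C.shape[1]} concentration columns != {len(components)} components"
        )
    if np.any(C < 0):
        raise ValueError("negative concentrations are not allowed")
    if axis is None:
        axis = default_axis()
    rng = np.random.default_rng(seed)

    E = np.vstack([c.epsilon(axis) for c in components])  # (m, n_wl)
    pure = C @ E + scatter.baseline(axis)[None, :]

    n_samples = C.shape[0]
    names = target_names or [f"y_{i + 1}" for i in range(len(components))]
    names = [n if n.startswith("y_") else f"y_{n}" for n in names]

    rows, meta_rows = [], []
    sample_eff = rng.normal(0.0, noise.sample, size=n_samples)
    rid = 0
    for s in range(n_samples):
        pos_eff = rng.normal(0.0, noise.position, size=n_positions)
        for p in range(n_positions):
            for r in range(n_replicates):
                spec = (
                    pure[s]
                    + sample_eff[s]
                    + pos_eff[p]
                    + rng.normal(0.0, noise.replicate, size=len(axis))
                )
                rows.append(spec)
                meta_rows.append((rid, 0, s, p, r))
                rid += 1
    X = np.vstack(rows)
    n = X.shape[0]
    meta = _meta_frame(
        n,
        id=np.array([m[0] for m in meta_rows]),
        batch=np.array([m[1] for m in meta_rows]),
        sample=np.array([m[2] for m in meta_rows]),
        position=np.array([m[3] for m in meta_rows]),
        replicate=np.array([m[4] for m in meta_rows]),
    )
    sample_idx = meta["sample"].to_numpy()
    for j, name in enumerate(names):
        meta[name] = C[sample_idx, j]
    if roles is not None:
        meta["role"] = np.asarray(roles, dtype=object)[sample_idx]
    return SpectraSet(axis=axis, X=X, meta=meta)


def process_series(
    trajectory_fn,
    n_times: int,
    turbulence_sd: float,
    seed: int | None = None,
    components: list[ComponentSpectrum] | None = None,
    scatter: ScatterModel = ScatterModel(),
    axis: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> SpectraSet:
    """Time-ordered spectra with multiplicative intensity turbulence.

    Each time point's noiseless spectrum is scaled by exp(N(0, sd^2)),
    emulating total-intensity fluctuations in fluidized-bed processes.
    Running with turbulence_sd = 0 recovers the noiseless series.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if n_times < 1:
        raise ValueError("n_times must be >= 1")
    if turbulence_sd < 0:
        raise ValueError("turbulence_sd must be >= 0")
    if components is None:
        raise ValueError("component list must not be empty")
    if axis is None:
        axis = default_axis()
    if times is None:
        times = np.arange(n_times, dtype=float)
    rng = np.random.default_rng(seed)

    E = np.vstack([c.epsilon(axis) for c in components])
    base = scatter.baseline(axis)
    C = np.vstack([np.atleast_1d(trajectory_fn(t)) for t in times]).astype(float)
    pure = C @ E + base[None, :]
    factors = np.exp(rng.normal(0.0, turbulence_sd, size=n_times))
    X = pure * factors[:, None]

    meta = _meta_frame(n_times, time=times, sample=np.arange(n_times))
    for j in range(C.shape[1]):
        meta[f"y_{j + 1}"] = C[:, j]
    return SpectraSet(axis=axis, X=X, meta=meta)


def two_class_spectra(
    n_per_class: int,
    class_effect: float,
    noise: NoiseHierarchy = NOISELESS,
    seed: int | None = None,
    components: list[ComponentSpectrum] | None = None,
    effect_band: GaussianBand | None = None,
    axis: np.ndarray | None = None,
    n_positions: int = 2,
    n_replicates: int = 2,
) -> SpectraSet:
    """Two-class spectra (labels 0/1) for discriminant analysis.

    Class 1 gains an extra band of amplitude ``class_effect``; hierarchy
    sample -> position -> replicate is present so segmented CV by
    position or sample is meaningful.  Label column: ``y_class``.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if axis is None:
        axis = default_axis()
    if components is None:
        components = [
            ComponentSpectrum((GaussianBand(650.0, 120.0, 1.0),)),
        ]
    if effect_band is None:
        effect_band = GaussianBand(900.0, 80.0, 1.0)
    rng = np.random.default_rng(seed)

    base = np.sum([c.epsilon(axis) for c in components], axis=0)
    effect = class_effect * ComponentSpectrum((effect_band,)).epsilon(axis)

    rows, meta_rows = [], []
    rid = 0
    for label in (0, 1):
        for s in range(n_per_class):
            s_eff = rng.normal(0.0, noise.sample)
            for p in range(n_positions):
                p_eff = rng.normal(0.0, noise.position)
                for r in range(n_replicates):
                    spec = (
                        base
                        + (effect if label == 1 else 0.0)
                        + s_eff
                        + p_eff
                        + rng.normal(0.0, noise.replicate, size=len(axis))
                    )
                    rows.append(spec)
                    meta_rows.append((rid, label * n_per_class + s, p, r, label))
                    rid += 1
    X = np.vstack(rows)
    meta = _meta_frame(
        X.shape[0],
        id=np.array([m[0] for m in meta_rows]),
        sample=np.array([m[1] for m in meta_rows]),
        position=np.array([m[2] for m in meta_rows]),
        replicate=np.array([m[3] for m in meta_rows]),
    )
    meta["y_class"] = np.array([m[4] for m in meta_rows])
    return SpectraSet(axis=axis, X=X, meta=meta)


@dataclass
class DissolutionBatch:
    """One batch's dissolution table plus its spectrally linked feature."""

    times: np.ndarray
    phi: np.ndarray
    k_true: float
    m_true: float
    feature: float


def dissolution_batches(
    n_batches: int,
    m_true: float,
    k_range: tuple[float, float],
    noise_sd: float,
    link_coefficients: tuple[float, float] = (0.0, 1.0),
    seed: int | None = None,
    times: np.ndarray | None = None,
) -> list[DissolutionBatch]:
    """Simulated release profiles sharing m, with per-batch k.

    k varies across batches (emulating coating thickness) and maps
    linearly onto a spectral feature: feature = a + b * k, noiseless, so
    the link coefficients are exactly recoverable by least squares.
    phi values are the kinetic-model curve plus Gaussian noise truncated
    to [0, 100].
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    if m_true <= 0:
        raise ValueError("m_true must be > 0")
    klo, khi = k_range
    if klo <= 0 or khi < klo:
        raise ValueError("k_range must be positive with low <= high")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.linspace(0.0, 30.0, 12)
    a, b = link_coefficients

    batches = []
    for _ in range(n_batches):
        k = float(rng.uniform(klo, khi))
        phi = kinetics.release_fraction(times, m_true, k)
        phi = phi + rng.normal(0.0, noise_sd, size=len(times))
        phi = np.clip(phi, 0.0, 100.0)
        batches.append(
            DissolutionBatch(
                times=times.copy(),
                phi=phi,
                k_true=k,
                m_true=m_true,
                feature=a + b * k,
            )
        )
    return batches
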