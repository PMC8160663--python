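"""Spectral and time-domain preprocessing operators.

All operators take and return :class:`~omskit.simulate.SpectraSet` and are
measurement-wise independent except :func:`moving_average_time`, which
couples rows along the time axis.  The catalogue covers reference
normalization to absorbance, reference-free internal normalization by a
comparison channel, SNV, Savitzky-Golay smoothing/derivatives, moving
averaging in the time domain, and multi-block augmentation, plus a
combinatorial search ranking candidate preprocessing pipelines by a
validation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .simulate import SpectraSet

__all__ = [
    "PreprocStep",
    "PreprocSpec",
    "reference_absorbance",
    "internal_normalization",
    "moving_average_time",
    "snv",
    "derivative",
    "augment_blocks",
    "apply_spec",
    "combinatorial_search",
]


def reference_absorbance(sset: SpectraSet, reference_spectrum: np.ndarray) -> SpectraSet:
    """Convert intensities to absorbance: A = -log10(I / I_ref)."""
    ref = np.asarray(reference_spectrum, dtype=float)
    if ref.shape != sset.axis.shape:
        raise ValueError("reference spectrum must match the wavelength axis")
    bad = np.where(ref <= 0)[0]
    if bad.size:
        raise ValueError(
            f"reference is non-positive at channel {sset.axis[bad[0]]:g}"
        )
    nonpos = np.argwhere(sset.X <= 0)
    if nonpos.size:
        r, c = nonpos[0]
        raise ValueError(
            f"non-positive intensity in measurement {sset.meta['id'].iloc[r]} "
            f"at channel {sset.axis[c]:g}"
        )
    return sset.with_X(-np.log10(sset.X / ref[None, :]))


def internal_normalization(sset: SpectraSet, comparison_channel: float) -> SpectraSet:
    """Reference-free normalization by one of the set's own channels.

    Each measurement is divided by its own comparison-channel intensity
    and log10-transformed, which makes the output invariant to any
    per-measurement multiplicative gain (source intensity fluctuations,
    probe coupling).
    """
    idx = int(np.argmin(np.abs(sset.axis - comparison_channel)))
    if abs(sset.axis[idx] - comparison_channel) > np.ptp(sset.axis):
        raise ValueError(f"comparison channel {comparison_channel} not on the axis")
    comp = sset.X[:, idx]
    zero = np.where(comp == 0)[0]
    if zero.size:
        raise ValueError(
            "zero comparison-channel value in measurement "
            f"{sset.meta['id'].iloc[zero[0]]}"
        )
    ratio = sset.X / comp[:, None]
    if np.any(ratio <= 0):
        raise ValueError("intensity ratios must be positive for the log transform")
    return sset.with_X(np.log10(ratio))


def moving_average_time(sset: SpectraSet, window: int) -> SpectraSet:
    """Moving-average smoothing of each channel along the time axis.

    Edges use shrinking symmetric windows (no padding), so the output has
    the same length as the input and window 1 is the identity.  Interior
    points of a white-noise series of variance sigma^2 come out with
    variance ~ sigma^2 / window.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    t = sset.meta["time"].to_numpy(dtype=float)
    if np.any(np.isnan(t)):
        raise ValueError("time metadata required for time-domain smoothing")
    if np.any(np.diff(t) < 0):
        raise ValueError("measurements must be sorted by time")
    n = sset.n_measurements
    h = window // 2
    out = np.empty_like(sset.X)
    for i in range(n):
        half = min(h, i, n - 1 - i)
        out[i] = sset.X[i - half : i + half + 1].mean(axis=0)
    return sset.with_X(out)


def snv(sset: SpectraSet) -> SpectraSet:
    """Standard normal variate: each spectrum centered and scaled to sd 1."""
    mu = sset.X.mean(axis=1, keepdims=True)
    sd = sset.X.std(axis=1, ddof=1, keepdims=True)
    flat = np.where(sd.ravel() == 0)[0]
    if flat.size:
        raise ValueError(
            f"constant spectrum (sd = 0) in measurement "
            f"{sset.meta['id'].iloc[flat[0]]}"
        )
    return sset.with_X((sset.X - mu) / sd)


def derivative(sset: SpectraSet, order: int, window: int, degree: int) -> SpectraSet:
    """Savitzky-Golay smoothing (order 0) or derivative along wavelength."""
    if order not in (0, 1, 2):
        raise ValueError("derivative order must be 0, 1, or 2")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    n_chan = sset.X.shape[1]
    if n_chan < window:
        raise ValueError(
            f"too few channels ({n_chan}) for Savitzky-Golay window {window}; "
            "spectral smoothing is inapplicable on few-channel data"
        )
    if degree >= window:
        raise ValueError("polynomial degree must be < window")
    step = float(np.mean(np.diff(sset.axis))) if len(sset.axis) > 1 else 1.0
    out = savgol_filter(
        sset.X, window_length=window, polyorder=degree, deriv=order,
        delta=abs(step), axis=1,
    )
    return sset.with_X(out)


def augment_blocks(
    blocks: list[SpectraSet], scaling: str = "none"
) -> SpectraSet:
    """Concatenate multi-method blocks of the same measurements column-wise.

    Blocks must share measurement ids in the same order.  ``scaling``:
    'none'; 'block_snv' (center each block by its grand mean and scale by
    its pooled sd); 'unit_total_variance' (divide each block by the square
    root of its summed column variances, so every block contributes total
    variance 1).  Block provenance is kept in ``col_blocks``; if the
    concatenated axis is not strictly monotone, a synthetic column index
    axis is used.
    """
    if not blocks:
        raise ValueError("no blocks to augment")
    if scaling not in ("none", "block_snv", "unit_total_variance"):
        raise ValueError(f"unknown scaling {scaling!r}")
    ids0 = blocks[0].meta["id"].to_numpy()
    for b in blocks[1:]:
        if not np.array_equal(b.meta["id"].to_numpy(), ids0):
            raise ValueError("blocks must share measurement ids and ordering")

    mats, axes, labels = [], [], []
    for bi, b in enumerate(blocks):
        X = b.X.astype(float)
        if scaling == "block_snv":
            mu = X.mean()
            sd = X.std(ddof=1)
            if sd == 0:
                raise ValueError(f"block {bi} is constant; cannot scale")
            X = (X - mu) / sd
        elif scaling == "unit_total_variance":
            tv = X.var(axis=0, ddof=1).sum()
            if tv == 0:
                raise ValueError(f"block {bi} has zero variance; cannot scale")
            X = X / np.sqrt(tv)
        mats.append(X)
        axes.append(b.axis)
        labels.extend([bi] * X.shape[1])

    X = np.hstack(mats)
    axis = np.concatenate(axes)
    d = np.diff(axis)
    if len(axis) > 1 and not np.all(d > 0):
        axis = np.arange(len(axis), dtype=float)
    return SpectraSet(
        axis=axis,
        X=X,
        meta=blocks[0].meta.copy(),
        col_blocks=np.array(labels),
    )


@dataclass(frozen=True)
class PreprocStep:
    name: str
    params: dict = field(default_factory=dict)

    _CATALOGUE = (
        "reference_absorbance",
        "internal_normalization",
        "snv",
        "derivative",
        "moving_average_time",
        "identity",
    )

    def __post_init__(self) -> None:
        if self.name not in self._CATALOGUE:
            raise ValueError(f"unknown preprocessing operator {self.name!r}")


@dataclass(frozen=True)
class PreprocSpec:
    """An ordered preprocessing pipeline; applied order is list order."""

    steps: tuple[PreprocStep, ...] = ()

    def describe(self) -> str:
        if not self.steps:
            return "identity"
        return " | ".join(
            s.name + (f"({s.params})" if s.params else "") for s in self.steps
        )


def apply_spec(spec: PreprocSpec, sset: SpectraSet) -> SpectraSet:
    out = sset
    for step in spec.steps:
        if step.name == "identity":
            continue
        elif step.name == "reference_absorbance":
            out = reference_absorbance(out, **step.params)
        elif step.name == "internal_normalization":
            out = internal_normalization(out, **step.params)
        elif step.name == "snv":
            out = snv(out)
        elif step.name == "derivative":
            out = derivative(out, **step.params)
        elif step.name == "moving_average_time":
            out = moving_average_time(out, **step.params)
    return out


def combinatorial_search(
    candidates: list[PreprocSpec],
    sset: SpectraSet,
    target: str,
    validator,
) -> pd.DataFrame:
    """Evaluate every candidate pipeline with the same validator and rank.

    ``validator(processed_set, target) -> float`` must hold model settings
    and the validation split fixed, so the ranking isolates preprocessing.
    Candidates failing with a ValueError (e.g. guards on channel counts)
    are ranked last with an infinite error.  Ties break by candidate
    order, so the ranking is deterministic.
    """
    if not candidates:
        raise ValueError("candidate list must not be empty")
    rows = []
    for i, cand in enumerate(candidates):
        try:
            err = float(validator(apply_spec(cand, sset), target))
        except ValueError:
            err = np.inf
        rows.append((i, cand.describe(), err))
    df = pd.DataFrame(rows, columns=["candidate", "pipeline", "error"])
    df = df.sort_values(["error", "candidate"], kind="stable").reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df
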