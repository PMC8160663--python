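"""Multivariate calibration: MLR / PLS regression, PLS-DA classification,
multilevel (nested) validation, latent-variable selection, and
slope-and-bias model transfer.

MLR is ordinary least squares with an intercept, appropriate for the few
uncorrelated channels of an optimized multisensor; PLS extracts latent
variables on centered (not autoscaled) data and is the tool of choice on
full-spectrum data.  Validation goes beyond leave-one-out CV: segmented
CV holds out whole segments of the experimental hierarchy (replicate,
position, sample, batch), which probes model stability against each
variability source, and the built-in test set of the diagonal design
provides independent test-set validation (RMSEP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "CalibrationModel",
    "ValidationReport",
    "ConfusionStats",
    "fit",
    "predict",
    "rmse",
    "cross_val_rmse",
    "nested_validation",
    "select_n_lv",
    "pls_da",
    "classify",
    "confusion",
    "slope_bias_transfer",
    "make_loocv_validator",
]


@dataclass
class CalibrationModel:
    model_type: str  # 'mlr' | 'pls' | 'pls_da'
    coef: np.ndarray
    intercept: float
    n_lv: int | None = None
    preproc: object | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef + self.intercept


def fit(
    X: np.ndarray,
    y: np.ndarray,
    model_type: str = "mlr",
    n_lv: int | None = None,
) -> CalibrationModel:
    """Fit an MLR or PLS model. Deterministic given input order.

    MLR requires full column rank (duplicated or collinear channels raise
    with advice); PLS extracts ``n_lv`` latent variables by NIPALS on
    centered data (no autoscaling: the channels share units and scaling
    would amplify noise channels).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X rows must match y length")
    n, p = X.shape
    if model_type == "mlr":
        Xc = X - X.mean(axis=0)
        rank = np.linalg.matrix_rank(Xc)
        if rank < min(n - 1, p) or p >= n:
            raise ValueError(
                f"rank-deficient design ({rank} < {p} channels, n={n}): "
                "use PLS or reduce the channel set"
            )
        coef, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        intercept = float(y.mean() - X.mean(axis=0) @ coef)
        return CalibrationModel("mlr", coef, intercept)
    if model_type in ("pls", "pls_da"):
        max_lv = min(n - 1, p)
        if n_lv is None or not 1 <= n_lv <= max_lv:
            raise ValueError(
                f"n_lv must be in [1, {max_lv}] for {n} samples x {p} channels"
            )
        pls = PLSRegression(n_components=n_lv, scale=False)
        pls.fit(X, y)
        coef = pls.coef_.ravel()
        # fold the training-mean centering into an explicit intercept
        intercept = float(y.mean() - X.mean(axis=0) @ coef)
        return CalibrationModel(model_type, coef, intercept, n_lv=n_lv)
    raise ValueError(f"unknown model_type {model_type!r}")


def predict(model: CalibrationModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def rmse(y, y_hat) -> float:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y) == 0 or len(y) != len(y_hat):
        raise ValueError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def _fold_indices(segments: np.ndarray) -> list[np.ndarray]:
    """Deterministic leave-one-segment-out folds (sorted segment labels)."""
    labels = sorted(pd.unique(segments), key=lambda v: str(v))
    return [np.where(segments == lab)[0] for lab in labels]


def cross_val_rmse(
    X: np.ndarray,
    y: np.ndarray,
    segments: np.ndarray | None = None,
    model_type: str = "mlr",
    n_lv: int | None = None,
) -> float:
    """RMSECV leaving out whole segments (LOOCV when segments are None)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if segments is None:
        segments = np.arange(len(y))
    segments = np.asarray(segments)
    folds = _fold_indices(segments)
    if len(folds) < 2:
        raise ValueError(
            "cross-validation needs at least 2 segments at this level"
        )
    resid = np.empty_like(y)
    for idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[idx] = False
        model = fit(X[mask], y[mask], model_type=model_type, n_lv=n_lv)
        resid[idx] = y[idx] - model.predict(X[idx])
    return float(np.sqrt(np.mean(resid**2)))


@dataclass
class ValidationReport:
    rmsec: float
    loocv: float
    scv: dict[str, float] = field(default_factory=dict)
    rmsep: float | None = None
    bias: float | None = None
    segment_errors: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [("RMSEC", self.rmsec), ("LOOCV", self.loocv)]
        rows += [(f"SCV@{lvl}", v) for lvl, v in self.scv.items()]
        if self.rmsep is not None:
            rows.append(("RMSEP", self.rmsep))
        if self.bias is not None:
            rows.append(("bias", self.bias))
        return pd.DataFrame(rows, columns=["statistic", "value"])


def _check_nested(hierarchy: dict[str, np.ndarray]) -> None:
    levels = list(hierarchy)
    for coarse, fine in zip(levels, levels[1:]):
        fine_lab = hierarchy[fine]
        coarse_lab = hierarchy[coarse]
        df = pd.DataFrame({"f": fine_lab, "c": coarse_lab})
        if (df.groupby("f")["c"].nunique() > 1).any():
            raise ValueError(
                f"hierarchy not nested: level {fine!r} labels map to multiple "
                f"{coarse!r} labels"
            )


def nested_validation(
    X: np.ndarray,
    y: np.ndarray,
    hierarchy: dict[str, np.ndarray],
    model_type: str = "mlr",
    n_lv: int | None = None,
    test_mask: np.ndarray | None = None,
) -> ValidationReport:
    """Multilevel validation: RMSEC, LOOCV, SCV per hierarchy level, RMSEP.

    ``hierarchy`` maps level name -> per-row segment labels, ordered
    coarse to fine (e.g. sample, position, replicate); each finer label
    must nest inside exactly one coarser label.  Segments are never split
    across CV folds.  Rows flagged by ``test_mask`` are excluded from
    calibration and cross-validation and scored as RMSEP.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    hierarchy = {k: np.asarray(v) for k, v in hierarchy.items()}
    for lvl, lab in hierarchy.items():
        if len(lab) != len(y):
            raise ValueError(f"hierarchy level {lvl!r} has wrong length")
    _check_nested(hierarchy)

    if test_mask is None:
        test_mask = np.zeros(len(y), dtype=bool)
    else:
        test_mask = np.asarray(test_mask, dtype=bool)
    train = ~test_mask

    model = fit(X[train], y[train], model_type=model_type, n_lv=n_lv)
    rmsec = rmse(y[train], model.predict(X[train]))
    loocv = cross_val_rmse(X[train], y[train], None, model_type, n_lv)

    scv, seg_rows = {}, []
    for lvl, lab in hierarchy.items():
        unique_train = pd.unique(lab[train])
        if len(unique_train) < 2:
            raise ValueError(
                f"level {lvl!r} has a single segment; cannot cross-validate"
            )
        scv[lvl] = cross_val_rmse(X[train], y[train], lab[train], model_type, n_lv)
        seg_rows.append((lvl, len(unique_train), scv[lvl]))

    rmsep = bias = None
    if test_mask.any():
        y_hat = model.predict(X[test_mask])
        rmsep = rmse(y[test_mask], y_hat)
        bias = float(np.mean(y_hat - y[test_mask]))

    return ValidationReport(
        rmsec=rmsec,
        loocv=loocv,
        scv=scv,
        rmsep=rmsep,
        bias=bias,
        segment_errors=pd.DataFrame(
            seg_rows, columns=["level", "n_segments", "rmsecv"]
        ),
    )


def select_n_lv(
    X: np.ndarray,
    y: np.ndarray,
    test_mask: np.ndarray,
    max_lv: int,
    tolerance: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Choose the PLS latent-variable count with the built-in test set.

    The smallest n_lv whose RMSEP lies within ``tolerance`` (relative) of
    the minimum over 1..max_lv wins — the parsimony rule.  Returns the
    choice and the full RMSEP-versus-LV curve.
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    test_mask = np.asarray(test_mask, dtype=bool)
    if not test_mask.any() or test_mask.all():
        raise ValueError("a non-trivial built-in test set is required")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    train = ~test_mask
    cap = min(max_lv, min(train.sum() - 1, X.shape[1]))
    rows = []
    import warnings

    for lv in range(1, cap + 1):
        with warnings.catch_warnings():
            # scanning past the data rank is expected here
            warnings.filterwarnings("ignore", message="y residual is constant")
            model = fit(X[train], y[train], "pls", n_lv=lv)
        rows.append((lv, rmse(y[test_mask], model.predict(X[test_mask]))))
    curve = pd.DataFrame(rows, columns=["n_lv", "rmsep"])
    best = curve["rmsep"].min()
    chosen = int(
        curve.loc[curve["rmsep"] <= best * (1 + tolerance), "n_lv"].iloc[0]
    )
    return chosen, curve


# ---------------------------------------------------------------------------
# PLS-DA


@dataclass
class ConfusionStats:
    """Binary confusion counts and the derived percentages.

    Percentages carry the raw value; ``*_pct_int`` are rounded half-up for
    display.  A statistic whose denominator is zero is None (undefined),
    never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den > 0 else None

    @staticmethod
    def _round_half_up(x: float | None) -> int | None:
        return None if x is None else int(math.floor(x + 0.5))

    @property
    def sn_pct(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def sp_pct(self) -> float | None:
        return self._pct(self.tn, self.fp + self.tn)

    @property
    def ac_pct(self) -> float | None:
        return self._pct(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def sn_pct_int(self) -> int | None:
        return self._round_half_up(self.sn_pct)

    @property
    def sp_pct_int(self) -> int | None:
        return self._round_half_up(self.sp_pct)

    @property
    def ac_pct_int(self) -> int | None:
        return self._round_half_up(self.ac_pct)


def pls_da(X: np.ndarray, labels: np.ndarray, n_lv: int) -> CalibrationModel:
    """PLS-DA: PLS regression on the 0/1 class coding."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("training labels must contain both classes 0 and 1")
    return fit(X, labels.astype(float), "pls_da", n_lv=n_lv)


def classify(model: CalibrationModel, X: np.ndarray) -> np.ndarray:
    """Assign class 1 when the predicted value is >= the 0.5 boundary."""
    return (model.predict(X) >= 0.5).astype(int)


def confusion(labels_true, labels_pred) -> ConfusionStats:
    t = np.asarray(labels_true).astype(int)
    p = np.asarray(labels_pred).astype(int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionStats(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


# ---------------------------------------------------------------------------
# Model transfer


def slope_bias_transfer(slave_predictions, references):
    """Slope-and-bias correction mapping slave predictions onto references.

    Returns (slope, bias, corrector) where corrector(y_hat) = slope*y_hat
    + bias is applied to future slave predictions.  Requires >= 2 transfer
    standards with distinct slave predictions.
    """
    s = np.asarray(slave_predictions, dtype=float).ravel()
    r = np.asarray(references, dtype=float).ravel()
    if len(s) != len(r) or len(s) < 2:
        raise ValueError("at least 2 paired transfer standards are required")
    if np.ptp(s) == 0:
        raise ValueError("slave predictions have zero variance")
    slope, bias = np.polyfit(s, r, 1)
    slope, bias = float(slope), float(bias)

    def corrector(y_hat):
        return slope * np.asarray(y_hat, dtype=float) + bias

    return slope, bias, corrector


# ---------------------------------------------------------------------------
# Validator factories (injected into the GA and the preprocessing search)


def make_loocv_validator(model_type: str = "mlr", n_lv: int | None = None):
    """LOOCV validator over a reduced matrix: (X, y) -> RMSECV."""

    def validator(X, y):
        return cross_val_rmse(X, y, None, model_type, n_lv)

    return validator
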