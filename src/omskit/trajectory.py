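"""Process-trajectory projection and monitoring.

A process is followed as the time-ordered projection of its measurements
into a low-dimensional analytical space — PCA scores of historical normal
batches, or predictions of calibration models (one per axis).  The
"normal process course" region is delimited by a Hotelling T-squared
limit on the scores plus a residual (Q) limit, the standard multivariate
statistical process-control convention.  Monitoring classifies each
incoming point as inside/outside after optional moving-average smoothing
of the score series, raises an alarm on the first excursion, and flags
the end-point when the smoothed point enters a user-supplied target box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .simulate import SpectraSet

__all__ = [
    "TrajectoryModel",
    "TrajectoryPoint",
    "fit_trajectory_model",
    "monitor",
]


@dataclass
class TrajectoryModel:
    """Projection basis plus normal-region limits.

    For PCA axes the loadings are orthonormal; the T-squared limit and
    residual limit are each taken at confidence (1 + c)/2 so that the
    combined in-control false-alarm rate is bounded by 1 - c.
    """

    kind: str  # 'pca' | 'predictions'
    mean: np.ndarray
    loadings: np.ndarray | None  # (p, n_comp) for pca
    models: list | None  # calibration models for prediction axes
    score_var: np.ndarray | None  # per-component training score variance
    t2_limit: float
    q_limit: float
    confidence: float
    axis: np.ndarray | None = None
    smoothing_window: int = 1

    @property
    def n_components(self) -> int:
        if self.kind == "pca":
            return self.loadings.shape[1]
        return len(self.models)

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.kind == "pca":
            return (X - self.mean) @ self.loadings
        return np.column_stack([m.predict(X) for m in self.models])

    def residual_ss(self, X: np.ndarray) -> np.ndarray:
        if self.kind != "pca":
            return np.zeros(len(X))
        Xc = np.asarray(X, dtype=float) - self.mean
        recon = (Xc @ self.loadings) @ self.loadings.T
        return np.sum((Xc - recon) ** 2, axis=1)

    def t_squared(self, scores: np.ndarray) -> np.ndarray:
        if self.score_var is None:
            return np.zeros(len(scores))
        return np.sum(scores**2 / self.score_var, axis=1)


@dataclass
class TrajectoryPoint:
    time: float
    scores: np.ndarray
    t2: float
    q: float
    inside_normal: bool
    end_point_reached: bool


def fit_trajectory_model(
    historical: SpectraSet,
    axes: str | list = "pca",
    n_components: int = 2,
    confidence: float = 0.95,
    smoothing_window: int = 1,
) -> TrajectoryModel:
    """Fit the projection and normal-region limits on normal batches.

    ``axes='pca'`` projects onto the first ``n_components`` principal
    components; a list of calibration models uses one prediction per
    axis.  The T-squared limit uses the F-distribution form for a future
    observation; the residual limit is the training-residual quantile.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    X = historical.X
    n = X.shape[0]
    # Bonferroni split of the two tests
    conf_each = 1.0 - (1.0 - confidence) / 2.0

    if axes == "pca":
        if n <= n_components:
            raise ValueError(
                f"{n} training samples cannot support {n_components} components"
            )
        pca = PCA(n_components=n_components)
        scores = pca.fit_transform(X)
        loadings = pca.components_.T
        mean = pca.mean_
        score_var = scores.var(axis=0, ddof=1)
        score_var = np.maximum(score_var, np.finfo(float).tiny)
        a = n_components
        f_crit = stats.f.ppf(conf_each, a, n - a)
        t2_limit = a * (n**2 - 1) / (n * (n - a)) * f_crit
        resid = np.sum((X - mean - scores @ loadings.T) ** 2, axis=1)
        q_limit = float(np.quantile(resid, conf_each)) if resid.max() > 0 else 0.0
        return TrajectoryModel(
            kind="pca",
            mean=mean,
            loadings=loadings,
            models=None,
            score_var=score_var,
            t2_limit=float(t2_limit),
            q_limit=q_limit,
            confidence=confidence,
            axis=historical.axis,
            smoothing_window=smoothing_window,
        )

    models = list(axes)
    preds = np.column_stack([m.predict(X) for m in models])
    mean = preds.mean(axis=0)
    score_var = np.maximum(preds.var(axis=0, ddof=1), np.finfo(float).tiny)
    a = preds.shape[1]
    if n <= a:
        raise ValueError("not enough samples for the prediction axes")
    f_crit = stats.f.ppf(conf_each, a, n - a)
    t2_limit = a * (n**2 - 1) / (n * (n - a)) * f_crit
    model = TrajectoryModel(
        kind="predictions",
        mean=np.zeros(X.shape[1]),
        loadings=None,
        models=models,
        score_var=score_var,
        t2_limit=float(t2_limit),
        q_limit=0.0,
        confidence=confidence,
        axis=historical.axis,
        smoothing_window=smoothing_window,
    )
    model.pred_center = mean  # centering for T2 on prediction axes
    return model


def _smooth(series: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return series
    n = len(series)
    h = window // 2
    out = np.empty_like(series)
    for i in range(n):
        half = min(h, i, n - 1 - i)
        out[i] = series[i - half : i + half + 1].mean(axis=0)
    return out


def monitor(
    model: TrajectoryModel,
    stream: SpectraSet,
    end_criteria: dict[int, tuple[float, float]] | None = None,
) -> list[TrajectoryPoint]:
    """Classify a time-ordered stream against the normal region.

    Scores are optionally smoothed with the model's moving-average
    window before the inside/outside test (raw excursions smoothed away
    are thereby ignored, matching how noisy process trajectories are
    read).  ``end_criteria`` maps score-axis index -> (low, high); the
    end-point flag is set once the smoothed point falls in the box.
    """
    if model.axis is not None and not np.array_equal(stream.axis, model.axis):
        raise ValueError("stream wavelength axis does not match the model")
    t = stream.meta["time"].to_numpy(dtype=float)
    if np.any(np.isnan(t)):
        t = np.arange(stream.n_measurements, dtype=float)

    scores = model.scores(stream.X)
    if model.kind == "predictions":
        scores_c = scores - model.pred_center
    else:
        scores_c = scores
    q = model.residual_ss(stream.X)

    scores_s = _smooth(scores_c, model.smoothing_window)
    q_s = _smooth(q, model.smoothing_window)
    t2 = model.t_squared(scores_s)

    points = []
    reached = False
    for i in range(len(t)):
        inside = bool(t2[i] <= model.t2_limit and q_s[i] <= model.q_limit + 1e-12) \
            if model.kind == "pca" else bool(t2[i] <= model.t2_limit)
        raw_scores = scores[i]
        if end_criteria is not None and not reached:
            smoothed_abs = scores_s[i] + (
                model.pred_center if model.kind == "predictions" else 0.0
            )
            reached = all(
                lo <= smoothed_abs[ax] <= hi
                for ax, (lo, hi) in end_criteria.items()
            )
        points.append(
            TrajectoryPoint(
                time=float(t[i]),
                scores=raw_scores,
                t2=float(t2[i]),
                q=float(q_s[i]),
                inside_normal=inside,
                end_point_reached=reached,
            )
        )
    return points


def points_to_frame(points: list[TrajectoryPoint]) -> pd.DataFrame:
    rows = []
    for p in points:
        row = {"time": p.time, "t2": p.t2, "q": p.q,
               "inside_normal": p.inside_normal,
               "end_point_reached": p.end_point_reached}
        for j, s in enumerate(np.atleast_1d(p.scores)):
            row[f"score_{j + 1}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
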