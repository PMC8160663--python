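"""Dissolution (API release) kinetics.

The released fraction phi (%) versus time follows an autocatalysis-like
two-constant law

    phi(t, m, k) = 100 k (e^{(m+k)t} - 1) / (m + k e^{(m+k)t})

where m sets the release rate (slope, a property of the coating material)
and k the induction delay (related to coating thickness).  phi(0) = 0,
phi is strictly increasing, and phi -> 100 as t -> infinity.

Fitting is nonlinear least squares in (log m, log k) so positivity holds
by construction; a Gaussian prior on log m turns the fit into a MAP
estimate, which is the engine of the successive Bayesian estimation over
process batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ReleaseKinetics",
    "release_fraction",
    "fit_release",
    "sequential_bayes",
    "feed_forward_profile",
]


@dataclass
class ReleaseKinetics:
    """Fitted release constants with covariance in (log m, log k) space."""

    m_slope: float
    k_induction: float
    covariance: np.ndarray  # 2x2, log-parameter space

    def __post_init__(self) -> None:
        if self.m_slope <= 0 or self.k_induction <= 0:
            raise ValueError("release constants must be > 0")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("covariance must be 2x2")
        eig = np.linalg.eigvalsh((cov + cov.T) / 2)
        if np.any(eig < -1e-10):
            raise ValueError("covariance must be positive semidefinite")
        self.covariance = cov


def release_fraction(t, m: float, k: float) -> np.ndarray | float:
    """Released fraction in percent at time(s) t.

    Evaluated as 100 k (1 - e^{-(m+k)t}) / (m e^{-(m+k)t} + k), which is
    numerically stable for large (m+k)t (no overflow; the asymptote 100 is
    reached smoothly).
    """
    if m <= 0 or k <= 0:
        raise ValueError("m and k must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    e = np.exp(-(m + k) * t_arr)
    phi = 100.0 * k * (1.0 - e) / (m * e + k)
    return phi if t_arr.ndim else float(phi)


_START_GRID = [-3.0, -1.5, 0.0, 1.5]  # log-parameter multi-start offsets


def _residuals(theta, times, phis, prior):
    m, k = math.exp(theta[0]), math.exp(theta[1])
    res = release_fraction(times, m, k) - phis
    if prior is not None:
        mu, sd = prior  # prior on log m only
        res = np.append(res, (theta[0] - mu) / sd)
    return res


def fit_release(
    times,
    phis,
    prior: ReleaseKinetics | None = None,
    prior_m_only: bool = True,
) -> ReleaseKinetics:
    """Fit (m, k) to a dissolution table by (penalized) least squares.

    With no prior this is plain NLS with a multi-start grid in log
    parameters.  A prior adds the Gaussian penalty on log m implied by the
    prior covariance (MAP estimate); k is always re-estimated freely when
    ``prior_m_only`` (the material constant is m, while k tracks coating
    thickness batch by batch).  The reported covariance comes from the
    Jacobian at the optimum.
    """
    times = np.asarray(times, dtype=float)
    phis = np.asarray(phis, dtype=float)
    if times.shape != phis.shape:
        raise ValueError("times and phis must have equal length")
    if len(times) < 3:
        raise ValueError("at least 3 points are required to fit two constants")
    if np.any((phis < -1e-9) | (phis > 100 + 1e-9)):
        raise ValueError("phi values must lie in [0, 100]")
    if np.ptp(phis) == 0:
        raise ValueError("degenerate data: all phi values equal")

    prior_term = None
    if prior is not None:
        sd_logm = math.sqrt(max(prior.covariance[0, 0], 1e-12))
        prior_term = (math.log(prior.m_slope), sd_logm)
        if not prior_m_only:
            raise NotImplementedError("only the shared-m prior is supported")

    best = None
    base = np.array([math.log(0.1), math.log(0.1)])
    for dm in _START_GRID:
        for dk in _START_GRID:
            x0 = base + np.array([dm, dk])
            if prior_term is not None:
                x0[0] = prior_term[0]
            try:
                sol = least_squares(
                    _residuals,
                    x0,
                    args=(times, phis, prior_term),
                    method="lm" if prior_term is None else "trf",
                    max_nfev=2000,
                )
            except Exception:
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise RuntimeError("release fit did not converge from any start point")

    n_data = len(times)
    jac = best.jac[:n_data]  # data part only
    res = best.fun[:n_data]
    dof = max(n_data - 2, 1)
    sigma2 = float(res @ res) / dof
    jtj = jac.T @ jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = sigma2 * np.linalg.pinv(jtj)
    if prior_term is not None:
        # fold the prior precision on log m into the posterior covariance
        prec = np.linalg.pinv(cov)
        prec[0, 0] += 1.0 / prior_term[1] ** 2
        cov = np.linalg.pinv(prec)
    cov = (cov + cov.T) / 2
    cov[np.diag_indices_from(cov)] = np.maximum(np.diag(cov), 0.0)
    m, k = math.exp(best.x[0]), math.exp(best.x[1])
    return ReleaseKinetics(m_slope=m, k_induction=k, covariance=cov)


def sequential_bayes(
    batches: list[tuple[np.ndarray, np.ndarray]],
) -> list[ReleaseKinetics]:
    """Successive Bayesian estimation of the shared material constant m.

    Batch 1 is fitted with a diffuse (flat) prior; each subsequent batch
    uses the previous posterior on log m as its prior while k is
    re-estimated freely.  The posterior sd of m is non-increasing in
    expectation as batches accumulate.
    """
    if not batches:
        raise ValueError("at least one batch is required")
    out: list[ReleaseKinetics] = []
    prior = None
    for times, phis in batches:
        fit = fit_release(times, phis, prior=prior)
        out.append(fit)
        prior = fit
    return out


def feed_forward_profile(
    k_predicted: float, m_material: float, time_grid
) -> np.ndarray:
    """Predicted release curve from a spectrally calibrated k and known m."""
    if k_predicted <= 0 or m_material <= 0:
        raise ValueError("k and m must be > 0")
    return np.asarray(
        release_fraction(np.asarray(time_grid, dtype=float), m_material, k_predicted)
    )
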