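"""Transcytosis kinetics and dose-response fitting.

Time courses of core tracer accumulation follow one-phase association,
``I(t) = B + A (1 - exp(-k t))``: B is the core background (AU), A the
plateau amplitude (AU) and k the association rate (per minute). Dose
responses at a fixed incubation time are fitted with ordinary least-squares
lines. Confidence bands are pointwise first-order (delta-method) bands with
a t-quantile at the residual degrees of freedom; steady-state timing is the
closed form ``t_frac = ln(1 / (1 - frac)) / k``.

Fits operate on per-organoid points, not per-time means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import AnalysisError, ConfigurationError

__all__ = [
    "AssociationFit",
    "LinearFit",
    "ConfidenceBand",
    "fit_association",
    "fit_linear",
    "confidence_band",
    "time_to_steady_state",
]

_K_BOUNDS = (1e-5, 10.0)  # per-minute; prevents runaway rates


@dataclass
class AssociationFit:
    """One-phase association fit with parameter covariance."""

    baseline: float
    amplitude: float
    k: float
    cov: np.ndarray  # 3x3, order (baseline, amplitude, k)
    resid_sd: float
    n: int
    dof: int
    converged: bool = True

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.baseline + self.amplitude * (1.0 - np.exp(-self.k * t))

    def gradient(self, t) -> np.ndarray:
        """Jacobian of the curve w.r.t. (B, A, k), shape (len(t), 3)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        e = np.exp(-self.k * t)
        return np.column_stack([np.ones_like(t), 1.0 - e, self.amplitude * t * e])


@dataclass
class LinearFit:
    """Ordinary least-squares dose-response line."""

    slope: float
    intercept: float
    cov: np.ndarray  # 2x2, order (slope, intercept)
    resid_sd: float
    n: int
    dof: int

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.slope * x + self.intercept

    def gradient(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.column_stack([x, np.ones_like(x)])


@dataclass
class ConfidenceBand:
    """Pointwise confidence band of a fitted curve."""

    grid: np.ndarray
    fitted: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float


def _group_means(t: np.ndarray, y: np.ndarray):
    uniq = np.unique(t)
    return uniq, np.array([y[t == u].mean() for u in uniq])


def fit_association(times, values) -> AssociationFit:
    """Least-squares fit of the one-phase association model.

    Initialization: B0 = smallest per-time mean, A0 = range of per-time
    means, k0 = 1/median(t); bounded on k with three fixed multistart
    perturbations of k0 if the first attempt fails to converge.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    uniq, means = _group_means(t, y)
    if uniq.size < 3:
        raise AnalysisError("need >= 3 distinct time points to fit kinetics")
    scale = max(abs(means).max(), 1.0)
    if means.max() - means.min() < 1e-9 * scale:
        raise AnalysisError("amplitude unidentifiable: response is constant in time")

    b0 = float(means.min())
    a0 = float(means.max() - means.min())
    k0 = 1.0 / float(np.median(t[t > 0])) if np.any(t > 0) else 0.01
    k0 = float(np.clip(k0, *_K_BOUNDS))

    def residuals(p):
        b, a, k = p
        return b + a * (1.0 - np.exp(-k * t)) - y

    lower = np.array([-np.inf, 0.0, _K_BOUNDS[0]])
    upper = np.array([np.inf, np.inf, _K_BOUNDS[1]])
    best = None
    for mult in (1.0, 0.2, 5.0, 0.05):
        x0 = np.array([b0, a0, float(np.clip(k0 * mult, *_K_BOUNDS))])
        res = optimize.least_squares(residuals, x0, bounds=(lower, upper))
        if res.success and (best is None or res.cost < best.cost):
            best = res
            if res.cost <= 1e-20:
                break
    if best is None:
        raise AnalysisError("kinetics fit did not converge for any start point")
    b, a, k = best.x
    if k <= _K_BOUNDS[0] * 1.001:
        raise AnalysisError(
            f"kinetics fit failed: rate estimate pinned at the lower bound (k={k:.2e})"
        )
    n = t.size
    dof = n - 3
    ssr = 2.0 * best.cost
    resid_var = ssr / dof if dof > 0 else 0.0
    J = best.jac
    try:
        cov = resid_var * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError as exc:
        raise AnalysisError(f"singular Jacobian in kinetics fit: {exc}") from exc
    return AssociationFit(
        baseline=float(b),
        amplitude=float(a),
        k=float(k),
        cov=cov,
        resid_sd=float(np.sqrt(resid_var)),
        n=n,
        dof=dof,
        converged=bool(best.success),
    )


def fit_linear(doses, values) -> LinearFit:
    """OLS dose-response line with slope/intercept covariance.

    With exactly two points the line interpolates exactly; the fit carries
    zero residual degrees of freedom and no finite confidence band exists
    (``confidence_band`` rejects it).
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doses and values must be 1-D arrays of equal length")
    if np.unique(x).size < 2:
        raise AnalysisError("need >= 2 distinct dose levels for a linear fit")
    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = x.size
    dof = n - 2
    if dof > 0:
        resid_var = float(resid @ resid) / dof
        cov = resid_var * np.linalg.inv(X.T @ X)
        resid_sd = float(np.sqrt(resid_var))
    else:
        cov = np.full((2, 2), np.nan)
        resid_sd = 0.0
    return LinearFit(
        slope=float(beta[0]),
        intercept=float(beta[1]),
        cov=cov,
        resid_sd=resid_sd,
        n=n,
        dof=dof,
    )


def confidence_band(fit, grid, level: float = 0.95) -> ConfidenceBand:
    """Pointwise delta-method confidence band of the fitted curve.

    Variance at each grid point is ``g(x) Cov g(x)^T`` with ``g`` the
    gradient of the curve w.r.t. the parameters; the half-width uses the
    two-sided t-quantile at the fit's residual degrees of freedom. The band
    is pointwise, not simultaneous.
    """
    if not 0 < level < 1:
        raise ConfigurationError("level must be in (0, 1)")
    if fit.dof <= 0:
        raise AnalysisError("zero residual degrees of freedom: band undefined")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    fitted = np.atleast_1d(fit.predict(grid))
    G = fit.gradient(grid)
    var = np.einsum("ij,jk,ik->i", G, fit.cov, G)
    var = np.maximum(var, 0.0)
    tq = stats.t.ppf(0.5 + level / 2.0, fit.dof)
    half = tq * np.sqrt(var)
    return ConfidenceBand(grid=grid, fitted=fitted, lower=fitted - half, upper=fitted + half, level=level)


def time_to_steady_state(fit_or_k, frac: float = 0.95) -> float:
    """Minutes for the association curve to reach ``frac`` of its plateau.

    Closed form ``ln(1 / (1 - frac)) / k``; e.g. the half-time is
    ``ln(2)/k`` and 95%-of-plateau is ``ln(20)/k``.
    """
    if not 0 < frac < 1:
        raise ConfigurationError("frac must be in (0, 1)")
    k = fit_or_k.k if hasattr(fit_or_k, "k") else float(fit_or_k)
    if k <= 0:
        raise AnalysisError("rate k must be > 0")
    return float(np.log(1.0 / (1.0 - frac)) / k)
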