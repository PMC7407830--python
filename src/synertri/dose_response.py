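"""Constrained four-parameter logistic (4PL) concentration-response fitting.

The model on the anchored percent scales is

    r(x) = bottom + (top - bottom) / (1 + 10^(s * hill * (log10 x - log10 m)))

with ``m`` the half-maximal concentration and ``s = +1`` for inhibition
(mediator release falling from the stimulated-control level) or ``s = -1``
for enhancement (normalized TEER rising from the stimulated-control level).

Constraints follow the assay's anchoring: for inhibition the top plateau is
*fixed* at the stimulated-control level (100 on the percent scale) and the
bottom is free in [0, top]; for enhancement the bottom is fixed at 0 and the
plateau is free in (0, 100]. The half-maximal concentration is the curve's
own (relative) midpoint between the constrained plateaus, the standard 4PL
convention. Fitting is least squares on well-level residuals over log10
concentration with a multistart over candidate midpoints; the 95% interval
is asymptotic on log10 m with a t quantile at the residual degrees of
freedom, back-transformed to µg/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .models import Endpoint, ValidationError
from .normalization import ConcentrationResponseSeries

__all__ = [
    "FourParamLogistic",
    "FitResult",
    "InsufficientDataError",
    "fit_inhibition",
    "fit_enhancement",
    "confidence_interval",
]


class InsufficientDataError(ValueError):
    """Fewer than four distinct concentrations."""


@dataclass(frozen=True)
class FitResult:
    """Fitted 4PL parameters and derived half-maximal concentration.

    ``half_max`` is None when the series was flat (no concentration
    dependence: the treatment is inactive for this endpoint) or the fit did
    not converge. ``ci95`` is ``(0, inf)`` when the parameter covariance is
    singular (an unbounded interval, reported as such).
    """

    endpoint: Endpoint | None
    treatment_label: str
    direction: Literal["inhibition", "enhancement"]
    top: float
    bottom: float
    log10_half_max: float | None
    hill: float | None
    half_max: float | None
    ci95: tuple[float, float] | None
    se_log10: float | None
    df: int
    converged: bool
    flat: bool
    residual_sd: float
    n_points: int

    @property
    def active(self) -> bool:
        """Curve-level activity: converged on a non-flat series."""
        return self.converged and not self.flat and self.half_max is not None


class FourParamLogistic(BaseEstimator, RegressorMixin):
    """Sklearn-style 4PL regressor of response on concentration.

    Parameters
    ----------
    direction:
        "inhibition" (falling curve, top fixed at ``anchor``) or
        "enhancement" (rising curve, bottom fixed at 0, plateau <= ``anchor``).
    anchor:
        The constrained plateau level; 100.0 on the control-anchored percent
        scales.
    hill_max:
        Upper bound on the (positive) Hill slope.
    n_starts:
        Number of multistart midpoints, log-spaced across the data range.
    tol:
        Relative tolerance on the sum-of-squares reduction.
    max_iter:
        Maximum least-squares iterations per start.

    Attributes
    ----------
    top_, bottom_, hill_, log10_half_max_, half_max_ : fitted parameters
    se_log10_ : asymptotic standard error of log10 half_max (None if singular)
    ci95_ : 95% interval on half_max in concentration units
    converged_, flat_ : fit diagnostics
    residual_sd_ : root mean squared residual at ``df_`` degrees of freedom
    """

    def __init__(
        self,
        direction: str = "inhibition",
        anchor: float = 100.0,
        hill_max: float = 10.0,
        n_starts: int = 5,
        tol: float = 1e-10,
        max_iter: int = 2000,
        weighting: str = "relative",
        irls_iter: int = 2,
    ):
        self.direction = direction
        self.anchor = anchor
        self.hill_max = hill_max
        self.n_starts = n_starts
        self.tol = tol
        self.max_iter = max_iter
        self.weighting = weighting
        self.irls_iter = irls_iter

    # free parameter vector: inhibition -> (bottom, hill, log10m)
    #                        enhancement -> (plateau, hill, log10m)
    def _curve(self, theta: np.ndarray, logx: np.ndarray) -> np.ndarray:
        if self.direction == "inhibition":
            bottom, hill, m = theta
            top = self.anchor
            return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - m)))
        plateau, hill, m = theta
        return plateau / (1.0 + 10.0 ** (-hill * (logx - m)))

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.shape != y.shape:
            raise ValidationError("X and y must be aligned 1-D arrays")
        if np.any(X <= 0):
            raise ValidationError("concentrations must be strictly positive")
        if not np.all(np.isfinite(y)):
            raise ValidationError("responses must be finite")
        if self.direction not in ("inhibition", "enhancement"):
            raise ValueError(f"unknown direction: {self.direction!r}")
        uniq = np.unique(X)
        if uniq.size < 4:
            raise InsufficientDataError(
                f"need >= 4 distinct concentrations, got {uniq.size}"
            )
        logx = np.log10(X)
        lo, hi = logx.min(), logx.max()
        A = self.anchor

        if self.direction == "inhibition":
            bounds = ([0.0, 1e-6, lo - 3.0], [A, self.hill_max, hi + 3.0])
            b0 = float(np.clip(np.min(y), 0.0, A - 1e-9))
            base = [b0, 1.0, 0.0]
        else:
            bounds = ([1e-9, 1e-6, lo - 3.0], [A, self.hill_max, hi + 3.0])
            t0 = float(np.clip(np.max(y), 1e-6, A))
            base = [t0, 1.0, 0.0]

        if self.weighting not in ("relative", "none"):
            raise ValueError(f"unknown weighting: {self.weighting!r}")

        starts = np.linspace(lo, hi, max(self.n_starts, 1))

        def _multistart(w: np.ndarray):
            best = None
            for m0 in starts:
                theta0 = np.array([base[0], base[1], m0])
                theta0 = np.clip(
                    theta0, np.asarray(bounds[0]) + 0, np.asarray(bounds[1]) - 0
                )
                res = optimize.least_squares(
                    lambda th: (self._curve(th, logx) - y) * w,
                    theta0,
                    bounds=bounds,
                    method="trf",
                    ftol=self.tol,
                    xtol=min(self.tol, 1e-12),
                    gtol=1e-12,
                    max_nfev=self.max_iter,
                )
                if best is None or res.cost < best.cost - 1e-15 * max(best.cost, 1.0):
                    best = res
            return best

        best = _multistart(np.ones_like(y))
        if self.weighting == "relative":
            # IRLS with weights 1/fitted: variance-stabilising for errors whose
            # sd scales with the response level (constant CV); weights are held
            # fixed within each pass so they do not enter the gradient
            floor_w = 1e-3 * A
            for _ in range(max(self.irls_iter, 0)):
                fitted = np.clip(self._curve(best.x, logx), floor_w, None)
                best = _multistart(1.0 / fitted)

        theta = best.x
        n = y.size
        n_free = 3
        df = max(n - n_free, 1)
        raw_resid = self._curve(theta, logx) - y
        resid_sd = math.sqrt(float(raw_resid @ raw_resid) / df)

        self.n_points_ = int(n)
        self.df_ = int(df)
        self.residual_sd_ = float(resid_sd)
        self.converged_ = bool(best.success)
        if self.direction == "inhibition":
            self.bottom_, self.hill_, self.log10_half_max_ = map(float, theta)
            self.top_ = float(A)
        else:
            self.top_, self.hill_, self.log10_half_max_ = map(float, theta)
            self.bottom_ = 0.0
        self.half_max_ = float(10.0 ** self.log10_half_max_)

        self.flat_ = self._is_flat(X, y, resid_sd)
        # covariance on the (possibly weighted) residual scale matching best.jac
        scale_sd = math.sqrt(2.0 * best.cost / df)
        self._set_ci(best.jac, scale_sd, df)
        return self

    def _is_flat(self, X: np.ndarray, y: np.ndarray, resid_sd: float) -> bool:
        """No concentration dependence: every per-concentration mean sits at
        the no-effect plateau to within one residual sd."""
        eps = 1e-9 * self.anchor
        means = np.array([y[X == c].mean() for c in np.unique(X)])
        if self.direction == "inhibition":
            effect = self.anchor - means.min()
        else:
            effect = means.max()  # rise above the 0% stimulated anchor
        return bool(effect <= resid_sd + eps)

    def _set_ci(self, jac: np.ndarray, resid_sd: float, df: int) -> None:
        jtj = jac.T @ jac
        try:
            cov = resid_sd**2 * np.linalg.inv(jtj)
            var_m = cov[2, 2]
            if not np.isfinite(var_m) or var_m < 0:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            self.se_log10_ = None
            self.ci95_ = (0.0, math.inf)
            return
        se = math.sqrt(var_m)
        self.se_log10_ = float(se)
        tq = float(stats.t.ppf(0.975, df))
        m = self.log10_half_max_
        self.ci95_ = (10.0 ** (m - tq * se), 10.0 ** (m + tq * se))

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        if self.direction == "inhibition":
            theta = np.array([self.bottom_, self.hill_, self.log10_half_max_])
        else:
            theta = np.array([self.top_, self.hill_, self.log10_half_max_])
        return self._curve(theta, np.log10(X))


def _fit_series(series: ConcentrationResponseSeries, direction: str) -> FitResult:
    # mediator (ELISA) errors scale with level -> relative weighting; TEER
    # resistance differences carry roughly constant absolute error -> none
    weighting = "relative" if direction == "inhibition" else "none"
    est = FourParamLogistic(direction=direction, weighting=weighting).fit(
        series.concentrations, series.responses
    )
    flat = est.flat_
    ok = est.converged_ and not flat
    return FitResult(
        endpoint=series.endpoint,
        treatment_label=series.treatment_label,
        direction=direction,  # type: ignore[arg-type]
        top=est.top_,
        bottom=est.bottom_,
        log10_half_max=est.log10_half_max_ if ok else None,
        hill=est.hill_ if ok else None,
        half_max=est.half_max_ if ok else None,
        ci95=est.ci95_ if ok else None,
        se_log10=est.se_log10_ if ok else None,
        df=est.df_,
        converged=est.converged_,
        flat=flat,
        residual_sd=est.residual_sd_,
        n_points=est.n_points_,
    )


def fit_inhibition(series: ConcentrationResponseSeries) -> FitResult:
    """Fit a falling 4PL to a percent-of-stimulated mediator series (IC50)."""
    if series.scale != "percent_of_stimulated":
        raise ValidationError(
            "fit_inhibition expects a percent_of_stimulated series; "
            "apply normalization.percent_of_stimulated first"
        )
    return _fit_series(series, "inhibition")


def fit_enhancement(series: ConcentrationResponseSeries) -> FitResult:
    """Fit a rising 4PL to a normalized-TEER series (EC50)."""
    if series.scale != "normalized_teer":
        raise ValidationError(
            "fit_enhancement expects a normalized_teer series; "
            "apply normalization.normalize_teer_series first"
        )
    return _fit_series(series, "enhancement")


def confidence_interval(fit: FitResult, level: float = 0.95) -> tuple[float, float]:
    """Symmetric asymptotic interval on log10 half_max, back-transformed.

    Uses the stored standard error and residual degrees of freedom; returns
    ``(0, inf)`` when the covariance was singular.
    """
    if not fit.converged or fit.log10_half_max is None:
        raise ValidationError("confidence interval requires a converged, non-flat fit")
    if fit.se_log10 is None:
        return (0.0, math.inf)
    tq = float(stats.t.ppf(0.5 + level / 2.0, fit.df))
    m = fit.log10_half_max
    return (10.0 ** (m - tq * fit.se_log10), 10.0 ** (m + tq * fit.se_log10))
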