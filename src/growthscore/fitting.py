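"""Least-squares estimation of the four Zwietering parameters.

The central object is :class:`ZwieteringLogistic`, a scikit-learn style
regressor: ``fit(t, od)`` estimates (y0, lag, mu, A) by bounded nonlinear
least squares (scipy's trust-region reflective solver) and ``predict(t)``
evaluates the fitted model.  :func:`fit_logistic` wraps it in the
dataclass-based API used by the rest of the package.

The objective is the plain (unweighted) residual sum of squares on the raw
OD readings.  A moving-median smoother is used only to build the starting
point, never inside the objective.  The fit is deterministic (single start
from :func:`initial_guess`); an optional seeded multistart perturbs the
start five times for hard curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .curves import FitResult, GrowthCurve, GrowthParameters, zwietering

__all__ = ["FitOptions", "ZwieteringLogistic", "initial_guess", "fit_logistic"]

_MU_FLOOR = 1e-6


@dataclass
class FitOptions:
    """Tuning knobs for the least-squares fit.

    ``tolerance`` is the relative convergence tolerance applied to the
    parameters, cost and gradient; ``smoothing_window`` (odd, in time
    points) controls the moving median used only for initialization;
    ``bounds`` optionally overrides the data-driven per-parameter
    (lower, upper) pairs in the order (y0, lag, mu, A).
    """

    max_iterations: int = 1000
    tolerance: float = 1e-12
    smoothing_window: int = 3
    bounds: Optional[tuple[tuple[float, float], ...]] = None
    multistart: bool = False
    n_starts: int = 5
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be an odd integer >= 1")


def _moving_median(od: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return od.copy()
    half = window // 2
    padded = np.pad(od, half, mode="edge")
    return np.array(
        [np.median(padded[i : i + window]) for i in range(len(od))]
    )


def initial_guess(curve: GrowthCurve, opts: Optional[FitOptions] = None) -> GrowthParameters:
    """Heuristic starting parameters from the smoothed curve.

    y0 is the median of the first readings, A the smoothed maximum, mu the
    steepest finite-difference slope (floored at a small positive value),
    and lag the time where the tangent through the max-slope point crosses
    y0, clipped to the observed window.
    """
    opts = opts or FitOptions()
    if len(curve) < 3:
        raise ValueError("too few points")
    t, od = curve.time, curve.od
    smoothed = _moving_median(od, opts.smoothing_window)

    y0 = float(np.median(smoothed[: min(3, len(smoothed))]))
    y0 = max(y0, 0.0)
    A = float(np.max(smoothed))
    A = max(A, _MU_FLOOR)

    slopes = np.diff(smoothed) / np.diff(t)
    k = int(np.argmax(slopes))
    mu = max(float(slopes[k]), _MU_FLOOR)

    # tangent through the max-slope midpoint, back to the y0 baseline
    t_star = 0.5 * (t[k] + t[k + 1])
    y_star = 0.5 * (smoothed[k] + smoothed[k + 1])
    if slopes[k] > _MU_FLOOR:
        lag = t_star - (y_star - y0) / slopes[k]
    else:
        lag = 0.0
    lag = float(np.clip(lag, 0.0, t[-1]))
    return GrowthParameters(y0=y0, lag=lag, mu=mu, A=A)


def _default_bounds(curve: GrowthCurve) -> tuple[np.ndarray, np.ndarray]:
    """Data-driven box constraints in the order (y0, lag, mu, A).

    The box keeps the exponent well scaled and forbids non-physical
    negatives: y0 in [0, max od], A in [min od, 2 max od], mu in
    [1e-6, 10 x steepest observed slope], lag in [0, max time].
    """
    od_max = max(float(np.max(curve.od)), _MU_FLOOR)
    od_min = max(float(np.min(curve.od)), 1e-8)
    slope_max = float(np.max(np.diff(curve.od) / np.diff(curve.time)))
    mu_hi = max(10.0 * slope_max, 1e-4)
    lower = np.array([0.0, 0.0, _MU_FLOOR, od_min])
    upper = np.array([od_max, float(curve.time[-1]), mu_hi, 2.0 * od_max])
    return lower, upper


class ZwieteringLogistic(RegressorMixin, BaseEstimator):
    """Zwietering logistic growth-curve regressor.

    Fits yhat(t) = y0 + (A - y0)/(1 + exp[(4 mu / A)(lag - t) + 2]) to a
    single well's OD time series by bounded least squares.

    Parameters
    ----------
    max_iterations : int, default=1000
        Maximum number of objective evaluations for the solver.
    tolerance : float, default=1e-12
        Relative convergence tolerance (ftol/xtol/gtol).
    smoothing_window : int, default=3
        Odd moving-median window (time points) for initialization only.
    bounds : tuple of (low, high) pairs, optional
        Per-parameter bounds in the order (y0, lag, mu, A); data-driven
        defaults when None.
    multistart : bool, default=False
        Retry from 5 seeded perturbations of the initial guess and keep the
        lowest-cost solution.
    n_starts : int, default=5
        Number of perturbed starts when ``multistart`` is on.
    random_state : int, default=0
        Seed for the multistart perturbations.

    Attributes
    ----------
    y0_, lag_, mu_, A_ : float
        Estimated parameters.
    rss_ : float
        Residual sum of squares at the solution.
    converged_ : bool
        Whether the solver reported convergence.
    n_points_ : int
        Number of observations used.

    Examples
    --------
    >>> import numpy as np
    >>> from growthscore.curves import GrowthParameters, logistic
    >>> t = np.arange(0, 48, 0.5)
    >>> od = logistic(GrowthParameters(0.05, 6.0, 0.3, 1.0), t)
    >>> est = ZwieteringLogistic().fit(t, od)
    >>> round(est.A_, 3)
    1.0
    """

    def __init__(
        self,
        max_iterations: int = 1000,
        tolerance: float = 1e-12,
        smoothing_window: int = 3,
        bounds: Optional[tuple[tuple[float, float], ...]] = None,
        multistart: bool = False,
        n_starts: int = 5,
        random_state: int = 0,
    ):
        self.max_iterations = max_iterations
        self.tolerance = tolerance
        self.smoothing_window = smoothing_window
        self.bounds = bounds
        self.multistart = multistart
        self.n_starts = n_starts
        self.random_state = random_state

    def _options(self) -> FitOptions:
        return FitOptions(
            max_iterations=self.max_iterations,
            tolerance=self.tolerance,
            smoothing_window=self.smoothing_window,
            bounds=self.bounds,
            multistart=self.multistart,
            n_starts=self.n_starts,
            random_state=self.random_state,
        )

    @staticmethod
    def _as_time(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("time must be a 1-D vector or a (n, 1) column")
        return t

    def fit(self, X, y) -> "ZwieteringLogistic":
        """Estimate (y0, lag, mu, A) from times ``X`` (hours) and OD ``y``."""
        t = self._as_time(X)
        od = np.asarray(y, dtype=float)
        if od.shape != t.shape:
            raise ValueError("time and od must have the same length")
        if len(t) < 4:
            raise ValueError("need at least 4 points to fit 4 parameters")
        if not np.isfinite(od).all():
            raise ValueError("non-finite readings")
        order = np.argsort(t)
        t, od = t[order], od[order]

        curve = GrowthCurve(time=t, od=od)
        opts = self._options()
        guess = initial_guess(curve, opts)

        if self.bounds is not None:
            pairs = np.asarray(self.bounds, dtype=float)
            lower, upper = pairs[:, 0], pairs[:, 1]
        else:
            lower, upper = _default_bounds(curve)

        x0 = np.clip(np.array(guess.as_tuple()), lower, upper)

        def residuals(p: np.ndarray) -> np.ndarray:
            return zwietering(t, p[0], p[1], p[2], p[3]) - od

        def solve(start: np.ndarray):
            return least_squares(
                residuals,
                start,
                bounds=(lower, upper),
                method="trf",
                ftol=self.tolerance,
                xtol=self.tolerance,
                gtol=self.tolerance,
                max_nfev=self.max_iterations,
            )

        best = solve(x0)
        if self.multistart:
            rng = np.random.default_rng(self.random_state)
            span = upper - lower
            for _ in range(self.n_starts):
                jitter = np.clip(x0 + rng.normal(0, 0.1, 4) * span, lower, upper)
                trial = solve(jitter)
                if trial.cost < best.cost:
                    best = trial

        self.y0_, self.lag_, self.mu_, self.A_ = (float(v) for v in best.x)
        self.rss_ = float(2.0 * best.cost)  # least_squares cost = 0.5 * rss
        self.converged_ = bool(best.success)
        self.n_points_ = len(t)
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        """Evaluate the fitted model at times ``X`` (hours)."""
        if not hasattr(self, "A_"):
            raise AttributeError("this ZwieteringLogistic instance is not fitted yet")
        t = self._as_time(X)
        return zwietering(t, self.y0_, self.lag_, self.mu_, self.A_)

    @property
    def params_(self) -> GrowthParameters:
        """The fitted parameters as a :class:`GrowthParameters`."""
        return GrowthParameters(y0=self.y0_, lag=self.lag_, mu=self.mu_, A=self.A_)


def fit_logistic(curve: GrowthCurve, opts: Optional[FitOptions] = None) -> FitResult:
    """Fit the Zwietering model to ``curve`` and return a :class:`FitResult`.

    Minimizes sum((od_i - yhat_i)^2) over (y0, lag, mu, A) within bounds;
    on non-convergence the best iterate is returned with
    ``converged=False``.
    """
    opts = opts or FitOptions()
    est = ZwieteringLogistic(
        max_iterations=opts.max_iterations,
        tolerance=opts.tolerance,
        smoothing_window=opts.smoothing_window,
        bounds=opts.bounds,
        multistart=opts.multistart,
        n_starts=opts.n_starts,
        random_state=opts.random_state,
    ).fit(curve.time, curve.od)
    return FitResult(
        params=est.params_,
        fitted=est.predict(curve.time),
        rss=est.rss_,
        converged=est.converged_,
        n_points=est.n_points_,
    )
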