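"""Synthetic growth-curve cohorts and the Growth Level vs Growth Score study.

A cohort of noise-free Zwietering logistic curves is drawn with uniformly
distributed parameters over ranges chosen to portray realistic 96-well
phenotype-assay behaviour over a 10-day (240 h) experiment:

    y0 ~ U(0.05, 0.10)      starting absorbance (OD)
    lag ~ U(0, 120)         lag time (h)
    A  ~ U(0.1, 1.2)        biomass yield (OD)
    mu ~ U(A/T, 1.1*A)      maximum growth rate (OD/h), conditioned on A

The growth-rate range is tied to the yield: the lower end is an organism
that only just reaches its yield by the end of the experiment (very slow
growth), the upper end reaches it within about an hour (very fast growth).
A is always drawn before mu.

:func:`compare_metrics` computes the comparison statistics between the two
metrics over such a cohort: Pearson correlation, sample skewness of each
metric, the GS-on-GL regression line, and the class-disagreement counts.
GL is evaluated on the model curve and GS on the true simulated parameters
— the curves are generated directly from the model, so refitting would be
an identity operation (the fitting module is exercised separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curves import GrowthCurve, GrowthParameters, logistic
from .metrics import ClassThresholds, classify, default_thresholds, growth_level, growth_score

__all__ = [
    "SimulationConfig",
    "ComparisonReport",
    "sample_parameters",
    "simulate_cohort",
    "compare_metrics",
    "report_from_metrics",
    "cohort_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Sample size, time grid, seed and parameter ranges for a cohort.

    ``mu_upper_factor`` scales the yield-dependent upper growth-rate bound
    (mu_max = mu_upper_factor * A); the lower bound is A / total_time.
    ``noise_sd`` adds optional Gaussian observation noise for fitting
    exercises and defaults to off.
    """

    n_curves: int = 1000
    total_time: float = 240.0
    dt: float = 0.5
    seed: Optional[int] = None
    y0_range: tuple[float, float] = (0.05, 0.10)
    lag_range: tuple[float, float] = (0.0, 120.0)
    A_range: tuple[float, float] = (0.1, 1.2)
    mu_upper_factor: float = 1.1
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_curves < 1:
            raise ValueError("n_curves must be >= 1")
        if self.dt <= 0 or self.total_time <= 0:
            raise ValueError("dt and total_time must be positive")
        for name in ("y0_range", "lag_range", "A_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must have lower < upper")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def time_grid(self) -> np.ndarray:
        """The evaluation grid 0, dt, ..., total_time (inclusive)."""
        n = int(round(self.total_time / self.dt))
        return np.linspace(0.0, n * self.dt, n + 1)


@dataclass
class ComparisonReport:
    """Cohort-level statistics comparing Growth Level and Growth Score."""

    pearson_r: float
    p_value: float
    skew_gl: float
    skew_gs: float
    regression: tuple[float, float]  # (slope, intercept) of GS on GL
    n_reclassified: int
    n_sign_flips: int
    n_curves: int

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "skew_gl": self.skew_gl,
            "skew_gs": self.skew_gs,
            "regression_slope": self.regression[0],
            "regression_intercept": self.regression[1],
            "n_reclassified": self.n_reclassified,
            "n_sign_flips": self.n_sign_flips,
            "n_curves": self.n_curves,
        }


def sample_parameters(
    config: SimulationConfig, rng: np.random.Generator
) -> GrowthParameters:
    """Draw one parameter set: y0, lag, A, then mu conditioned on A.

    The sampling order is fixed so a given seed reproduces the same cohort
    across versions.
    """
    y0 = rng.uniform(*config.y0_range)
    lag = rng.uniform(*config.lag_range)
    A = rng.uniform(*config.A_range)
    mu = rng.uniform(A / config.total_time, config.mu_upper_factor * A)
    return GrowthParameters(y0=y0, lag=lag, mu=mu, A=A)


def simulate_cohort(
    config: Optional[SimulationConfig] = None,
) -> list[tuple[GrowthParameters, GrowthCurve]]:
    """Generate ``config.n_curves`` logistic curves on the shared grid.

    Curves are noise-free unless ``config.noise_sd > 0``; the true
    parameters are recorded alongside each curve.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    grid = config.time_grid
    cohort = []
    for i in range(config.n_curves):
        params = sample_parameters(config, rng)
        od = logistic(params, grid)
        if config.noise_sd > 0:
            od = od + rng.normal(0.0, config.noise_sd, size=od.shape)
        curve = GrowthCurve(time=grid, od=od, well_id=f"sim{i:04d}")
        cohort.append((params, curve))
    return cohort


def _derive_gs_thresholds(
    gl_thresholds: ClassThresholds, slope: float, intercept: float
) -> ClassThresholds:
    """GS cutoffs as the GL cutoffs mapped through the regression line."""
    mapped = tuple(slope * c + intercept for c in gl_thresholds.cutoffs)
    return ClassThresholds(labels=gl_thresholds.labels, cutoffs=mapped)


def report_from_metrics(
    gl: Sequence[float],
    gs: Sequence[float],
    gl_thresholds: Optional[ClassThresholds] = None,
    gs_thresholds: Optional[ClassThresholds] = None,
) -> ComparisonReport:
    """Comparison statistics from per-curve GL and GS vectors.

    Skewness is the adjusted Fisher-Pearson sample skewness.  When
    ``gs_thresholds`` is None the GS cutoffs are derived by mapping the GL
    cutoffs through the fitted GS-on-GL regression line, so the two class
    systems are directly comparable.
    """
    gl = np.asarray(gl, dtype=float)
    gs = np.asarray(gs, dtype=float)
    if gl.shape != gs.shape:
        raise ValueError("gl and gs must have the same length")
    n = len(gl)
    if n < 3:
        raise ValueError("need at least 3 curves to compare metrics")
    if gl_thresholds is None:
        gl_thresholds = default_thresholds("gl")

    r, p = stats.pearsonr(gl, gs)
    reg = stats.linregress(gl, gs)
    if gs_thresholds is None:
        gs_thresholds = _derive_gs_thresholds(gl_thresholds, reg.slope, reg.intercept)

    gl_classes = [classify(v, gl_thresholds) for v in gl]
    gs_classes = [classify(v, gs_thresholds) for v in gs]
    lowest = gl_thresholds.labels[0]
    n_reclassified = sum(a != b for a, b in zip(gl_classes, gs_classes))
    n_sign_flips = sum(
        (a == lowest) != (b == lowest) for a, b in zip(gl_classes, gs_classes)
    )

    return ComparisonReport(
        pearson_r=float(r),
        p_value=float(p),
        skew_gl=float(stats.skew(gl, bias=False)),
        skew_gs=float(stats.skew(gs, bias=False)),
        regression=(float(reg.slope), float(reg.intercept)),
        n_reclassified=n_reclassified,
        n_sign_flips=n_sign_flips,
        n_curves=n,
    )


def compare_metrics(
    cohort: Sequence[tuple[GrowthParameters, GrowthCurve]],
    gl_thresholds: Optional[ClassThresholds] = None,
    gs_thresholds: Optional[ClassThresholds] = None,
) -> ComparisonReport:
    """Compare GL and GS over a simulated cohort.

    GL is the harmonic-mean metric on the model curve evaluated on each
    curve's time grid; GS is computed from the true simulated parameters.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 curves to compare metrics")
    gl = [growth_level(logistic(p, c.time), p.y0, p.A) for p, c in cohort]
    gs = [growth_score(p) for p, _ in cohort]
    return report_from_metrics(gl, gs, gl_thresholds, gs_thresholds)


def cohort_table(
    cohort: Sequence[tuple[GrowthParameters, GrowthCurve]],
    gl_thresholds: Optional[ClassThresholds] = None,
    gs_thresholds: Optional[ClassThresholds] = None,
) -> pd.DataFrame:
    """Per-curve parameters, metrics and classes as a DataFrame.

    Columns: id, y0, lag, mu, A, gl, gs, gl_class, gs_class — the layout
    written by the ``simulate`` CLI verb and read back by ``compare``.
    """
    if gl_thresholds is None:
        gl_thresholds = default_thresholds("gl")
    if gs_thresholds is None:
        gs_thresholds = default_thresholds("gs")
    rows = []
    for p, c in cohort:
        gl = growth_level(logistic(p, c.time), p.y0, p.A)
        gs = growth_score(p)
        rows.append(
            {
                "id": c.well_id,
                "y0": p.y0,
                "lag": p.lag,
                "mu": p.mu,
                "A": p.A,
                "gl": gl,
                "gs": gs,
                "gl_class": classify(gl, gl_thresholds),
                "gs_class": classify(gs, gs_thresholds),
            }
        )
    return pd.DataFrame(rows)
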