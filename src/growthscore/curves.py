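"""Core data types and evaluation of the Zwietering logistic growth model.

The model describes a bacterial batch growth curve measured as optical
density (OD) over time:

    yhat(t) = y0 + (A - y0) / (1 + exp[(4*mu/A) * (lag - t) + 2])

with four parameters: the starting absorbance ``y0`` (OD), the lag time
``lag`` (hours), the maximum growth rate ``mu`` (OD per hour, the slope at
the inflection point scaled by A/(A - y0)), and the biomass yield ``A``
(OD, the stationary-phase asymptote).  The parameterization pins the curve
so that at t = lag the exponent equals 2, i.e. yhat(lag) - y0 =
(A - y0)/(1 + e^2).

OD values are treated as already blank-corrected; time is always in hours
(file readers convert, see :mod:`growthscore.plate_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["GrowthParameters", "GrowthCurve", "FitResult", "logistic", "zwietering"]

# exp() overflows past ~709; clamping keeps extreme (lag - t)*mu/A products
# on the correct asymptote instead of producing inf/nan.
_EXP_CLAMP = 700.0


@dataclass(frozen=True)
class GrowthParameters:
    """The four Zwietering parameters for one growth curve.

    Parameters
    ----------
    y0 : float
        Starting absorbance at inoculation (OD units).
    lag : float
        Lag time lambda (hours).
    mu : float
        Maximum growth rate (OD per hour).
    A : float
        Biomass yield / asymptote (OD units).
    """

    y0: float
    lag: float
    mu: float
    A: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.y0, self.lag, self.mu, self.A]).all():
            raise ValueError("growth parameters must be finite")
        if self.y0 < 0:
            raise ValueError(f"y0 must be >= 0, got {self.y0}")
        if self.lag < 0:
            raise ValueError(f"lag must be >= 0, got {self.lag}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.A <= 0:
            raise ValueError("asymptote must be positive")

    @property
    def amplitude(self) -> float:
        """Total biomass accumulated, A - y0 (may be <= 0 for non-growers)."""
        return self.A - self.y0

    @property
    def is_growing(self) -> bool:
        """False when the asymptote never rises above the inoculum (A <= y0)."""
        return self.A > self.y0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.y0, self.lag, self.mu, self.A)


@dataclass
class GrowthCurve:
    """Paired time and absorbance vectors for one well.

    ``time`` is in hours and must be strictly increasing with at least three
    points; ``od`` is the same length.
    """

    time: np.ndarray
    od: np.ndarray
    well_id: Optional[str] = None
    sample: Optional[str] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.ndim != 1 or self.od.ndim != 1:
            raise ValueError("time and od must be one-dimensional")
        if len(self.time) != len(self.od):
            raise ValueError(
                f"time and od lengths differ ({len(self.time)} vs {len(self.od)})"
            )
        if len(self.time) < 3:
            raise ValueError("too few points: a growth curve needs >= 3 readings")
        if not np.isfinite(self.time).all():
            raise ValueError("time vector contains non-finite values")
        if (self.time < 0).any():
            raise ValueError("time values must be >= 0")
        if not (np.diff(self.time) > 0).all():
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class FitResult:
    """A fitted curve: parameters, modeled OD, and residual diagnostics."""

    params: GrowthParameters
    fitted: np.ndarray
    rss: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        self.fitted = np.asarray(self.fitted, dtype=float)
        if len(self.fitted) != self.n_points:
            raise ValueError("fitted vector length must equal n_points")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


def zwietering(
    t: np.ndarray, y0: float, lag: float, mu: float, A: float
) -> np.ndarray:
    """Evaluate the Zwietering logistic model elementwise on ``t``.

    Raw-parameter form used by the optimizer; :func:`logistic` is the
    validated public entry point.
    """
    if A <= 0:
        raise ValueError("asymptote must be positive")
    t = np.asarray(t, dtype=float)
    exponent = np.clip((4.0 * mu / A) * (lag - t) + 2.0, -_EXP_CLAMP, _EXP_CLAMP)
    return y0 + (A - y0) / (1.0 + np.exp(exponent))


def logistic(params: GrowthParameters, time: np.ndarray) -> np.ndarray:
    """Modeled absorbance yhat for ``params`` on the given time grid (hours).

    Returns an array of the same length as ``time``; an empty time vector
    yields an empty result.  For finite t every value lies strictly between
    min(y0, A) and max(y0, A).
    """
    return zwietering(time, params.y0, params.lag, params.mu, params.A)
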