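"""Growth Level, Growth Score, and qualitative growth-class assignment.

Two scalar summaries of a fitted growth curve:

* **Growth Level (GL)** — the legacy metric: the harmonic mean of the
  amplitude-shifted model curve,

      GL = n / sum_i(1/x_i),   x_i = (yhat_i - y0) + (A - y0),

  computed over the *model* curve yhat on the observed time grid.  Because
  it averages over time it depends on lag time and experiment length.

* **Growth Score (GS)** — the replacement metric:

      GS = (A - y0) + 0.25 * mu.

  Only the accumulated biomass (amplitude) and the maximum growth rate
  enter; the rate is down-weighted to 25% so that yield remains the primary
  component.  GS needs no raw data and no lag estimate, so it composes with
  any external curve-parameterization software.

Either metric is mapped to an ordinal growth class ("-" no growth through
"++++" very high growth) by thresholding against inclusive lower bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .curves import FitResult, GrowthParameters

__all__ = [
    "ClassThresholds",
    "ScoreResult",
    "growth_level",
    "growth_score",
    "classify",
    "score_curve",
    "default_thresholds",
    "load_thresholds",
    "DEFAULT_LABELS",
]

logger = logging.getLogger(__name__)

DEFAULT_LABELS = ("-", "+", "++", "+++", "++++")


@dataclass(frozen=True)
class ClassThresholds:
    """Ordered class labels with ascending inclusive lower-bound cutoffs.

    ``cutoffs[k]`` is the smallest metric value assigned ``labels[k + 1]``;
    values below ``cutoffs[0]`` get the lowest label.  A value exactly equal
    to a cutoff belongs to the higher class.
    """

    labels: tuple[str, ...] = DEFAULT_LABELS
    cutoffs: tuple[float, ...] = (0.25, 0.75, 1.25, 1.75)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "cutoffs", tuple(float(c) for c in self.cutoffs))
        if len(self.cutoffs) != len(self.labels) - 1:
            raise ValueError(
                f"need exactly len(labels)-1 cutoffs, got {len(self.cutoffs)} "
                f"for {len(self.labels)} labels"
            )
        if not all(a < b for a, b in zip(self.cutoffs, self.cutoffs[1:])):
            raise ValueError("cutoffs must be strictly ascending")


@dataclass
class ScoreResult:
    """GL, GS and their class labels for one curve."""

    gl: float
    gs: float
    gl_class: str
    gs_class: str
    gl_degenerate: bool = False


def growth_level(
    fitted: Sequence[float],
    y0: float,
    A: float,
    *,
    with_flag: bool = False,
):
    """Growth Level: harmonic mean of x_i = (yhat_i - y0) + (A - y0).

    Parameters
    ----------
    fitted : array-like
        The *model* curve yhat on the observed time grid (not raw readings).
    y0, A : float
        Starting absorbance and biomass yield of the fit.
    with_flag : bool
        When True return ``(gl, degenerate)`` where ``degenerate`` marks the
        zero-amplitude rule below.

    Any x_i <= 0 (possible when A <= y0, i.e. a flat or non-growing well)
    makes the harmonic mean undefined; such curves get GL = 0 with the
    degenerate flag set rather than an error, because non-growing wells are
    routine inputs.
    """
    yhat = np.asarray(fitted, dtype=float)
    if yhat.size == 0:
        raise ValueError("growth_level needs a non-empty fitted curve")
    x = (yhat - y0) + (A - y0)
    if (x <= 0).any():
        if with_flag:
            return 0.0, True
        return 0.0
    gl = float(len(x) / np.sum(1.0 / x))
    if with_flag:
        return gl, False
    return gl


def growth_score(params: GrowthParameters) -> float:
    """Growth Score GS = (A - y0) + 0.25*mu.

    May be <= 0 when A <= y0; the value is reported as computed (not
    clamped) so downstream statistics stay unbiased — classification maps
    it to the lowest class.
    """
    return (params.A - params.y0) + 0.25 * params.mu


def classify(value: float, thresholds: ClassThresholds) -> str:
    """Map a metric value to its class label (inclusive lower bounds)."""
    k = int(np.searchsorted(thresholds.cutoffs, value, side="right"))
    return thresholds.labels[k]


def score_curve(
    fit: FitResult,
    gl_thresholds: Optional[ClassThresholds] = None,
    gs_thresholds: Optional[ClassThresholds] = None,
    *,
    allow_unconverged: bool = False,
) -> ScoreResult:
    """Compute both metrics and both class labels for a fitted curve."""
    if not fit.converged and not allow_unconverged:
        raise ValueError(
            "fit did not converge; pass allow_unconverged=True to score anyway"
        )
    if gl_thresholds is None:
        gl_thresholds = default_thresholds("gl")
    if gs_thresholds is None:
        gs_thresholds = default_thresholds("gs")
    p = fit.params
    gl, degenerate = growth_level(fit.fitted, p.y0, p.A, with_flag=True)
    gs = growth_score(p)
    return ScoreResult(
        gl=gl,
        gs=gs,
        gl_class=classify(gl, gl_thresholds),
        gs_class=classify(gs, gs_thresholds),
        gl_degenerate=degenerate,
    )


def _parse_threshold_text(text: str, source: str) -> dict[str, ClassThresholds]:
    """Parse the flat key/value threshold format.

    Lines are ``key = v1, v2, ...``; ``labels`` lists the class labels low
    to high, and every other key names a metric whose value is its cutoff
    list.  '#' starts a comment.
    """
    labels: tuple[str, ...] = DEFAULT_LABELS
    cutoff_sets: dict[str, tuple[float, ...]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{source}:{lineno}: expected 'key = values', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip().lower()
        items = [v.strip() for v in value.split(",") if v.strip()]
        if key == "labels":
            labels = tuple(items)
        else:
            try:
                cutoff_sets[key] = tuple(float(v) for v in items)
            except ValueError as exc:
                raise ValueError(f"{source}:{lineno}: non-numeric cutoff") from exc
    return {
        metric: ClassThresholds(labels=labels, cutoffs=cuts)
        for metric, cuts in cutoff_sets.items()
    }


def load_thresholds(path: Union[str, Path]) -> dict[str, ClassThresholds]:
    """Load per-metric class thresholds from a flat key/value text file."""
    path = Path(path)
    return _parse_threshold_text(path.read_text(encoding="utf-8"), str(path))


def default_thresholds(metric: str) -> ClassThresholds:
    """Shipped default thresholds for ``metric`` ("gl" or "gs").

    These are implementation defaults (the upstream PMAnalyzer cutoffs are
    not published); override them with :func:`load_thresholds`.
    """
    text = (
        resources.files("growthscore.data")
        .joinpath("default_thresholds.cfg")
        .read_text(encoding="utf-8")
    )
    table = _parse_threshold_text(text, "default_thresholds.cfg")
    try:
        return table[metric.lower()]
    except KeyError:
        raise KeyError(f"no default thresholds for metric {metric!r}") from None
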