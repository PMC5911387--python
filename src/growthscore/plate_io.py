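"""Readers and writers for plate-reader time series and results tables.

Two input dialects are supported:

* a long tab-delimited table with header columns ``sample``, ``well``,
  ``time``, ``od`` (one reading per row), and
* a wide CSV with a first ``time`` column and one column per well.

Time in files is decimal hours by default; pass ``time_unit`` to convert
from minutes or seconds on read.  Well labels are normalized ("A1" ->
"A01") so joins against condition maps are stable.  All text I/O is UTF-8
with LF line endings and "." as the decimal separator.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .curves import FitResult, GrowthCurve
from .metrics import ScoreResult

__all__ = [
    "PlateDataset",
    "ConditionMap",
    "read_long_table",
    "read_wide_csv",
    "read_condition_map",
    "write_results",
    "normalize_well",
]

logger = logging.getLogger(__name__)

WELL_RE = re.compile(r"^[A-H](0?[1-9]|1[0-2])$")

_TIME_FACTORS = {"hours": 1.0, "minutes": 1.0 / 60.0, "seconds": 1.0 / 3600.0}


class ConditionMap(dict):
    """well -> condition mapping; absent wells map to "unknown"."""

    def __missing__(self, key: str) -> str:
        return "unknown"


@dataclass
class PlateDataset:
    """Growth curves keyed by (sample, well), with optional condition map."""

    curves: list[GrowthCurve]
    conditions: Optional[ConditionMap] = None
    metadata: dict = field(default_factory=dict)

    @property
    def ragged(self) -> bool:
        """True when the curves do not share a common time grid."""
        if not self.curves:
            return False
        first = self.curves[0].time
        return not all(
            len(c.time) == len(first) and np.array_equal(c.time, first)
            for c in self.curves[1:]
        )

    def condition_for(self, well: str) -> str:
        if self.conditions is None:
            return "unknown"
        return self.conditions[well]


def normalize_well(label: str) -> str:
    """Normalize a 96-well label ("a1" -> "A01"); raise if not one."""
    candidate = str(label).strip().upper()
    m = re.match(r"^([A-H])0?([1-9]|1[0-2])$", candidate)
    if not m:
        raise ValueError(f"{label!r} is not a 96-well label")
    return f"{m.group(1)}{int(m.group(2)):02d}"


def _time_factor(time_unit: str) -> float:
    try:
        return _TIME_FACTORS[time_unit]
    except KeyError:
        raise ValueError(
            f"unknown time unit {time_unit!r}; expected hours, minutes or seconds"
        ) from None


def _require_numeric(series: pd.Series, name: str, header_offset: int = 2) -> pd.Series:
    """Coerce to float; on failure name the offending file line."""
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() & series.notna()
    if bad.any():
        line = int(series.index[bad][0]) + header_offset
        raise ValueError(f"non-numeric {name} value {series[bad].iloc[0]!r} at line {line}")
    return numeric.astype(float)


def read_long_table(
    path: Union[str, Path], time_unit: str = "hours"
) -> PlateDataset:
    """Read a long tab-delimited table (sample, well, time, od).

    Rows are grouped into one :class:`GrowthCurve` per (sample, well) and
    sorted by time; unsorted input is sorted silently with a logged notice.
    Duplicate (sample, well, time) rows are an error.  Extra columns are
    preserved in the dataset metadata.
    """
    factor = _time_factor(time_unit)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("sample", "well", "time", "od"):
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    df["time"] = _require_numeric(df["time"], "time") * factor
    df["od"] = _require_numeric(df["od"], "od")
    df["well"] = [normalize_well(w) for w in df["well"]]

    dup = df.duplicated(subset=["sample", "well", "time"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicate time point for "
            f"(sample={row['sample']!r}, well={row['well']!r}, time={row['time']})"
        )

    curves = []
    for (sample, well), group in df.groupby(["sample", "well"], sort=True):
        if not group["time"].is_monotonic_increasing:
            logger.info("times for (%s, %s) were unsorted; sorting", sample, well)
            group = group.sort_values("time")
        curves.append(
            GrowthCurve(
                time=group["time"].to_numpy(),
                od=group["od"].to_numpy(),
                well_id=well,
                sample=sample,
            )
        )
    extra = [c for c in df.columns if c not in ("sample", "well", "time", "od")]
    metadata = {"source": str(path), "time_unit": time_unit}
    if extra:
        metadata["extra_columns"] = extra
    return PlateDataset(curves=curves, metadata=metadata)


def read_wide_csv(
    path: Union[str, Path],
    time_unit: str = "hours",
    well_labels: str = "strict",
) -> PlateDataset:
    """Read a wide CSV: first column "time" (hours), one column per well.

    ``well_labels="strict"`` (default) requires 96-well labels and
    normalizes them; ``"any"`` accepts arbitrary column names, as used for
    simulated-cohort exports.  Empty well columns are skipped with a
    logged warning.
    """
    if well_labels not in ("strict", "any"):
        raise ValueError("well_labels must be 'strict' or 'any'")
    factor = _time_factor(time_unit)
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if not df.columns.size or df.columns[0].lower() != "time":
        raise ValueError("missing required column: 'time' (must be the first column)")
    time = _require_numeric(df.iloc[:, 0], "time").to_numpy() * factor

    curves = []
    for col in df.columns[1:]:
        label = normalize_well(col) if well_labels == "strict" else col
        series = df[col]
        if series.isna().all():
            logger.warning("well column %r is empty; skipping", col)
            continue
        od = _require_numeric(series, f"od ({col})").to_numpy()
        curves.append(GrowthCurve(time=time, od=od, well_id=label))
    return PlateDataset(
        curves=curves, metadata={"source": str(path), "time_unit": time_unit}
    )


def read_condition_map(path: Union[str, Path]) -> ConditionMap:
    """Read a tab-delimited well -> condition map (<= 96 entries).

    Requires columns ``well`` and ``condition``; duplicate wells are an
    error.  Querying a well absent from the map returns "unknown".
    """
    mapping = ConditionMap()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise ValueError("empty condition map")
        cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
        for col in ("well", "condition"):
            if col not in cols:
                raise ValueError(f"missing required column: {col!r}")
        iw, ic = cols.index("well"), cols.index("condition")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise ValueError(
                    f"malformed row at line {lineno}: expected {len(cols)} fields, "
                    f"got {len(parts)}"
                )
            well = normalize_well(parts[iw])
            if well in mapping:
                raise ValueError(f"duplicate well {well!r} at line {lineno}")
            mapping[well] = parts[ic].strip()
    return mapping


def _sig6(value) -> str:
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


_RESULT_COLUMNS = (
    "sample",
    "well",
    "condition",
    "y0",
    "lag",
    "mu",
    "A",
    "rss",
    "converged",
    "gl",
    "gs",
    "gl_class",
    "gs_class",
)


def _result_record(
    key: tuple, fit: FitResult, score: ScoreResult
) -> dict:
    sample, well, *rest = key
    condition = rest[0] if rest else "unknown"
    p = fit.params
    return {
        "sample": sample,
        "well": well,
        "condition": condition,
        "y0": p.y0,
        "lag": p.lag,
        "mu": p.mu,
        "A": p.A,
        "rss": fit.rss,
        "converged": fit.converged,
        "gl": score.gl,
        "gs": score.gs,
        "gl_class": score.gl_class,
        "gs_class": score.gs_class,
    }


def write_results(
    path: Union[str, Path],
    results: Sequence[tuple[tuple, FitResult, ScoreResult]],
    format: str = "tsv",
) -> None:
    """Write one record per curve, sorted by (sample, well).

    ``results`` holds ``(key, FitResult, ScoreResult)`` triples where key
    is ``(sample, well)`` or ``(sample, well, condition)``.  Floats are
    printed with 6 significant digits; output is byte-identical across
    reruns on the same input.  ``format`` is "tsv" or "json".
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown results format {format!r}; expected tsv or json")
    records = sorted(
        (_result_record(k, f, s) for k, f, s in results),
        key=lambda r: (str(r["sample"]), str(r["well"])),
    )
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(_RESULT_COLUMNS)]
        for rec in records:
            lines.append("\t".join(_sig6(rec[c]) for c in _RESULT_COLUMNS))
        path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    else:
        rounded = [
            {c: (float(_sig6(rec[c])) if isinstance(rec[c], float) else rec[c]) for c in _RESULT_COLUMNS}
            for rec in records
        ]
        path.write_text(
            json.dumps(rounded, indent=2) + "\n", encoding="utf-8", newline="\n"
        )


def write_wide_csv(
    path: Union[str, Path], curves: Sequence[GrowthCurve]
) -> None:
    """Write curves sharing a common grid as a wide CSV (time + wells)."""
    if not curves:
        raise ValueError("no curves to write")
    grid = curves[0].time
    for c in curves[1:]:
        if len(c.time) != len(grid) or not np.array_equal(c.time, grid):
            raise ValueError("wide-format export requires a common time grid")
    df = pd.DataFrame({"time": grid})
    for c in curves:
        df[c.well_id] = c.od
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
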