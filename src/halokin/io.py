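"""CSV readers/writers for time-course sets and fraction tables.

Fixture/observation CSV layout (long format, UTF-8, "." decimal)::

    replicate,time_min,class,fraction_pct
    1,0.0,S,100.0
    1,0.0,P1,0.0
    ...

Per (replicate, time) the class fractions must sum to 100; sums within
100 ± 5 are accepted and renormalized with a warning (chromatographic
integration rarely closes exactly), anything further off is rejected.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic_data import ExperimentDesign, TimeCourseSet

__all__ = ["parse_timecourse_csv", "write_timecourse_csv", "write_fraction_csv"]

_REQUIRED = ["replicate", "time_min", "class", "fraction_pct"]
SUM_TOLERANCE = 5.0  # percentage points


class TimecourseParseError(ValueError):
    """Malformed time-course CSV; message carries offending line numbers."""


def parse_timecourse_csv(
    path, s0: float = 500.0, e0: float = 6.0, halide: str = "Cl"
) -> TimeCourseSet:
    """Read and validate a long-format fraction CSV.

    The file carries no concentrations, so the design's s0/e0 are passed
    separately (defaults: the optimized chlorination assay).
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TimecourseParseError(f"{path}: missing column(s) {missing}")
    for col in ("replicate", "time_min", "fraction_pct"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-indexing
            raise TimecourseParseError(
                f"{path}: non-numeric {col!r} at line(s) {lines}"
            )
        df[col] = coerced

    dup = df.duplicated(subset=["replicate", "time_min", "class"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup][:5]]
        raise TimecourseParseError(
            f"{path}: duplicate (replicate, time, class) row(s) at line(s) {lines}"
        )

    # validate and renormalize per (replicate, time)
    parts = []
    for (rep, t), grp in df.groupby(["replicate", "time_min"], sort=True):
        total = grp["fraction_pct"].sum()
        if abs(total - 100.0) > SUM_TOLERANCE:
            raise TimecourseParseError(
                f"{path}: fractions at replicate {rep}, t={t} min sum to "
                f"{total:.3f}, outside 100 ± {SUM_TOLERANCE}"
            )
        if abs(total - 100.0) > 1e-9:
            warnings.warn(
                f"fractions at replicate {rep}, t={t} min sum to {total:.3f}; "
                "renormalized to 100",
                stacklevel=2,
            )
            grp = grp.assign(fraction_pct=grp["fraction_pct"] * 100.0 / total)
        parts.append(grp)
    out = pd.concat(parts, ignore_index=True)

    times = tuple(sorted(out["time_min"].unique()))
    reps = out["replicate"].nunique()
    design = ExperimentDesign(s0=s0, e0=e0, times=times, replicates=reps, halide=halide)
    return TimeCourseSet(design=design, observations=out, provenance={"source": str(path)})


def write_timecourse_csv(data: TimeCourseSet, path) -> None:
    """Write a TimeCourseSet in the long fixture layout."""
    data.observations.to_csv(path, index=False)


def write_fraction_csv(fractions: pd.DataFrame, path) -> None:
    """Write a model fraction table (time_min + class columns, 4 decimals)."""
    fractions.to_csv(path, index=False, float_format="%.4f")
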