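"""Fluorescence-polarization activity pipeline and replicate statistics.

The enzymatic read-out is the kinetic slope of a plate-reader time course
(polarization vs time). The pipeline mirrors standard practice for
acyl-transfer assays run with and without the acyl-CoA cofactor:

1. fit an ordinary least-squares line to every well;
2. background-subtract each +cofactor well by the mean −cofactor slope of
   the *same condition*;
3. average wells within each biological replicate;
4. divide each replicate mean by the matching reference (wild-type)
   replicate mean, so the reference is exactly 1.0 by construction;
5. report mean ± SEM across replicates (sd with n−1 denominator over √n).

``aggregate_pka`` applies the same replicate statistics to per-frame pKa
traces produced by an external per-frame predictor: each replicate is
reduced to its time mean first, then mean ± SEM is taken across replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import TimeSeries
from .structio import PlateTable

__all__ = [
    "ActivityResult",
    "fit_linear_slope",
    "process_acyl_clip",
    "replicate_mean_sem",
    "aggregate_pka",
]

PLUS = "+PalmCoA"
MINUS = "-PalmCoA"


@dataclass
class ActivityResult:
    """Relative activity of one condition: mean ± SEM over replicates.

    ``sem`` is None when only a single replicate is available (a SEM of a
    single value is undefined, not zero).
    """

    condition: str
    mean_activity: float
    sem: float | None
    n_replicates: int


def fit_linear_slope(times, signal) -> tuple[float, float, float]:
    """OLS line fit via the closed-form normal equations.

    Returns (slope, intercept, slope_stderr); stderr comes from the
    residual variance with n−2 degrees of freedom.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and signal must be 1D of equal length")
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 points")
    tbar = t.mean()
    ybar = y.mean()
    sxx = ((t - tbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("times are constant; slope undefined")
    slope = ((t - tbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * tbar
    resid = y - (intercept + slope * t)
    sigma2 = (resid**2).sum() / (n - 2)
    stderr = math.sqrt(sigma2 / sxx)
    return float(slope), float(intercept), float(stderr)


def replicate_mean_sem(values) -> tuple[float, float | None]:
    """Mean and standard error over replicate-level values.

    SEM = sd(n−1)/√n; with a single replicate the SEM is None (undefined).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no replicate values")
    if not np.isfinite(v).all():
        raise ValueError("replicate values contain non-finite entries")
    mean = float(v.mean())
    if v.size == 1:
        return mean, None
    sem = float(v.std(ddof=1) / math.sqrt(v.size))
    return mean, sem


def _well_slopes(plate: PlateTable) -> "dict[tuple, float]":
    """Per-well OLS slopes, the same closed form as fit_linear_slope but
    computed in one vectorized groupby pass over the whole plate."""
    df = plate.data.copy()
    keys = ["condition", "cofactor", "replicate", "well"]
    df["_ty"] = df["time_min"] * df["signal"]
    df["_tt"] = df["time_min"] * df["time_min"]
    g = df.groupby(keys).agg(
        n=("signal", "size"),
        st=("time_min", "sum"),
        sy=("signal", "sum"),
        sty=("_ty", "sum"),
        stt=("_tt", "sum"),
    )
    sxx = g["stt"] - g["st"] ** 2 / g["n"]
    if (sxx <= 0).any():
        bad = sxx.index[int(np.argmax((sxx <= 0).to_numpy()))]
        raise ValueError(f"well {bad[-1]}: times are constant; slope undefined")
    slope = (g["sty"] - g["st"] * g["sy"] / g["n"]) / sxx
    return dict(slope.items())


def process_acyl_clip(
    plate: PlateTable, reference_condition: str = "WT"
) -> list[ActivityResult]:
    """Slopes → background subtraction → reference normalization → mean ± SEM.

    Background pairing is per condition: every +cofactor well has the mean
    of that condition's −cofactor slopes subtracted (zero, with a warning,
    when a condition lacks −cofactor wells). Normalization is
    replicate-matched against ``reference_condition``. Negative activities
    are reported as-is.
    """
    conditions = plate.conditions()
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} not in plate")
    slopes = _well_slopes(plate)

    background: dict[str, float] = {}
    for cond in conditions:
        minus = [v for (c, cof, *_), v in slopes.items() if c == cond and cof == MINUS]
        if not minus:
            warnings.warn(
                f"condition {cond!r} has no {MINUS} wells; background set to 0",
                stacklevel=2,
            )
            background[cond] = 0.0
        else:
            background[cond] = float(np.mean(minus))

    # replicate-level background-subtracted means of +cofactor wells
    rep_means: dict[str, dict[int, float]] = {c: {} for c in conditions}
    for cond in conditions:
        per_rep: dict[int, list[float]] = {}
        for (c, cof, rep, _), v in slopes.items():
            if c == cond and cof == PLUS:
                per_rep.setdefault(rep, []).append(v - background[cond])
        if not per_rep:
            raise ValueError(f"condition {cond!r} has no {PLUS} wells")
        rep_means[cond] = {rep: float(np.mean(vs)) for rep, vs in per_rep.items()}

    ref = rep_means[reference_condition]
    results = []
    for cond in conditions:
        normalized = []
        for rep, value in sorted(rep_means[cond].items()):
            if rep not in ref:
                raise ValueError(
                    f"replicate {rep} of {cond!r} has no matching reference replicate"
                )
            normalized.append(value / ref[rep])
        mean, sem = replicate_mean_sem(normalized)
        results.append(ActivityResult(cond, mean, sem, len(normalized)))
    return results


def aggregate_pka(series: "list[TimeSeries]", skip: int = 0) -> tuple[float, float | None]:
    """Replicate mean ± SEM of per-frame pKa traces.

    Each replicate trace is reduced to its time mean (after discarding the
    first ``skip`` frames as equilibration), then
    :func:`replicate_mean_sem` is applied across replicates. NaN frames are
    an error rather than silently propagated.
    """
    if not series:
        raise ValueError("no replicate series")
    means = []
    for i, ts in enumerate(series):
        vals = np.asarray(ts.values, dtype=float)[skip:]
        if vals.size == 0:
            raise ValueError(f"replicate {i}: no frames after skip={skip}")
        if not np.isfinite(vals).all():
            raise ValueError(f"replicate {i}: non-finite pKa values")
        means.append(vals.mean())
    return replicate_mean_sem(means)
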