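"""Label-incorporation dynamics: linear slopes of abundance vs time.

After correction, the relative abundance of each isotopologue as a
function of labelling time carries the turnover information (for a
modification such as lysine acetylation, the initial rate at which the
unlabelled form is replaced).  The estimator here is a straight
ordinary-least-squares line through all (time, abundance) points, pooled
across replicates, as implemented by :func:`scipy.stats.linregress`; the
standard error of the slope is the usual OLS formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MeasurementError


@dataclass(frozen=True)
class SlopeEstimate:
    """OLS slope of relative abundance versus time."""

    slope: float  # % per h (or fraction per h, matching the input units)
    intercept: float
    stderr: float  # standard error of the slope
    n: int  # number of (time, abundance) points

    def __str__(self) -> str:
        return f"{self.slope:.3g} ± {self.stderr:.2g} (n={self.n})"


def fit_slope(
    timecourse: pd.DataFrame,
    isotopologue: str,
    time_column: str = "time",
    window: tuple[float, float] | None = None,
) -> SlopeEstimate:
    """Fit a line to one isotopologue's abundance over time.

    Parameters
    ----------
    timecourse:
        One row per replicate measurement; must contain ``time_column``
        and the ``isotopologue`` column.  Replicates at the same time
        point are simply additional rows (pooled OLS).
    window:
        Optional (t_min, t_max) restriction, for estimating an initial
        slope from the early part of a saturating curve.  Default: all
        points.
    """
    if isotopologue not in timecourse.columns:
        raise MeasurementError(f"no column {isotopologue!r} in time course")
    if time_column not in timecourse.columns:
        raise MeasurementError(f"no column {time_column!r} in time course")
    sub = timecourse[[time_column, isotopologue]].dropna()
    if window is not None:
        lo, hi = window
        sub = sub[(sub[time_column] >= lo) & (sub[time_column] <= hi)]
    t = sub[time_column].to_numpy(dtype=float)
    y = sub[isotopologue].to_numpy(dtype=float)
    if len(np.unique(t)) < 2:
        raise MeasurementError(
            "slope fitting needs at least 2 distinct time points"
        )
    res = stats.linregress(t, y)
    stderr = res.stderr if np.isfinite(res.stderr) else 0.0
    return SlopeEstimate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(stderr),
        n=len(t),
    )


def fit_slopes(
    timecourse: pd.DataFrame,
    time_column: str = "time",
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Fit every non-time column; returns a slopes table."""
    rows = []
    for col in timecourse.columns:
        if col == time_column:
            continue
        est = fit_slope(timecourse, col, time_column, window)
        rows.append(
            {
                "isotopologue": col,
                "slope": est.slope,
                "stderr": est.stderr,
                "intercept": est.intercept,
                "n": est.n,
            }
        )
    return pd.DataFrame(rows).set_index("isotopologue")


def slope_change(
    uncorrected: SlopeEstimate | float, corrected: SlopeEstimate | float
) -> float:
    """Relative change of the slope introduced by isotope correction.

    ``(corrected - uncorrected) / |uncorrected|``; e.g. 1.3 -> 1.9 %/h is
    a change of +0.46 (46%).
    """
    u = uncorrected.slope if isinstance(uncorrected, SlopeEstimate) else uncorrected
    c = corrected.slope if isinstance(corrected, SlopeEstimate) else corrected
    if u == 0:
        raise MeasurementError("relative slope change undefined for zero slope")
    return (c - u) / abs(u)
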