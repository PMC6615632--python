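"""Maximum growth rate from absorbance time series.

The fitness proxy is the largest slope of ln(absorbance) on time over
candidate windows of 5-8 consecutive readings on the 12-h grid between 12
and 96 h, keeping only windows whose log-linear fit achieves R^2 >= 0.75.
If no window passes, the replicate's rate is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WindowFit",
    "enumerate_windows",
    "fit_window",
    "max_growth_rate",
    "estimate_growth_rates",
]

WINDOW_SIZES = (5, 6, 7, 8)
DEFAULT_R2_MIN = 0.75


@dataclass(frozen=True)
class WindowFit:
    start: float
    end: float
    n_points: int
    slope: float
    r_squared: float
    valid: bool = True


def enumerate_windows(times: np.ndarray) -> list[tuple[int, int]]:
    """All contiguous windows of 5-8 time points, as (start, stop) index pairs.

    A curve with fewer than five points yields no windows.
    """
    n = len(times)
    windows = []
    for i in range(n):
        for k in WINDOW_SIZES:
            if i + k <= n:
                windows.append((i, i + k))
    # candidate order: by start time, then window length (the tie-break order
    # used by max_growth_rate)
    windows.sort(key=lambda w: (w[0], w[1] - w[0]))
    return windows


def fit_window(times: np.ndarray, absorbance: np.ndarray, window: tuple[int, int]) -> WindowFit:
    """OLS of ln(absorbance) on time within one window.

    Windows containing nonpositive or missing absorbance are flagged invalid.
    A flat window (zero variance of ln A) gets slope 0 and R^2 defined as 0,
    so it never passes the adequacy filter.
    """
    i, j = window
    t = np.asarray(times[i:j], dtype=float)
    a = np.asarray(absorbance[i:j], dtype=float)
    if np.any(~np.isfinite(a)) or np.any(a <= 0.0):
        return WindowFit(t[0], t[-1], j - i, math.nan, math.nan, valid=False)
    la = np.log(a)
    tc = t - t.mean()
    sxx = float(tc @ tc)
    sxy = float(tc @ (la - la.mean()))
    syy = float(((la - la.mean()) ** 2).sum())
    slope = sxy / sxx
    if syy <= 0.0:
        return WindowFit(t[0], t[-1], j - i, 0.0, 0.0)
    r2 = (sxy * sxy) / (sxx * syy)
    return WindowFit(t[0], t[-1], j - i, slope, min(r2, 1.0))


def max_growth_rate(
    times: np.ndarray,
    absorbance: np.ndarray,
    r2_min: float = DEFAULT_R2_MIN,
) -> tuple[float, WindowFit | None]:
    """Maximum slope over qualifying windows; NaN if none qualifies.

    A window qualifies if it is valid and R^2 >= ``r2_min`` (a fit of exactly
    ``r2_min`` is retained; the exclusion rule is strictly R^2 < r2_min).
    Slope ties are broken by earliest window start, then fewest points,
    via the candidate ordering of :func:`enumerate_windows`.
    """
    best: WindowFit | None = None
    for w in enumerate_windows(np.asarray(times, dtype=float)):
        fit = fit_window(times, absorbance, w)
        if not fit.valid or fit.r_squared < r2_min:
            continue
        if best is None or fit.slope > best.slope:
            best = fit
    if best is None:
        return math.nan, None
    return best.slope, best


def estimate_growth_rates(
    curves: pd.DataFrame, r2_min: float = DEFAULT_R2_MIN
) -> pd.DataFrame:
    """Apply :func:`max_growth_rate` to a long-format curve table.

    ``curves`` must have columns plate, well, line, replicate, time_h, od650.
    Returns one row per (plate, well, line, replicate) with the estimated
    maximum growth rate (NaN when no window passes) and the best window's
    start, size and R^2.
    """
    required = {"plate", "well", "line", "replicate", "time_h", "od650"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curve table is missing columns: {sorted(missing)}")
    out = []
    keys = ["plate", "well", "line", "replicate"]
    for key, grp in curves.sort_values("time_h").groupby(keys, sort=False):
        rate, best = max_growth_rate(
            grp["time_h"].to_numpy(), grp["od650"].to_numpy(), r2_min=r2_min
        )
        rec = dict(zip(keys, key))
        rec["max_growth_rate"] = rate
        rec["best_window_start"] = best.start if best else math.nan
        rec["best_window_n"] = best.n_points if best else math.nan
        rec["r_squared"] = best.r_squared if best else math.nan
        out.append(rec)
    return pd.DataFrame(out)
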