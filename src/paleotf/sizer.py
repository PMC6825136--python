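"""SiZer maps: significant zero crossings of smoothed-curve derivatives.

A reconstruction is smoothed with local-linear Gaussian-kernel fits over a
log-spaced family of bandwidths.  At each (time, bandwidth) cell the local
slope and its standard error are computed; a simultaneous confidence
interval (Bonferroni-adjusted for the number of effectively independent
blocks at that bandwidth) classifies the cell as a significant rising trend,
a significant falling trend, no significant trend, or -- where the
effective sample size falls below a cutoff -- insufficient data.

Slopes are taken with respect to increasing age; set ``time_forward=True``
to flip signs so that "rise" means rising toward the present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import DataError

CATEGORIES = ("rise", "fall", "flat", "insufficient")


@dataclass
class SiZerMap:
    """Category matrix over a (bandwidth, time) grid plus effective sample sizes."""

    times: np.ndarray
    bandwidths: np.ndarray       # log-spaced, ascending
    categories: np.ndarray       # (n_bandwidths, n_times) of CATEGORIES strings
    ess: np.ndarray              # effective sample size per cell
    slopes: np.ndarray
    slope_se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.categories,
                            index=pd.Index(self.bandwidths, name="bandwidth"),
                            columns=pd.Index(self.times, name="age_ka"))

    def coarsest_row(self) -> np.ndarray:
        return self.categories[-1]


def _local_linear(ages: np.ndarray, values: np.ndarray, t: float, bw: float
                  ) -> tuple[float, float, float]:
    """Weighted linear fit at centre t; returns (slope, slope SE, ESS)."""
    w = np.exp(-0.5 * ((ages - t) / bw) ** 2)
    ess = float(w.sum() / w.max()) if w.max() > 0 else 0.0
    sw = w.sum()
    if sw <= 0:
        return np.nan, np.nan, 0.0
    x = ages - t
    xbar = float(np.sum(w * x) / sw)
    sxx = float(np.sum(w * (x - xbar) ** 2))
    if sxx <= 0:
        return np.nan, np.nan, ess
    ybar = float(np.sum(w * values) / sw)
    slope = float(np.sum(w * (x - xbar) * (values - ybar)) / sxx)
    resid = values - (ybar + slope * (x - xbar))
    # local residual variance with an effective-dof correction
    nu = max(ess - 2.0, 1.0)
    sigma2 = float(np.sum(w * resid**2) / w.sum()) * ess / nu
    var_slope = sigma2 * float(np.sum(w**2 * (x - xbar) ** 2)) / sxx**2
    return slope, float(np.sqrt(max(var_slope, 0.0))), ess


def sizer_map(ages: np.ndarray, values: np.ndarray, n_bandwidths: int = 25,
              alpha: float = 0.05, n_times: int = 101, ess_cutoff: float = 5.0,
              time_forward: bool = False) -> SiZerMap:
    """Compute a SiZer map of a dated series.

    Bandwidths are log-spaced from twice the median age spacing to half the
    age range; the time grid spans the observed ages.  Missing values are
    dropped.  Requires at least 10 samples and strictly monotone ages.
    """
    ages = np.asarray(ages, float)
    values = np.asarray(values, float)
    if len(ages) != len(values):
        raise DataError("ages and values differ in length")
    d = np.diff(ages)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise DataError("ages must be strictly monotone")
    if ages[0] > ages[-1]:
        ages, values = ages[::-1], values[::-1]
    ok = np.isfinite(values)
    ages, values = ages[ok], values[ok]
    if len(ages) < 10:
        raise DataError("need >= 10 samples for a SiZer map")

    span = float(ages[-1] - ages[0])
    bw_min = 2.0 * float(np.median(np.diff(ages)))
    bw_max = span / 2.0
    if bw_min >= bw_max:
        bw_min = bw_max / 4.0
    bandwidths = np.geomspace(bw_min, bw_max, n_bandwidths)
    times = np.linspace(ages[0], ages[-1], n_times)

    cats = np.empty((n_bandwidths, n_times), dtype=object)
    ess = np.zeros((n_bandwidths, n_times))
    slopes = np.full((n_bandwidths, n_times), np.nan)
    ses = np.full((n_bandwidths, n_times), np.nan)
    sign = -1.0 if time_forward else 1.0
    for bi, bw in enumerate(bandwidths):
        m = max(span / (2.0 * bw), 1.0)  # effectively independent blocks
        q = norm.ppf(1.0 - alpha / (2.0 * m))
        for ti, t in enumerate(times):
            slope, se, e = _local_linear(ages, values, t, bw)
            ess[bi, ti] = e
            slopes[bi, ti] = sign * slope if np.isfinite(slope) else np.nan
            ses[bi, ti] = se
            if e < ess_cutoff or not np.isfinite(slope) or not np.isfinite(se):
                cats[bi, ti] = "insufficient"
            elif sign * slope - q * se > 0:
                cats[bi, ti] = "rise"
            elif sign * slope + q * se < 0:
                cats[bi, ti] = "fall"
            else:
                cats[bi, ti] = "flat"
    return SiZerMap(times, bandwidths, cats, ess, slopes, ses)


def trend_blocks(row: np.ndarray) -> list[str]:
    """Collapse one bandwidth row into its sequence of significant trends.

    Consecutive duplicate categories are merged and flat/insufficient cells
    dropped, e.g. ['rise', 'fall'] for a hump-shaped series.
    """
    blocks = []
    for c in row:
        if c in ("flat", "insufficient"):
            continue
        if not blocks or blocks[-1] != c:
            blocks.append(c)
    return blocks
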