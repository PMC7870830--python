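"""Annual climate indices and nonparametric trend tests.

Indices
-------
* mean annual temperature T (degC) and total precipitation P (mm);
* aridity index P / 2T (mm/degC; larger = wetter);
* growing degree days: accumulated excess of the daily mean temperature
  ``(t_max + t_min) / 2`` over a developmental threshold (default 10 degC);
* three seasonal temperature cues: a 12-month window starting the month
  after the last survey (Oct of the previous year through Sep), the
  spring-summer window (Mar-Aug) overlapping the surveys, and the
  autumn-winter window (prior Sep through Feb) preceding them.

Trend testing uses the Mann-Kendall S statistic with tie-corrected
variance (normal approximation with continuity correction for n > 10, the
exact permutation null for n <= 10 without ties) and the Sen slope, the
median of all pairwise slopes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lepiphen.config import AnalysisConfig


@dataclass(frozen=True)
class AnnualClimate:
    year: int
    mean_temp: float
    total_precip: float
    aridity: float
    gdd: float
    cue_annual: float
    cue_spring_summer: float
    cue_autumn_winter: float


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall S, its p-value and the Sen slope for one series."""

    statistic: int
    p_value: float
    sen_slope: float
    n: int


def aridity_index(P: float, T: float) -> float:
    """Aridity index P / 2T (mm/degC); larger values mean wetter conditions."""
    if T <= 0:
        raise ValueError(f"aridity index undefined for mean temperature {T} <= 0 degC")
    return P / (2.0 * T)


def growing_degree_days(days, threshold: float = 10.0) -> float:
    """Sum of max(0, (t_max + t_min)/2 - threshold) over a day sequence.

    ``days`` is a frame with ``tmax``/``tmin`` columns or an iterable of
    (t_max, t_min) pairs.
    """
    if isinstance(days, pd.DataFrame):
        tmax = days["tmax"].to_numpy(dtype=float)
        tmin = days["tmin"].to_numpy(dtype=float)
    else:
        pairs = [(d.t_max, d.t_min) if hasattr(d, "t_max") else tuple(d) for d in days]
        if not pairs:
            warnings.warn("empty day sequence: GDD = 0", stacklevel=2)
            return 0.0
        arr = np.asarray(pairs, dtype=float)
        tmax, tmin = arr[:, 0], arr[:, 1]
    if tmax.size == 0:
        warnings.warn("empty day sequence: GDD = 0", stacklevel=2)
        return 0.0
    mean = (tmax + tmin) / 2.0
    return float(np.maximum(0.0, mean - threshold).sum())


def seasonal_cue_means(
    climate: pd.DataFrame, year: int, windows: dict | None = None
) -> dict[str, float]:
    """Mean daily temperature over each seasonal cue window for ``year``.

    ``windows`` maps cue names to (year_offset, month) pairs; defaults to
    the three standard windows from :mod:`lepiphen.config`.  A cue whose
    window is not fully covered by the series is returned as NaN.
    """
    if windows is None:
        windows = AnalysisConfig().cue_windows
    df = climate.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["_y"] = df["date"].dt.year
    df["_m"] = df["date"].dt.month
    df["_tmean"] = (df["tmax"] + df["tmin"]) / 2.0
    out: dict[str, float] = {}
    for cue, months in windows.items():
        masks = []
        complete = True
        for offset, month in months:
            m = (df["_y"] == year + offset) & (df["_m"] == month)
            if not m.any():
                complete = False
                break
            masks.append(m)
        if not complete:
            out[cue] = float("nan")
            continue
        sel = np.logical_or.reduce([m.to_numpy() for m in masks])
        out[cue] = float(df.loc[sel, "_tmean"].mean())
    return out


def annual_climate_table(
    climate: pd.DataFrame, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Per-year climate indices from a daily series (date,tmax,tmin,prcp)."""
    config = config or AnalysisConfig()
    df = climate.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year
    rows = []
    for year, grp in df.groupby("year"):
        T = float(((grp["tmax"] + grp["tmin"]) / 2.0).mean())
        P = float(grp["prcp"].sum())
        cues = seasonal_cue_means(df, int(year), config.cue_windows)
        rows.append(
            {
                "year": int(year),
                "mean_temp": T,
                "total_precip": P,
                "aridity": aridity_index(P, T) if T > 0 else float("nan"),
                "gdd": growing_degree_days(grp, config.gdd_threshold),
                **cues,
            }
        )
    return pd.DataFrame(rows).sort_values("year").reset_index(drop=True)


def _mk_statistic(x: np.ndarray) -> int:
    diff = np.sign(x[None, :] - x[:, None])
    return int(np.triu(diff, k=1).sum())


def _mk_variance(x: np.ndarray) -> float:
    n = x.size
    var = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(x, return_counts=True)
    for t in counts[counts > 1]:
        var -= t * (t - 1) * (2 * t + 5)
    return var / 18.0


def _exact_s_pvalue(s: int, n: int, alternative: str) -> float:
    """Exact null P for Mann-Kendall S with n untied values.

    Under the null every ordering is equally likely; S = M - 2*inv with
    M = n(n-1)/2 and inv the inversion count, whose distribution is given
    by the coefficients of prod_{i=1}^{n-1} (1 + x + ... + x^i).
    """
    poly = np.ones(1, dtype=float)
    for i in range(1, n):
        poly = np.convolve(poly, np.ones(i + 1, dtype=float))
    poly /= poly.sum()
    m = n * (n - 1) // 2
    s_values = m - 2 * np.arange(poly.size)  # S for each inversion count
    if alternative == "two-sided":
        return float(poly[np.abs(s_values) >= abs(s)].sum())
    if alternative == "greater":
        return float(poly[s_values >= s].sum())
    return float(poly[s_values <= s].sum())


def mann_kendall_sen(
    series: Sequence[float] | Iterable[float],
    confidence: float = 0.95,
    alternative: str = "two-sided",
) -> TrendResult:
    """Mann-Kendall trend test plus Sen slope for an annual series.

    For n <= 10 with no tied values the exact permutation null of S is
    used; otherwise the normal approximation with tie-corrected variance
    and continuity correction.  The Sen slope is the median of all
    pairwise slopes against the series index (one step = one year).
    ``confidence`` is retained for reporting symmetry; the returned
    p-value is compared against ``1 - confidence`` by callers.
    """
    x = np.asarray(list(series), dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    s = _mk_statistic(x)
    i, j = np.triu_indices(n, k=1)
    slopes = (x[j] - x[i]) / (j - i)
    sen = float(np.median(slopes))
    if np.all(x == x[0]):
        return TrendResult(statistic=0, p_value=1.0, sen_slope=0.0, n=n)
    has_ties = np.unique(x).size < n
    if n <= 10 and not has_ties:
        p = _exact_s_pvalue(s, n, alternative)
    else:
        var = _mk_variance(x)
        if s > 0:
            z = (s - 1) / math.sqrt(var)
        elif s < 0:
            z = (s + 1) / math.sqrt(var)
        else:
            z = 0.0
        if alternative == "two-sided":
            p = 2.0 * stats.norm.sf(abs(z))
        elif alternative == "greater":
            p = float(stats.norm.sf(z))
        else:
            p = float(stats.norm.cdf(z))
    return TrendResult(statistic=s, p_value=min(1.0, float(p)), sen_slope=sen, n=n)


def climate_trend_summary(
    annual: pd.DataFrame,
    variables: Sequence[str] = ("mean_temp", "aridity", "gdd"),
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Mann-Kendall + Sen summary for each annual climate variable."""
    rows = []
    for var in variables:
        series = annual.sort_values("year")[var].dropna()
        res = mann_kendall_sen(series.to_numpy(), confidence=confidence)
        rows.append(
            {
                "variable": var,
                "S": res.statistic,
                "p_value": res.p_value,
                "sen_slope": res.sen_slope,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
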