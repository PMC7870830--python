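"""Robust per-taxon trend estimation and site-structured population trends.

Phenology-versus-year and phenology-versus-temperature slopes use the
Siegel repeated-medians estimator (50% breakdown point): for each point i
take the median of pairwise slopes to every other point, then the median
of those per-point medians.  Inference is a one-sample Wilcoxon
signed-rank test of the per-point median slopes against zero — a
documented convention, since the repeated-medians estimator carries no
canonical standard error.

Population trends follow the TRIM (TRends and Indices for Monitoring
data) approach at its linear-trend level: annual counts are modelled as
Poisson with log mean = site effect + beta * year, fitted by iteratively
reweighted least squares; missing site-by-year cells are imputed with the
model predictions.  The trend is reported both multiplicatively (beta)
and as the implied additive change in mean count per transect walk per
year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from lepiphen.phenology import FlightYearSummary


@dataclass(frozen=True)
class SlopeEstimate:
    taxon: str
    response: str
    predictor: str
    slope: float
    intercept: float
    p_value: float
    n: int
    method: str = "repeated_medians"


@dataclass(frozen=True)
class PopulationTrend:
    """Per-taxon abundance trend from the Poisson site + year model."""

    taxon: str
    trend: float | None  # additive: individuals per walk per year
    beta: float | None  # multiplicative: log-counts per year
    p_value: float | None
    converged: bool


def _repeated_medians(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    n = x.size
    point_medians = np.empty(n)
    for i in range(n):
        dx = x - x[i]
        dy = y - y[i]
        ok = dx != 0
        if not ok.any():
            raise ValueError("all predictor values identical for some point")
        point_medians[i] = np.median(dy[ok] / dx[ok])
    slope = float(np.median(point_medians))
    intercept = float(np.median(y - slope * x))
    return slope, intercept, point_medians


def _theil_sen(x: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    i, j = np.triu_indices(x.size, k=1)
    dx = x[j] - x[i]
    ok = dx != 0
    slopes = (y[j] - y[i])[ok] / dx[ok]
    slope = float(np.median(slopes))
    intercept = float(np.median(y - slope * x))
    return slope, intercept, slopes


def _signed_rank_p(values: np.ndarray) -> float:
    """Wilcoxon signed-rank p of the values against zero; 1.0 if all zero."""
    nonzero = values[values != 0]
    if nonzero.size == 0:
        return 1.0
    try:
        return float(stats.wilcoxon(values, zero_method="wilcox").pvalue)
    except ValueError:
        return 1.0


def median_based_linear_model(
    x, y, *, taxon: str = "", response: str = "", predictor: str = "",
    method: str = "repeated_medians",
) -> SlopeEstimate:
    """Robust slope of y on x by Siegel repeated medians (or Theil-Sen).

    Exact on collinear data and resistant to up to half the points being
    corrupted.  Raises ``ValueError`` for n < 3 or constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.all(x == x[0]):
        raise ValueError("slope undefined: all predictor values equal")
    if method == "repeated_medians":
        slope, intercept, basis = _repeated_medians(x, y)
        p = _signed_rank_p(basis)
    elif method == "theil_sen":
        slope, intercept, basis = _theil_sen(x, y)
        p = _signed_rank_p(basis)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SlopeEstimate(
        taxon=taxon, response=response, predictor=predictor,
        slope=slope, intercept=intercept, p_value=p, n=int(x.size), method=method,
    )


def phenology_year_slopes(
    summaries: list[FlightYearSummary], method: str = "repeated_medians"
) -> pd.DataFrame:
    """Per-taxon mean-date and duration slopes against year."""
    df = pd.DataFrame(
        [(s.taxon, s.year, s.mean_date, s.duration) for s in summaries],
        columns=["taxon", "year", "mean_date", "duration"],
    )
    rows = []
    for taxon, grp in df.groupby("taxon"):
        if len(grp) < 3:
            continue
        for response in ("mean_date", "duration"):
            est = median_based_linear_model(
                grp["year"], grp[response],
                taxon=taxon, response=response, predictor="year", method=method,
            )
            rows.append(est.__dict__)
    return pd.DataFrame(rows)


def sensitivity_slopes(
    summaries: list[FlightYearSummary],
    cues: pd.DataFrame,
    cue_names: tuple[str, ...] = ("cue_annual", "cue_spring_summer", "cue_autumn_winter"),
    method: str = "repeated_medians",
) -> pd.DataFrame:
    """Per-taxon phenology slopes against each seasonal temperature cue.

    ``cues`` is the annual climate table (one row per year).  Taxa with
    fewer than 3 overlapping years yield no estimate.
    """
    df = pd.DataFrame(
        [(s.taxon, s.year, s.mean_date, s.duration) for s in summaries],
        columns=["taxon", "year", "mean_date", "duration"],
    )
    merged = df.merge(cues[["year", *cue_names]], on="year", how="inner")
    rows = []
    for taxon, grp in merged.groupby("taxon"):
        for cue in cue_names:
            sub = grp.dropna(subset=[cue])
            if len(sub) < 3 or sub[cue].nunique() < 2:
                continue
            for response in ("mean_date", "duration"):
                est = median_based_linear_model(
                    sub[cue], sub[response],
                    taxon=taxon, response=response, predictor=cue, method=method,
                )
                rows.append(est.__dict__)
    return pd.DataFrame(rows)


def population_trend(
    counts: pd.DataFrame,
    *,
    taxon: str = "",
    walks_per_cell: float | pd.DataFrame | None = None,
    max_iter: int = 100,
) -> PopulationTrend:
    """TRIM-style Poisson log-linear trend with site effects and imputation.

    ``counts`` is a site x year table of annual counts (NaN = site not
    surveyed that year).  Fits log mu_{s,y} = site_s + beta * year by
    IRLS; missing cells are imputed with the fitted means (the refit on
    the completed table leaves the estimate unchanged, which is the
    defining property of model-based imputation here).  The additive
    trend is beta times the mean fitted count per walk;
    ``walks_per_cell`` (scalar or site x year table) converts annual
    counts to per-walk counts, defaulting to 1.
    """
    long = counts.stack(future_stack=True).rename("count").reset_index()
    long.columns = ["site", "year", "count"]
    observed = long.dropna(subset=["count"])
    n_sites = counts.shape[0]
    if len(observed) < 3 or observed["year"].nunique() < 2:
        return PopulationTrend(taxon, None, None, None, converged=False)
    if float(observed["count"].sum()) == 0.0:
        return PopulationTrend(taxon, None, None, None, converged=False)
    year0 = float(observed["year"].mean())
    X = pd.get_dummies(observed["site"].astype(str), prefix="site", dtype=float)
    X["year"] = observed["year"].astype(float) - year0
    y = observed["count"].astype(float).to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X.to_numpy(), family=sm.families.Poisson())
            res = model.fit(maxiter=max_iter)
    except Exception:
        return PopulationTrend(taxon, None, None, None, converged=False)
    beta = float(res.params[-1])
    p = float(res.pvalues[-1])
    if not getattr(res, "converged", False) or not np.isfinite(beta) or abs(beta) > 10:
        return PopulationTrend(taxon, None, None, None, converged=False)
    # impute missing cells from the fitted model, then average per walk
    full = long.copy()
    Xf = pd.get_dummies(full["site"].astype(str), prefix="site", dtype=float)
    for col in X.columns[:-1]:
        if col not in Xf.columns:
            Xf[col] = 0.0
    Xf = Xf[[c for c in X.columns if c != "year"]]
    Xf["year"] = full["year"].astype(float) - year0
    mu = res.predict(Xf.to_numpy())
    if walks_per_cell is None:
        walks = np.ones_like(mu)
    elif np.isscalar(walks_per_cell):
        walks = np.full_like(mu, float(walks_per_cell))
    else:
        walks = (
            walks_per_cell.stack(future_stack=True).reset_index(drop=True).to_numpy(dtype=float)
        )
    per_walk = float(np.mean(mu / walks))
    additive = beta * per_walk
    return PopulationTrend(taxon, trend=additive, beta=beta, p_value=p, converged=True)


def impute_counts(counts: pd.DataFrame, trend: "PopulationTrend | None" = None) -> pd.DataFrame:
    """Return the counts table with missing cells filled by model predictions."""
    long = counts.stack(future_stack=True).rename("count").reset_index()
    long.columns = ["site", "year", "count"]
    observed = long.dropna(subset=["count"])
    year0 = float(observed["year"].mean())
    X = pd.get_dummies(observed["site"].astype(str), prefix="site", dtype=float)
    X["year"] = observed["year"].astype(float) - year0
    res = sm.GLM(
        observed["count"].astype(float).to_numpy(), X.to_numpy(), family=sm.families.Poisson()
    ).fit()
    Xf = pd.get_dummies(long["site"].astype(str), prefix="site", dtype=float)
    Xf["year"] = long["year"].astype(float) - year0
    Xf = Xf[X.columns]
    long["fitted"] = res.predict(Xf.to_numpy())
    long["completed"] = long["count"].fillna(long["fitted"])
    return long.pivot(index="site", columns="year", values="completed")
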