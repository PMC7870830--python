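"""Synthetic Pollard-walk surveys, climate series and phylogenies.

Every generator carries a known ground truth so each pipeline stage can
be validated end to end.  Flight curves are Gaussian in day-of-year — the
weighted mean-date and SD-duration metrics are exactly the first two
moments of such a curve — with Poisson observation noise, multiplicative
site effects, weekly visits within the survey season and optional visit
dropout.  Climate is a sinusoidal seasonal cycle with a linear year
trend, a per-year random effect and daily noise; precipitation is daily
gamma draws with a linear trend in the annual total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from lepiphen.pgls import _chol, tree_structure


@dataclass(frozen=True)
class TaxonSimParams:
    """Ground-truth generative parameters for one simulated taxon."""

    taxon: str
    mu0: float = 200.0  # baseline flight peak, Julian day
    sigma0: float = 10.0  # baseline flight spread, days
    b_mu_year: float = 0.0  # true mean-date shift, days/yr
    b_sigma_year: float = 0.0  # true duration shift, days/yr
    b_sigma_cue: float = 0.0  # true temperature sensitivity, days/degC
    n_per_year: float = 500.0  # expected individuals per year
    pop_beta: float = 0.0  # log-scale abundance trend per year
    lts: str = "polyphagous"
    ldc: str = "herb"
    voltinism: str = "multivoltine"
    broods: int = 1
    brood_gap: float = 60.0  # days between brood peaks when broods == 2

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.n_per_year < 0:
            raise ValueError("n_per_year must be non-negative")


@dataclass(frozen=True)
class SimScenario:
    """Survey design: years, sites, weekly visit schedule, missingness."""

    years: tuple[int, int] = (2007, 2016)  # inclusive
    n_sites: int = 5
    site_effects: tuple[float, ...] | None = None  # multiplicative; default log-spaced
    season: tuple[int, int] = (121, 304)  # weekly visits May 1 - Oct 31
    visit_interval: int = 7
    dropout: float = 0.0  # per-visit missingness probability
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not (1 <= self.season[0] <= self.season[1] <= 366):
            raise ValueError("season window must lie within [1, 366]")

    def resolved_site_effects(self) -> np.ndarray:
        if self.site_effects is not None:
            return np.asarray(self.site_effects, dtype=float)
        # mild heterogeneity around 1, fixed by design rather than random
        return np.geomspace(0.6, 1.6, self.n_sites)

    def year_range(self) -> range:
        return range(self.years[0], self.years[1] + 1)


def simulate_climate(
    years: tuple[int, int] = (1981, 2016),
    *,
    temp_trend: float = 0.02,
    precip_trend: float = 2.0,
    base_temp: float = 11.0,
    seasonal_amp: float = 12.0,
    diurnal_range: float = 10.0,
    noise_sd: float = 2.0,
    annual_effect_sd: float = 0.3,
    annual_precip: float = 1100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily climate series with a linear warming/wetting trend.

    Daily mean temperature = ``base_temp`` + seasonal sinusoid (peak late
    July) + ``temp_trend`` * (year - first year) + a per-year Gaussian
    effect (SD ``annual_effect_sd``) + daily noise.  ``precip_trend`` is
    mm of annual total per year.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    frames = []
    y0 = years[0]
    for year in range(years[0], years[1] + 1):
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        doy = dates.dayofyear.to_numpy(dtype=float)
        year_effect = rng.normal(0.0, annual_effect_sd) if annual_effect_sd > 0 else 0.0
        tmean = (
            base_temp
            + seasonal_amp * np.cos(2.0 * np.pi * (doy - 205.0) / 365.25)
            + temp_trend * (year - y0)
            + year_effect
            + (rng.normal(0.0, noise_sd, doy.size) if noise_sd > 0 else 0.0)
        )
        total = max(annual_precip + precip_trend * (year - y0), 0.0)
        if total > 0:
            daily_mean = total / doy.size
            prcp = rng.gamma(shape=0.4, scale=daily_mean / 0.4, size=doy.size)
            prcp *= total / prcp.sum()
        else:
            prcp = np.zeros(doy.size)
        frames.append(
            pd.DataFrame(
                {
                    "date": dates,
                    "tmax": tmean + diurnal_range / 2.0,
                    "tmin": tmean - diurnal_range / 2.0,
                    "prcp": prcp,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _gaussian_visit_intensity(
    days: np.ndarray, mu: float, sigma: float, interval: float
) -> np.ndarray:
    """Expected fraction of the annual total seen per visit.

    A weekly visit integrates roughly ``interval`` days of the flight
    curve, so the expected count is N * phi(day; mu, sigma) * interval.
    """
    return stats.norm.pdf(days, loc=mu, scale=sigma) * interval


def simulate_transects(
    params: list[TaxonSimParams],
    scenario: SimScenario,
    climate: pd.DataFrame | None = None,
    cue_column: str = "cue_spring_summer",
    cues: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate Pollard-walk counts; returns (survey table, truth ledger).

    Per taxon and year y the flight peak is mu_y = mu0 + b_mu_year*(y-y0)
    and the spread sigma_y = sigma0 + b_sigma_year*(y-y0)
    [+ b_sigma_cue * (cue_y - mean cue) when an annual cue table is
    supplied].  The expected count at a visit on day t at site s is
    n_per_year * site_s * exp(pop_beta*(y-y0)) * N(t; mu_y, sigma_y) * dt
    with dt the visit interval, realized as Poisson.  Two-brood taxa are
    equal mixtures of two Gaussian kernels ``brood_gap`` days apart.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    site_eff = scenario.resolved_site_effects()
    sites = [f"S{i + 1}" for i in range(scenario.n_sites)]
    y0 = scenario.years[0]
    visit_days = np.arange(
        scenario.season[0], scenario.season[1] + 1, scenario.visit_interval
    )
    cue_by_year: dict[int, float] = {}
    if cues is not None:
        dev = cues.set_index("year")[cue_column]
        cue_by_year = (dev - dev.mean()).to_dict()
    rows = []
    truth = []
    for p in params:
        for year in scenario.year_range():
            dy = year - y0
            mu_y = p.mu0 + p.b_mu_year * dy
            sigma_y = p.sigma0 + p.b_sigma_year * dy
            if cue_by_year:
                sigma_y += p.b_sigma_cue * cue_by_year.get(year, 0.0)
            if sigma_y <= 0:
                raise ValueError(f"{p.taxon}: non-positive flight spread in year {year}")
            n_exp = p.n_per_year * np.exp(p.pop_beta * dy)
            if p.broods == 2:
                intensity = 0.5 * (
                    _gaussian_visit_intensity(
                        visit_days.astype(float), mu_y - p.brood_gap / 2.0, sigma_y,
                        scenario.visit_interval,
                    )
                    + _gaussian_visit_intensity(
                        visit_days.astype(float), mu_y + p.brood_gap / 2.0, sigma_y,
                        scenario.visit_interval,
                    )
                )
            else:
                intensity = _gaussian_visit_intensity(
                    visit_days.astype(float), mu_y, sigma_y, scenario.visit_interval
                )
            truth.append(
                {
                    "taxon": p.taxon, "year": year, "mu": mu_y, "sigma": sigma_y,
                    "n_expected": n_exp * site_eff.sum(),
                    "b_mu_year": p.b_mu_year, "b_sigma_year": p.b_sigma_year,
                    "b_sigma_cue": p.b_sigma_cue, "pop_beta": p.pop_beta,
                }
            )
            for s_idx, site in enumerate(sites):
                lam = n_exp * site_eff[s_idx] * intensity
                counts = rng.poisson(lam)
                if scenario.dropout > 0:
                    visited = rng.random(visit_days.size) >= scenario.dropout
                else:
                    visited = np.ones(visit_days.size, dtype=bool)
                for day, cnt, vis in zip(visit_days, counts, visited):
                    if not vis:
                        continue
                    date = pd.Timestamp(year=year, month=1, day=1) + pd.Timedelta(
                        days=int(day) - 1
                    )
                    rows.append(
                        {
                            "date": date, "site": site, "taxon": p.taxon,
                            "sex": "unknown", "count": int(cnt),
                        }
                    )
    surveys = pd.DataFrame(rows)
    if not surveys.empty:
        surveys["julian_day"] = surveys["date"].dt.dayofyear
        surveys["year"] = surveys["date"].dt.year
    return surveys, pd.DataFrame(truth)


def default_community(
    n_taxa: int = 18,
    *,
    n_per_year: float = 500.0,
    slope_range: tuple[float, float] = (-1.5, 1.5),
    seed: int = 0,
) -> list[TaxonSimParams]:
    """A community of taxa with evenly spread true mean-date shifts.

    Peaks are spread over the mid-season, spreads over 8-16 days, and the
    true mean-date shifts span ``slope_range`` days/yr so that estimated
    slopes can be correlated with truth across taxa.
    """
    rng = np.random.default_rng(seed)
    slopes = np.linspace(*slope_range, n_taxa)
    mus = np.linspace(170.0, 250.0, n_taxa)
    sigmas = np.linspace(8.0, 16.0, n_taxa)
    lts = ["oligophagous", "polyphagous"]
    ldc = ["herb", "woody"]
    volt = ["univoltine", "multivoltine"]
    order = rng.permutation(n_taxa)
    return [
        TaxonSimParams(
            taxon=f"T{i + 1:02d}",
            mu0=float(mus[i]),
            sigma0=float(sigmas[i]),
            b_mu_year=float(slopes[order[i]]),
            b_sigma_year=float(rng.uniform(-0.3, 0.3)),
            n_per_year=n_per_year,
            pop_beta=float(rng.uniform(-0.05, 0.05)),
            lts=lts[i % 2],
            ldc=ldc[(i // 2) % 2],
            voltinism=volt[(i // 4) % 2],
        )
        for i in range(n_taxa)
    ]


def params_to_traits(params: list[TaxonSimParams]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"taxon": p.taxon, "lts": p.lts, "ldc": p.ldc, "voltinism": p.voltinism}
            for p in params
        ]
    )


def simulate_tree(n_taxa: int, seed: int = 0, *, depth: float = 1.0) -> dendropy.Tree:
    """Ultrametric birth-death tree rescaled to the given root-to-tip depth."""
    import random as _random

    from dendropy.model.birthdeath import birth_death_tree

    tree = birth_death_tree(
        birth_rate=1.0,
        death_rate=0.3,
        num_extant_tips=n_taxa,
        rng=_random.Random(int(seed)),
    )
    current = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= depth / current
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"T{i + 1:02d}"
    return tree


def simulate_tree_and_slopes(
    n_taxa: int,
    trait_effect: float = 2.0,
    lambda_true: float = 0.8,
    seed: int = 0,
    *,
    sigma_phylo: float = 1.0,
    sigma_noise: float = 0.3,
    trait_name: str = "voltinism",
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Tree + tip slopes with a known trait effect and phylogenetic signal.

    Tip slope = trait-level mean (difference ``trait_effect``) + a
    Brownian deviate whose off-tip covariances are scaled by
    ``lambda_true`` + white noise.  Returns the tree and a tidy frame
    (taxon, trait level, slope).
    """
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_taxa, seed=seed)
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    C, _ = tree_structure(tree, taxa)
    V = lambda_true * C
    np.fill_diagonal(V, np.diag(C))
    levels = np.array(["univoltine", "multivoltine"])[rng.integers(0, 2, n_taxa)]
    # guarantee both levels occur
    if len(set(levels)) == 1:
        levels[0] = "univoltine" if levels[0] == "multivoltine" else "multivoltine"
    base = np.where(levels == "multivoltine", trait_effect, 0.0)
    phylo = sigma_phylo * (_chol(V) @ rng.standard_normal(n_taxa))
    noise = rng.normal(0.0, sigma_noise, n_taxa)
    slopes = base + phylo + noise
    df = pd.DataFrame({"taxon": taxa, trait_name: levels, "slope": slopes})
    return tree, df
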