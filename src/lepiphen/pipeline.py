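"""End-to-end orchestration, shift classification and assemblage summaries.

The packaged per-taxon results table (one row per analysis entity; the
two sexes of *Speyeria idalia idalia* are separate entities on one
taxon) drives the classification and assemblage bookkeeping:

* a taxon **advanced** (or **delayed**) its mean flight date when the
  mean-date slope is negative (positive) with p <= ``shift_alpha``;
  **prolonged**/**shortened** likewise for the duration slope;
* for taxon-level counts the sex entities merge — a taxon counts once if
  either sex qualifies;
* assemblage population summaries report, per trait level, the share of
  entities with converged, significant (p < ``trend_alpha``) and positive
  population trends among entities with converged significant trends; the
  community-wide share is reported against the taxon count (each taxon
  once in the denominator) while each sex entity's trend direction
  contributes to the numerator.
"""

from __future__ import annotations

import logging
import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from lepiphen.climate import annual_climate_table, climate_trend_summary
from lepiphen.config import AnalysisConfig
from lepiphen.phenology import (
    apply_inclusion_filters,
    flight_year_summaries,
    summaries_to_frame,
)
from lepiphen.pgls import trait_sensitivity_analysis
from lepiphen.trends import phenology_year_slopes, population_trend, sensitivity_slopes

logger = logging.getLogger(__name__)


def parse_printed_p(value) -> float:
    """Parse a printed p-value; '<x' (an upper bound) parses to x.

    All downstream uses compare against thresholds well above the printed
    bounds, so representing '<0.001' by 0.001 is conservative and exact
    for every comparison the pipeline makes.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return float("nan")
    s = str(value).strip()
    if not s:
        return float("nan")
    if s.startswith("<"):
        return float(s[1:])
    return float(s)


def load_table1() -> pd.DataFrame:
    """Load the packaged per-taxon results table (19 entities, 18 taxa)."""
    with resources.files("lepiphen.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"sex": str})
    for col in ("mean_date_p", "duration_p", "pop_trend_p"):
        df[col] = df[col].map(parse_printed_p)
    df["converged"] = df["converged"].astype(bool)
    return df


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def classify_shifts(table: pd.DataFrame, alpha: float = 0.07) -> tuple[pd.DataFrame, dict]:
    """Classify phenological shifts per entity and count them per taxon.

    Returns the per-entity classification frame and a counts dict with
    taxon-level tallies (sex entities merged: a taxon counts once when
    either entity qualifies), the share of taxa shifted in at least one
    metric (percent, rounded half-up) and the largest advancement in
    days/yr among advancing entities.
    """
    df = table.copy()
    skipped = df["mean_date_p"].isna() & df["duration_p"].isna() & df["converged"]
    for _, row in df[df["mean_date_p"].isna() & df["mean_date_slope"].notna()].iterrows():
        logger.info("classify_shifts: %s has no mean-date p-value; skipped", row["entity"])
    def md_class(row):
        if pd.isna(row["mean_date_p"]) or row["mean_date_p"] > alpha:
            return "none"
        return "advanced" if row["mean_date_slope"] < 0 else "delayed"

    def du_class(row):
        if pd.isna(row["duration_p"]) or row["duration_p"] > alpha:
            return "none"
        return "prolonged" if row["duration_slope"] > 0 else "shortened"

    df["mean_date_class"] = df.apply(md_class, axis=1)
    df["duration_class"] = df.apply(du_class, axis=1)
    out = df[["entity", "taxon", "mean_date_class", "duration_class"]].copy()
    if df.empty:
        counts = {
            "advanced": 0, "delayed": 0, "prolonged": 0, "shortened": 0,
            "n_taxa": 0, "shifted_any": 0, "pct_shifted": 0,
            "largest_advance": float("nan"),
        }
        return out, counts
    by_taxon = df.groupby("taxon")
    adv = by_taxon.apply(lambda g: (g["mean_date_class"] == "advanced").any(), include_groups=False)
    del_ = by_taxon.apply(lambda g: (g["mean_date_class"] == "delayed").any(), include_groups=False)
    pro = by_taxon.apply(lambda g: (g["duration_class"] == "prolonged").any(), include_groups=False)
    sho = by_taxon.apply(lambda g: (g["duration_class"] == "shortened").any(), include_groups=False)
    shifted = adv | del_ | pro | sho
    n_taxa = int(df["taxon"].nunique())
    advancing = df[df["mean_date_class"] == "advanced"]
    counts = {
        "advanced": int(adv.sum()),
        "delayed": int(del_.sum()),
        "prolonged": int(pro.sum()),
        "shortened": int(sho.sum()),
        "n_taxa": n_taxa,
        "shifted_any": int(shifted.sum()),
        "pct_shifted": _round_half_up(100.0 * shifted.sum() / n_taxa) if n_taxa else 0,
        "largest_advance": float((-advancing["mean_date_slope"]).max())
        if len(advancing)
        else float("nan"),
    }
    return out, counts


def assemblage_population_summary(
    table: pd.DataFrame, trend_alpha: float = 0.05
) -> dict[str, float | None]:
    """Percent of entities with increasing populations, per trait level.

    The denominator per trait level counts entities with converged,
    significant trends; the numerator counts those with positive trends.
    The overall share uses the taxon count (sex entities collapse to one
    taxon) as its denominator while each entity with an increasing trend
    contributes to the numerator.  Percentages are rounded half-up.
    Levels with no usable entity report None.
    """
    df = table.copy()
    usable = df[df["converged"] & (df["pop_trend_p"] < trend_alpha)]
    out: dict[str, float | None] = {}
    for trait in ("lts", "ldc", "voltinism"):
        for level in sorted(df[trait].dropna().unique()):
            grp = usable[usable[trait] == level]
            if grp.empty:
                out[level] = None
                continue
            out[level] = _round_half_up(100.0 * (grp["pop_trend"] > 0).sum() / len(grp))
    n_increasing = int((usable["pop_trend"] > 0).sum())
    n_taxa_usable = int(usable["taxon"].nunique())
    out["overall"] = (
        _round_half_up(100.0 * n_increasing / n_taxa_usable) if n_taxa_usable else None
    )
    return out


def run_full_analysis(
    config: AnalysisConfig,
    surveys: pd.DataFrame,
    traits: pd.DataFrame,
    climate: pd.DataFrame,
    tree,
    *,
    outdir: str | Path | None = None,
    rules=None,
    per_sex_taxa=(),
) -> dict:
    """Run phenology -> climate -> trends -> comparative -> classification.

    Returns a results bundle (dict of DataFrames plus logs); when
    ``outdir`` is given, writes each table as CSV together with a run log
    and a methods echo restating every threshold used.
    """
    stage = "phenology"
    try:
        summaries = flight_year_summaries(surveys, rules, per_sex_taxa=per_sex_taxa)
        retained, exclusion_log = apply_inclusion_filters(summaries, config)
        analyzed = sorted({s.taxon for s in retained})
        missing_traits = [t for t in analyzed if t not in set(traits["taxon"])]
        # sex entities inherit the traits of their parent taxon
        missing_traits = [
            t for t in missing_traits if t.rsplit(" (", 1)[0] not in set(traits["taxon"])
        ]
        if missing_traits:
            raise ValueError(f"missing traits for analyzed taxa: {missing_traits}")

        stage = "climate"
        annual = annual_climate_table(climate, config)
        climate_trends = climate_trend_summary(annual)

        stage = "trends"
        year_slopes = phenology_year_slopes(retained)
        cue_slopes = sensitivity_slopes(retained, annual)
        pop_rows = []
        df = surveys.copy()
        for taxon in analyzed:
            base = taxon.rsplit(" (", 1)[0]
            sub = df[df["taxon"] == base]
            counts = (
                sub.groupby(["site", "year"])["count"].sum().unstack("year")
            )
            pt = population_trend(counts, taxon=taxon)
            pop_rows.append(
                {
                    "taxon": taxon, "trend": pt.trend, "beta": pt.beta,
                    "p_value": pt.p_value, "converged": pt.converged,
                }
            )
            if not pt.converged:
                logger.warning("population trend for %s did not converge", taxon)
        pop_trends = pd.DataFrame(pop_rows)

        stage = "comparative"
        expanded_traits = traits.copy()
        extra = []
        for t in analyzed:
            if t not in set(expanded_traits["taxon"]):
                base = t.rsplit(" (", 1)[0]
                row = expanded_traits[expanded_traits["taxon"] == base].iloc[0].to_dict()
                row["taxon"] = t
                extra.append(row)
        if extra:
            expanded_traits = pd.concat(
                [expanded_traits, pd.DataFrame(extra)], ignore_index=True
            )
        slopes_tidy = pd.concat([year_slopes, cue_slopes], ignore_index=True)
        pgls_results = trait_sensitivity_analysis(
            slopes_tidy[slopes_tidy["taxon"].isin(analyzed)],
            expanded_traits,
            tree,
            population_trends=pop_trends,
        )

        stage = "classification"
        wide = _results_table(year_slopes, pop_trends, expanded_traits)
        classes, counts = classify_shifts(wide, config.shift_alpha)
        assemblage = assemblage_population_summary(wide, config.trend_alpha)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle = {
        "flight_years": summaries_to_frame(retained),
        "exclusions": exclusion_log,
        "annual_climate": annual,
        "climate_trends": climate_trends,
        "year_slopes": year_slopes,
        "cue_slopes": cue_slopes,
        "population_trends": pop_trends,
        "pgls": pgls_results,
        "results_table": wide,
        "shift_classes": classes,
        "shift_counts": counts,
        "assemblage_summary": assemblage,
    }
    if outdir is not None:
        _write_bundle(bundle, config, Path(outdir))
    return bundle


def _results_table(year_slopes, pop_trends, traits) -> pd.DataFrame:
    md = year_slopes[year_slopes["response"] == "mean_date"].set_index("taxon")
    du = year_slopes[year_slopes["response"] == "duration"].set_index("taxon")
    pt = pop_trends.set_index("taxon")
    tr = traits.set_index("taxon")
    rows = []
    for taxon in md.index:
        base = taxon.rsplit(" (", 1)[0]
        rows.append(
            {
                "entity": taxon,
                "taxon": base,
                "lts": tr.loc[taxon, "lts"] if taxon in tr.index else tr.loc[base, "lts"],
                "ldc": tr.loc[taxon, "ldc"] if taxon in tr.index else tr.loc[base, "ldc"],
                "voltinism": tr.loc[taxon, "voltinism"]
                if taxon in tr.index
                else tr.loc[base, "voltinism"],
                "mean_date_slope": md.loc[taxon, "slope"],
                "mean_date_p": md.loc[taxon, "p_value"],
                "duration_slope": du.loc[taxon, "slope"] if taxon in du.index else np.nan,
                "duration_p": du.loc[taxon, "p_value"] if taxon in du.index else np.nan,
                "pop_trend": pt.loc[taxon, "trend"] if taxon in pt.index else np.nan,
                "pop_trend_p": pt.loc[taxon, "p_value"] if taxon in pt.index else np.nan,
                "converged": bool(pt.loc[taxon, "converged"]) if taxon in pt.index else False,
            }
        )
    return pd.DataFrame(rows)


def _write_bundle(bundle: dict, config: AnalysisConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name in (
        "flight_years", "annual_climate", "climate_trends", "year_slopes",
        "cue_slopes", "population_trends", "pgls", "results_table", "shift_classes",
    ):
        bundle[name].to_csv(outdir / f"{name}.csv", index=False)
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write("exclusions:\n")
        for line in bundle["exclusions"]:
            fh.write(f"  {line}\n")
        fh.write(f"shift_counts: {bundle['shift_counts']}\n")
        fh.write(f"assemblage_summary: {bundle['assemblage_summary']}\n")
    with open(outdir / "methods_echo.txt", "w") as fh:
        fh.write(
            "thresholds used\n"
            f"  gdd_threshold: {config.gdd_threshold} degC\n"
            f"  shift_alpha: {config.shift_alpha}\n"
            f"  trend_alpha: {config.trend_alpha}\n"
            f"  min_counts_per_year: {config.min_counts_per_year}\n"
            f"  min_years: {config.min_years}\n"
            f"  rng_seed: {config.rng_seed}\n"
        )
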