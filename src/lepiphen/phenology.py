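"""Per-taxon, per-year flight phenology from transect counts.

Two metrics summarise a taxon's flight curve within a year:

* **mean flight date** — the abundance-weighted mean of the observation
  dates, ``sum_t p_t * t`` with ``p_t = n_t / N`` the relative abundance
  on day ``t`` and ``N`` the annual total;
* **flight-period duration** — the abundance-weighted (population)
  standard deviation of the observation dates about that mean.

Both are the first two moments of the observed flight curve and are far
less sensitive to sampling effort than first/last-appearance dates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from lepiphen.config import AnalysisConfig


@dataclass(frozen=True)
class FlightYearSummary:
    """Phenology of one taxon in one year."""

    taxon: str
    year: int
    mean_date: float
    duration: float
    total_count: int
    n_visits_with_counts: int


@dataclass(frozen=True)
class FlightPeriodRule:
    """Which part of the season enters the phenology estimate for a taxon.

    ``all_season`` uses every record; ``second_brood_only`` keeps records
    at or after a brood split day (given, or found automatically as the
    deepest trough of a smoothed daily-count profile between the two
    largest modes); ``combined_broods`` deliberately spans both broods.
    """

    taxon: str
    mode: str = "all_season"
    brood_split_day: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("all_season", "second_brood_only", "combined_broods"):
            raise ValueError(f"unknown flight-period mode {self.mode!r}")


def _days_counts(records) -> tuple[np.ndarray, np.ndarray]:
    """Coerce {day: count} mappings or survey frames to day/count arrays."""
    if isinstance(records, Mapping):
        days = np.array(sorted(records), dtype=float)
        counts = np.array([records[d] for d in sorted(records)], dtype=float)
    else:
        df = pd.DataFrame(records)
        grouped = df.groupby("julian_day")["count"].sum().sort_index()
        days = grouped.index.to_numpy(dtype=float)
        counts = grouped.to_numpy(dtype=float)
    keep = counts > 0
    return days[keep], counts[keep]


def weighted_mean_date(records) -> float:
    """Abundance-weighted mean Julian day for one taxon-year.

    ``records`` is either a mapping {julian_day: count} or a frame with
    ``julian_day``/``count`` columns.  Raises ``ValueError`` when no
    individuals were counted (the mean is then undefined).
    """
    days, counts = _days_counts(records)
    total = counts.sum()
    if total < 1:
        raise ValueError("no individuals counted: mean flight date undefined")
    return float(np.dot(days, counts) / total)


def flight_duration(records) -> float:
    """Abundance-weighted population SD of observation dates (days).

    Zero for a single observation date.  Uses the same relative-abundance
    weights as the mean date, so it is invariant to rescaling all counts.
    """
    days, counts = _days_counts(records)
    total = counts.sum()
    if total < 1:
        raise ValueError("no individuals counted: duration undefined")
    mean = np.dot(days, counts) / total
    var = np.dot(counts, (days - mean) ** 2) / total
    return float(np.sqrt(var))


def select_flight_period(records: pd.DataFrame, rule: FlightPeriodRule) -> pd.DataFrame:
    """Filter one taxon-year's records according to its flight-period rule."""
    if rule.mode in ("all_season", "combined_broods"):
        return records
    split = rule.brood_split_day
    if split is None:
        split = _automatic_brood_split(records)
        if split is None:
            warnings.warn(
                f"{rule.taxon}: no bimodal structure found; keeping all records",
                stacklevel=2,
            )
            return records
    kept = records[records["julian_day"] >= split]
    return kept


def _automatic_brood_split(records: pd.DataFrame, window: int = 7) -> int | None:
    """Deepest trough between the two largest modes of a smoothed profile.

    The daily-count profile is smoothed with a ``window``-day moving
    average; modes are local maxima of the smoothed profile.  Returns the
    day of the minimum between the two largest modes, ties broken toward
    the earlier day, or None when the profile is unimodal.
    """
    grouped = records.groupby("julian_day")["count"].sum()
    if grouped.empty:
        return None
    lo, hi = int(grouped.index.min()), int(grouped.index.max())
    profile = grouped.reindex(range(lo, hi + 1), fill_value=0).to_numpy(dtype=float)
    smooth = np.convolve(profile, np.ones(window) / window, mode="same")
    peaks = [
        i
        for i in range(1, len(smooth) - 1)
        if smooth[i] > smooth[i - 1] and smooth[i] >= smooth[i + 1]
    ]
    if len(peaks) < 2:
        return None
    top_two = sorted(sorted(peaks, key=lambda i: -smooth[i])[:2])
    a, b = top_two
    seg = smooth[a : b + 1]
    trough = a + int(np.argmin(seg))  # argmin takes the earliest minimum on ties
    return lo + trough


def flight_year_summaries(
    surveys: pd.DataFrame,
    rules: Mapping[str, FlightPeriodRule] | None = None,
    *,
    per_sex_taxa: Iterable[str] = (),
) -> list[FlightYearSummary]:
    """Compute FlightYearSummary rows for every taxon-year with counts.

    Taxa listed in ``per_sex_taxa`` are split into one analysis entity per
    sex (labelled ``taxon (F)`` / ``taxon (M)``), as appropriate for
    sexually dichromatic species whose sexes fly on different schedules.
    Years in which a taxon was surveyed but never counted yield no row.
    """
    rules = rules or {}
    df = surveys.copy()
    per_sex = set(per_sex_taxa)
    sex_tag = {"female": " (F)", "male": " (M)", "unknown": ""}
    df["entity"] = [
        t + sex_tag[s] if t in per_sex else t for t, s in zip(df["taxon"], df["sex"])
    ]
    out: list[FlightYearSummary] = []
    for (entity, year), grp in df.groupby(["entity", "year"], sort=True):
        rule = rules.get(entity) or rules.get(grp["taxon"].iloc[0])
        if rule is not None:
            grp = select_flight_period(grp, rule)
        grp = grp[grp["count"] > 0]
        if grp.empty:
            continue
        out.append(
            FlightYearSummary(
                taxon=entity,
                year=int(year),
                mean_date=weighted_mean_date(grp),
                duration=flight_duration(grp),
                total_count=int(grp["count"].sum()),
                n_visits_with_counts=int(len(grp)),
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[FlightYearSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": s.taxon,
                "year": s.year,
                "mean_date": s.mean_date,
                "duration": s.duration,
                "total_count": s.total_count,
                "n_visits_with_counts": s.n_visits_with_counts,
            }
            for s in summaries
        ],
        columns=["taxon", "year", "mean_date", "duration", "total_count", "n_visits_with_counts"],
    )


def apply_inclusion_filters(
    summaries: Iterable[FlightYearSummary], config: AnalysisConfig
) -> tuple[list[FlightYearSummary], list[str]]:
    """Drop infrequently observed taxa; return retained rows + exclusion log.

    A taxon-year is retained when its total count exceeds
    ``min_counts_per_year``; a taxon is retained when it keeps more than
    ``min_years`` such years.  The log records which rule fired for every
    exclusion.
    """
    summaries = list(summaries)
    log: list[str] = []
    retained: list[FlightYearSummary] = []
    by_taxon: dict[str, list[FlightYearSummary]] = {}
    for s in summaries:
        by_taxon.setdefault(s.taxon, []).append(s)
    for taxon in sorted(by_taxon):
        rows = by_taxon[taxon]
        good_years = [s for s in rows if s.total_count > config.min_counts_per_year]
        dropped = len(rows) - len(good_years)
        if dropped:
            log.append(
                f"{taxon}: dropped {dropped} year(s) with <= {config.min_counts_per_year} counts"
            )
        if len(good_years) <= config.min_years:
            log.append(
                f"{taxon}: excluded, <= {config.min_years} years of records "
                f"({len(good_years)} usable year(s))"
            )
            continue
        retained.extend(sorted(good_years, key=lambda s: s.year))
    return retained, log
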