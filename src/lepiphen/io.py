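"""Readers and writers for survey, trait and climate tables and phylogenies.

Tables are plain CSV with a header row; trees are Newick.  Survey and
climate tables are returned as pandas DataFrames with validated, typed
columns; the per-row domain types are available as dataclasses for code
that works record-wise.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

SEXES = ("male", "female", "unknown")
LTS_LEVELS = ("oligophagous", "polyphagous")
LDC_LEVELS = ("herb", "woody")
VOLTINISM_LEVELS = ("univoltine", "multivoltine")


@dataclass(frozen=True)
class SurveyRecord:
    """One transect visit for one taxon: the count of individuals seen."""

    date: _dt.date
    julian_day: int
    site: str
    taxon: str
    sex: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        if not 1 <= self.julian_day <= 366:
            raise ValueError(f"julian_day out of [1, 366]: {self.julian_day}")
        if self.julian_day != self.date.timetuple().tm_yday:
            raise ValueError(
                f"julian_day {self.julian_day} inconsistent with date {self.date}"
            )


@dataclass(frozen=True)
class TaxonTraits:
    taxon: str
    lts: str
    ldc: str
    voltinism: str

    def __post_init__(self) -> None:
        for name, levels in (
            ("lts", LTS_LEVELS),
            ("ldc", LDC_LEVELS),
            ("voltinism", VOLTINISM_LEVELS),
        ):
            if getattr(self, name) not in levels:
                raise ValueError(f"{name} must be one of {levels}, got {getattr(self, name)!r}")


@dataclass(frozen=True)
class DailyClimate:
    date: _dt.date
    t_max: float
    t_min: float
    precip: float

    def __post_init__(self) -> None:
        if self.t_max < self.t_min:
            raise ValueError(f"t_max < t_min on {self.date}")
        if self.precip < 0:
            raise ValueError(f"negative precipitation on {self.date}")


def read_surveys(path: str | Path, config=None) -> pd.DataFrame:
    """Read a survey CSV (date,site,taxon[,sex],count) into a typed frame.

    Adds a 1-based ``julian_day`` day-of-year column.  Rows with negative
    counts, malformed dates or non-integer counts raise ``ValueError``
    naming the offending row.
    """
    df = pd.read_csv(path, dtype={"site": str, "taxon": str})
    required = {"date", "site", "taxon", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed date in survey table: {exc}") from exc
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts != counts.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"non-integer count in survey row {row + 2} (1-based, incl. header)")
    if (counts < 0).any():
        row = int(np.flatnonzero((counts < 0).to_numpy())[0])
        raise ValueError(f"negative count in survey row {row + 2} (1-based, incl. header)")
    df["count"] = counts.astype(int)
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    df["sex"] = df["sex"].fillna("unknown").replace("", "unknown")
    unknown_sex = ~df["sex"].isin(SEXES)
    if unknown_sex.any():
        raise ValueError(f"unrecognized sex values: {sorted(df.loc[unknown_sex, 'sex'].unique())}")
    df["julian_day"] = df["date"].dt.dayofyear
    df["year"] = df["date"].dt.year
    return df


def write_surveys(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[["date", "site", "taxon", "sex", "count"]].to_csv(path, index=False)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a traits CSV (taxon,lts,ldc,voltinism); validates factor levels."""
    df = pd.read_csv(path, dtype=str)
    records = [
        TaxonTraits(r.taxon, r.lts, r.ldc, r.voltinism) for r in df.itertuples(index=False)
    ]
    if len({t.taxon for t in records}) != len(records):
        raise ValueError("duplicate taxon in traits table")
    return df


def read_climate(path: str | Path) -> pd.DataFrame:
    """Read a daily climate CSV (date,tmax,tmin,prcp) into a typed frame."""
    df = pd.read_csv(path)
    required = {"date", "tmax", "tmin", "prcp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    if (df["tmax"] < df["tmin"]).any():
        bad = df.loc[df["tmax"] < df["tmin"], "date"].iloc[0]
        raise ValueError(f"t_max < t_min on {bad.date()}")
    if (df["prcp"] < 0).any():
        bad = df.loc[df["prcp"] < 0, "date"].iloc[0]
        raise ValueError(f"negative precipitation on {bad.date()}")
    return df


def write_climate(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[["date", "tmax", "tmin", "prcp"]].to_csv(path, index=False)


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = np.array([leaf.distance_from_root() for leaf in tree.leaf_node_iter()])
    span = depths.max() - depths.min()
    return bool(span <= rel_tol * max(depths.max(), 1.0))


def read_tree(
    path: str | Path | None = None,
    *,
    data: str | None = None,
    taxa: Iterable[str] | None = None,
    require_ultrametric: bool = False,
) -> dendropy.Tree:
    """Read a Newick phylogeny and validate it against the analyzed taxa.

    Branch lengths must be non-negative and tip labels unique.  A
    non-ultrametric tree triggers a warning, or an error when
    ``require_ultrametric`` is set (the Ornstein-Uhlenbeck covariance
    assumes equal root-to-tip depths).  When ``taxa`` is given, tips must
    cover it; missing taxa are reported by name.
    """
    if (path is None) == (data is None):
        raise ValueError("pass exactly one of path= or data=")
    kwargs = {"path": str(path)} if path is not None else {"data": data}
    tree = dendropy.Tree.get(schema="newick", preserve_underscores=True, **kwargs)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")
    if not is_ultrametric(tree):
        if require_ultrametric:
            raise ValueError("tree is not ultrametric (required for the OU model)")
        warnings.warn("tree is not ultrametric; OU fits will be rejected", stacklevel=2)
    if taxa is not None:
        missing = sorted(set(taxa) - set(labels))
        if missing:
            raise ValueError(f"tree is missing tips for taxa: {missing}")
    return tree
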