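"""Analysis configuration: thresholds, filters and seasonal windows."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

# Seasonal cue windows, as (year_offset, month) pairs relative to the focal
# survey year.  The annual cue starts the month after the last survey month
# (October of the previous year); spring-summer overlaps the surveys;
# autumn-winter precedes them.
CUE_ANNUAL = tuple((-1, m) for m in (10, 11, 12)) + tuple((0, m) for m in range(1, 10))
CUE_SPRING_SUMMER = tuple((0, m) for m in range(3, 9))
CUE_AUTUMN_WINTER = tuple((-1, m) for m in (9, 10, 11, 12)) + tuple((0, m) for m in (1, 2))


@dataclass
class AnalysisConfig:
    """Tunable constants of the analysis pipeline.

    Parameters
    ----------
    gdd_threshold:
        Developmental base temperature (degC) for growing degree days.
        10 degC is the usual minimal thermal condition for butterfly
        development.
    shift_alpha:
        Significance threshold for classifying a phenological shift
        (advanced/delayed, prolonged/shortened).  The default 0.07 counts
        marginal shifts.
    trend_alpha:
        Significance threshold for accepting a population trend.
    min_counts_per_year:
        Years with this many or fewer individuals of a taxon are dropped
        before phenology estimation.
    min_years:
        Taxa observed in this many or fewer (retained) years are excluded.
    rng_seed:
        Seed for every stochastic component.
    """

    gdd_threshold: float = 10.0
    shift_alpha: float = 0.07
    trend_alpha: float = 0.05
    min_counts_per_year: int = 4
    min_years: int = 4
    cue_windows: dict = field(
        default_factory=lambda: {
            "cue_annual": CUE_ANNUAL,
            "cue_spring_summer": CUE_SPRING_SUMMER,
            "cue_autumn_winter": CUE_AUTUMN_WINTER,
        }
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shift_alpha", "trend_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if "cue_windows" in known:
            cfg.cue_windows = {
                k: tuple(tuple(p) for p in v) for k, v in known["cue_windows"].items()
            }
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cue_windows"] = {k: [list(p) for p in v] for k, v in self.cue_windows.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
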