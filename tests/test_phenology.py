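"""Weighted phenology metrics, flight-period selection and inclusion filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lepiphen.config import AnalysisConfig
from lepiphen.phenology import (
    FlightPeriodRule,
    FlightYearSummary,
    apply_inclusion_filters,
    flight_duration,
    flight_year_summaries,
    select_flight_period,
    weighted_mean_date,
)

count_tables = st.dictionaries(
    st.integers(min_value=1, max_value=366),
    st.integers(min_value=0, max_value=50),
    min_size=1,
    max_size=12,
).filter(lambda d: sum(d.values()) >= 1)


class TestWeightedMeanDate:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({100: 5}, 100.0),
            ({100: 2, 200: 2}, 150.0),
            ({100: 1, 110: 3}, 107.5),
        ],
    )
    def test_examples(self, counts, expected):
        assert weighted_mean_date(counts) == pytest.approx(expected)

    def test_all_zero_counts_signalled(self):
        with pytest.raises(ValueError, match="undefined"):
            weighted_mean_date({100: 0, 110: 0})


class TestFlightDuration:
    @pytest.mark.parametrize(
        "counts,expected", [({150: 7}, 0.0), ({10: 1, 20: 1}, 5.0)]
    )
    def test_examples(self, counts, expected):
        assert flight_duration(counts) == pytest.approx(expected)

    @given(count_tables)
    @settings(max_examples=60, derandomize=True)
    def test_scale_invariance(self, counts):
        scaled = {d: 10 * c for d, c in counts.items()}
        assert flight_duration(scaled) == pytest.approx(flight_duration(counts))
        assert weighted_mean_date(scaled) == pytest.approx(weighted_mean_date(counts))

    @given(count_tables, st.integers(min_value=-50, max_value=50))
    @settings(max_examples=60, derandomize=True)
    def test_translation_equivariance(self, counts, shift):
        shifted = {d + shift: c for d, c in counts.items()}
        assert weighted_mean_date(shifted) == pytest.approx(
            weighted_mean_date(counts) + shift
        )
        assert flight_duration(shifted) == pytest.approx(flight_duration(counts))

    @given(count_tables)
    @settings(max_examples=60, derandomize=True)
    def test_matches_brute_force_moment_oracle(self, counts):
        # expand to one entry per individual and take plain moments
        expanded = np.repeat(
            list(counts.keys()), list(counts.values())
        ).astype(float)
        assert weighted_mean_date(counts) == pytest.approx(expanded.mean())
        assert flight_duration(counts) == pytest.approx(expanded.std(ddof=0))


def _frame(day_counts: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"julian_day": list(day_counts), "count": list(day_counts.values())}
    )


class TestSelectFlightPeriod:
    def test_all_season_is_identity(self):
        df = _frame({120: 5, 200: 4})
        rule = FlightPeriodRule("X", "all_season")
        pd.testing.assert_frame_equal(select_flight_period(df, rule), df)

    def test_explicit_split_keeps_late_records(self):
        df = _frame({120: 5, 130: 6, 200: 4, 210: 5})
        rule = FlightPeriodRule("X", "second_brood_only", brood_split_day=165)
        kept = select_flight_period(df, rule)
        assert sorted(kept["julian_day"]) == [200, 210]

    def test_automatic_split_on_bimodal_profile(self):
        days = {d: 10 for d in range(120, 141)} | {d: 12 for d in range(200, 221)}
        days[170] = 0
        rule = FlightPeriodRule("X", "second_brood_only")
        kept = select_flight_period(_frame(days), rule)
        assert kept["julian_day"].min() >= 150

    def test_unimodal_profile_warns_and_keeps_all(self):
        df = _frame({150: 2, 157: 5, 164: 2})
        rule = FlightPeriodRule("X", "second_brood_only")
        with pytest.warns(UserWarning, match="keeping all"):
            kept = select_flight_period(df, rule)
        assert len(kept) == len(df)


def _summary(taxon, year, total=10):
    return FlightYearSummary(taxon, year, 200.0, 5.0, total, 4)


class TestInclusionFilters:
    def test_few_years_excluded_with_reason(self):
        cfg = AnalysisConfig()
        rows = [_summary("A", y) for y in (2010, 2011, 2012)]
        retained, log = apply_inclusion_filters(rows, cfg)
        assert retained == []
        assert any("A" in line and "4 years" in line for line in log)

    def test_low_count_years_dropped_before_year_rule(self):
        cfg = AnalysisConfig()
        rows = [_summary("A", y, total=3) for y in range(2007, 2017)]
        retained, log = apply_inclusion_filters(rows, cfg)
        assert retained == []
        assert any("<= 4 counts" in line for line in log)

    def test_well_observed_taxon_retained(self):
        cfg = AnalysisConfig()
        rows = [_summary("A", y, total=5) for y in range(2007, 2017)]
        retained, log = apply_inclusion_filters(rows, cfg)
        assert len(retained) == 10

    def test_empty_input(self):
        retained, log = apply_inclusion_filters([], AnalysisConfig())
        assert retained == [] and log == []


class TestFlightYearSummaries:
    def test_per_sex_entities_split(self):
        df = pd.DataFrame(
            {
                "date": pd.to_datetime(["2010-06-01", "2010-07-01"]),
                "site": ["S1", "S1"],
                "taxon": ["Regal", "Regal"],
                "sex": ["male", "female"],
                "count": [3, 2],
            }
        )
        df["julian_day"] = df["date"].dt.dayofyear
        df["year"] = df["date"].dt.year
        out = flight_year_summaries(df, per_sex_taxa=["Regal"])
        assert {s.taxon for s in out} == {"Regal (M)", "Regal (F)"}

    def test_zero_count_year_yields_no_row(self):
        df = pd.DataFrame(
            {
                "date": pd.to_datetime(["2010-06-01"]),
                "site": ["S1"],
                "taxon": ["A"],
                "sex": ["unknown"],
                "count": [0],
            }
        )
        df["julian_day"] = df["date"].dt.dayofyear
        df["year"] = df["date"].dt.year
        assert flight_year_summaries(df) == []


class TestEstimatorConsistency:
    def test_mean_and_duration_converge_to_truth(self):
        """At very high abundance the moments recover the Gaussian flight curve."""
        from lepiphen.simulate import SimScenario, TaxonSimParams, simulate_transects

        params = [TaxonSimParams("X", mu0=200.0, sigma0=10.0, n_per_year=10_000)]
        scen = SimScenario(years=(2010, 2010), n_sites=1, site_effects=(1.0,), rng_seed=7)
        surveys, _ = simulate_transects(params, scen)
        out = flight_year_summaries(surveys)
        assert len(out) == 1
        assert out[0].mean_date == pytest.approx(200.0, abs=0.5)
        assert out[0].duration == pytest.approx(10.0, abs=0.5)
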