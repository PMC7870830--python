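"""Robust slopes (Siegel / Theil-Sen) and TRIM-style population trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lepiphen.phenology import FlightYearSummary
from lepiphen.trends import (
    impute_counts,
    median_based_linear_model,
    population_trend,
    sensitivity_slopes,
)


class TestSiegelSlopes:
    def test_collinear_exact(self):
        x = np.arange(1.0, 8.0)
        est = median_based_linear_model(x, 3.0 * x - 2.0)
        assert est.slope == pytest.approx(3.0, abs=1e-12)
        assert est.intercept == pytest.approx(-2.0, abs=1e-12)

    def test_single_outlier_ignored(self):
        est = median_based_linear_model([1, 2, 3, 4, 5], [1, 2, 3, 4, 100])
        assert est.slope == pytest.approx(1.0)

    def test_breakdown_point(self):
        # corrupting floor((n-1)/2) = 5 of 11 collinear points leaves the
        # repeated-medians slope exact
        x = np.arange(11.0)
        y = 2.0 * x + 1.0
        y[[0, 2, 4, 6, 8]] += np.array([50.0, -30.0, 80.0, -120.0, 60.0])
        est = median_based_linear_model(x, y)
        assert est.slope == pytest.approx(2.0, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="predictor"):
            median_based_linear_model([2, 2, 2, 2], [1, 2, 3, 4])

    def test_matches_scipy_reference(self, rng):
        # scipy's siegelslopes implements the same hierarchical-medians
        # estimator and serves as an independent oracle
        for _ in range(25):
            x = rng.standard_normal(rng.integers(5, 30))
            y = 1.5 * x + rng.standard_normal(x.size)
            est = median_based_linear_model(x, y)
            ref = stats.siegelslopes(y, x)
            assert est.slope == pytest.approx(ref.slope, rel=1e-9, abs=1e-9)

    def test_theil_sen_matches_scipy(self, rng):
        for _ in range(25):
            x = np.arange(rng.integers(5, 25), dtype=float)
            y = -0.5 * x + rng.standard_normal(x.size)
            est = median_based_linear_model(x, y, method="theil_sen")
            ref = stats.theilslopes(y, x)
            assert est.slope == pytest.approx(ref.slope, rel=1e-9, abs=1e-9)

    def test_null_slope_centred_on_zero(self, rng):
        # response unrelated to predictor: slopes scatter tightly around
        # zero.  The signed-rank p-values are known to be liberal (the
        # per-point medians are correlated), so only weak calibration is
        # asserted; see the methods note.
        x = np.arange(20.0)
        pvals, slopes = [], []
        for _ in range(100):
            est = median_based_linear_model(x, rng.standard_normal(20))
            pvals.append(est.p_value)
            slopes.append(est.slope)
        assert abs(np.median(slopes)) < 0.05
        assert np.median(pvals) > 0.05
        assert np.mean(np.array(pvals) < 0.05) < 0.5


def _counts_frame(values: dict[str, dict[int, float]]) -> pd.DataFrame:
    return pd.DataFrame(values).T


class TestPopulationTrend:
    def test_exact_loglinear_single_site(self):
        years = range(2007, 2017)
        counts = _counts_frame({"S1": {y: 10.0 * np.exp(0.1 * (y - 2007)) for y in years}})
        pt = population_trend(counts)
        assert pt.converged
        assert pt.beta == pytest.approx(0.1, abs=1e-6)

    def test_equal_counts_zero_trend(self):
        counts = _counts_frame({s: {y: 25.0 for y in range(2010, 2016)} for s in ("S1", "S2")})
        pt = population_trend(counts)
        assert pt.beta == pytest.approx(0.0, abs=1e-8)
        assert pt.trend == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_counts_flagged(self):
        counts = _counts_frame({"S1": {y: 0.0 for y in range(2010, 2016)}})
        pt = population_trend(counts)
        assert not pt.converged and pt.trend is None

    def test_missing_cell_imputed_with_model_prediction(self):
        years = range(2010, 2016)
        counts = _counts_frame(
            {
                "S1": {y: 20.0 * np.exp(0.05 * (y - 2010)) for y in years},
                "S2": {y: 40.0 * np.exp(0.05 * (y - 2010)) for y in years},
            }
        )
        counts.loc["S2", 2013] = np.nan
        completed = impute_counts(counts)
        # the model surface is exact, so the imputed cell must match it
        assert completed.loc["S2", 2013] == pytest.approx(40.0 * np.exp(0.05 * 3), rel=1e-4)
        # refitting on the completed table leaves the trend unchanged
        b1 = population_trend(counts).beta
        b2 = population_trend(completed).beta
        assert b1 == pytest.approx(b2, abs=1e-6)

    @pytest.mark.parametrize("beta_true", [-0.1, 0.0, 0.1])
    def test_poisson_recovery_unbiased(self, beta_true, rng):
        """beta-hat is unbiased within Monte-Carlo error (mean 50, 10 yr, 5 sites)."""
        est = []
        for _ in range(60):
            lam = 50.0 * np.exp(beta_true * np.arange(10))
            data = {
                f"S{s}": {2007 + y: float(rng.poisson(lam[y])) for y in range(10)}
                for s in range(5)
            }
            pt = population_trend(_counts_frame(data))
            est.append(pt.beta)
        err = np.mean(est) - beta_true
        mc_se = np.std(est) / np.sqrt(len(est))
        assert abs(err) < max(4 * mc_se, 5e-3)


class TestSensitivitySlopes:
    def _summaries(self, durations):
        return [
            FlightYearSummary("X", 2007 + i, 200.0, d, 50, 5) for i, d in enumerate(durations)
        ]

    def test_exact_linear_response_to_cue(self):
        cues = pd.DataFrame(
            {"year": range(2007, 2013), "cue_spring_summer": [10, 12, 11, 14, 13, 15],
             "cue_annual": 10.0, "cue_autumn_winter": 5.0}
        )
        durations = 2.0 * cues["cue_spring_summer"] + 5.0
        out = sensitivity_slopes(self._summaries(durations), cues)
        row = out[(out.response == "duration") & (out.predictor == "cue_spring_summer")]
        assert row["slope"].iloc[0] == pytest.approx(2.0, abs=1e-10)

    def test_too_few_overlapping_years_skipped(self):
        cues = pd.DataFrame(
            {"year": [2007, 2008], "cue_spring_summer": [10.0, 12.0],
             "cue_annual": 10.0, "cue_autumn_winter": 5.0}
        )
        out = sensitivity_slopes(self._summaries([20.0, 22.0]), cues)
        assert out.empty
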