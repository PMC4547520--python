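"""Regression validation and the packaged score -> IQ predictors."""

import numpy as np
import pytest

from nartscale import (
    MINI_NART_MODEL,
    NART_MODEL,
    conversion_table,
    criterion_correlation,
    fit_predictor,
    predict_iq,
)


class TestPackagedModels:
    def test_published_equations(self):
        assert (MINI_NART_MODEL.intercept, MINI_NART_MODEL.slope) == (64.94, 2.345)
        assert MINI_NART_MODEL.slope_ci == (2.13, 2.56)
        assert (NART_MODEL.intercept, NART_MODEL.slope) == (55.97, 1.306)
        assert NART_MODEL.slope_ci == (1.19, 1.42)

    @pytest.mark.parametrize(
        "model, score, point, lo, hi",
        [
            (MINI_NART_MODEL, 20, 111.84, 107.54, 116.14),
            (NART_MODEL, 45, 114.74, 109.52, 119.87),
        ],
    )
    def test_worked_examples(self, model, score, point, lo, hi):
        est = predict_iq(model, score)
        assert est.rounded() == (point, lo, hi)

    def test_score_zero_returns_intercept(self):
        est = predict_iq(MINI_NART_MODEL, 0)
        assert est.point == pytest.approx(64.94)
        assert est.ci_low == est.ci_high == pytest.approx(64.94)

    def test_score_out_of_range_names_maximum(self):
        with pytest.raises(ValueError, match="23"):
            predict_iq(MINI_NART_MODEL, 24)
        with pytest.raises(ValueError):
            predict_iq(NART_MODEL, -1)

    def test_prediction_interval_unavailable_for_packaged_models(self):
        with pytest.raises(ValueError, match="packaged"):
            predict_iq(MINI_NART_MODEL, 10, interval="prediction")


class TestFitPredictor:
    def test_noise_free_line_recovered_exactly(self):
        scores = np.arange(0, 24, dtype=float)
        iq = 64.94 + 2.345 * scores
        model = fit_predictor(scores, iq)
        assert model.intercept == pytest.approx(64.94, abs=1e-9)
        assert model.slope == pytest.approx(2.345, abs=1e-12)
        assert model.r_squared == pytest.approx(1.0)

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(17)
        scores = rng.integers(0, 24, size=500).astype(float)
        iq = 60.0 + 2.5 * scores + rng.normal(0.0, 5.0, size=500)
        model = fit_predictor(scores, iq)
        lo, hi = model.slope_ci
        se = (hi - lo) / (2 * 1.96)
        assert abs(model.slope - 2.5) < 3 * se
        assert lo <= model.slope <= hi

    def test_unrelated_criterion_gives_near_zero_r_squared(self):
        rng = np.random.default_rng(23)
        scores = rng.integers(0, 24, size=4000).astype(float)
        iq = rng.normal(100.0, 15.0, size=4000)
        model = fit_predictor(scores, iq)
        assert model.r_squared < 0.01

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_predictor([5.0, 5.0, 5.0, 5.0], [90.0, 95.0, 100.0, 105.0])

    def test_prediction_interval_contains_point_and_widens(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 24, size=200).astype(float)
        iq = 65.0 + 2.3 * scores + rng.normal(0.0, 5.0, size=200)
        model = fit_predictor(scores, iq, max_score=23)
        centre = predict_iq(model, 12, interval="prediction")
        edge = predict_iq(model, 23, interval="prediction")
        assert centre.ci_low <= centre.point <= centre.ci_high
        assert (edge.ci_high - edge.ci_low) > 0

    def test_linearity_of_predictions(self):
        scores = np.arange(24, dtype=float)
        iq = 64.94 + 2.345 * scores
        model = fit_predictor(scores, iq)
        points = [predict_iq(model, s).point for s in (0, 10, 20)]
        assert points[2] - points[1] == pytest.approx(points[1] - points[0])


class TestConversionTable:
    def test_mini_table_rows_and_ceiling(self):
        table = conversion_table(MINI_NART_MODEL)
        assert len(table) == 24
        assert table["iq_rounded"].iloc[23] == 119
        assert table["predicted_iq"].iloc[0] == pytest.approx(64.94)

    def test_full_table_ceiling(self):
        table = conversion_table(NART_MODEL)
        assert len(table) == 51
        assert table["iq_rounded"].iloc[50] == 121

    def test_ci_width_grows_linearly(self):
        table = conversion_table(MINI_NART_MODEL)
        widths = table["ci_high"] - table["ci_low"]
        diffs = np.diff(widths)
        assert diffs == pytest.approx(np.full(23, diffs[0]))


class TestCriterionCorrelation:
    def test_perfect_line(self):
        x = np.arange(10, dtype=float)
        assert criterion_correlation(x, 3 * x + 1) == pytest.approx(1.0)

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(68)
        n = 5000
        rho = 0.68
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        se = (1 - rho**2) / np.sqrt(n)
        assert abs(criterion_correlation(x, y) - rho) < 3 * se

    def test_independent_near_zero(self):
        rng = np.random.default_rng(9)
        assert abs(
            criterion_correlation(
                rng.standard_normal(5000), rng.standard_normal(5000)
            )
        ) < 3 / np.sqrt(5000)

    def test_r_squared_equals_squared_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 24, size=300).astype(float)
        y = 60 + 2.0 * x + rng.normal(0, 8, size=300)
        model = fit_predictor(x, y)
        assert model.r_squared == pytest.approx(
            criterion_correlation(x, y) ** 2, abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            criterion_correlation([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])
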