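"""Criterion validation: predicting premorbid IQ from reading-scale scores.

The validation study regressed age-11 IQ on the number of correctly
pronounced words, yielding linear predictors for both the 23-item
hierarchical subset ("mini-NART") and the full 50-item test.  The
published equations are packaged here verbatim:

    mini-NART:  IQ = 64.94 + 2.345 * score,  slope 95% CI [2.13, 2.56]
    full NART:  IQ = 55.97 + 1.306 * score,  slope 95% CI [1.19, 1.42]

The published interval convention applies the slope's 95% CI with a fixed
intercept, so the CI of a prediction at score s is
intercept + [slope_lo, slope_hi] * s; its width grows linearly in s and is
zero at s = 0.  ``predict_iq`` reproduces this convention by default and
additionally offers a conventional regression prediction interval for
models fitted from data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "PredictorModel",
    "IQEstimate",
    "MINI_NART_MODEL",
    "NART_MODEL",
    "fit_predictor",
    "predict_iq",
    "conversion_table",
    "criterion_correlation",
]


@dataclass(frozen=True)
class PredictorModel:
    """Linear score -> IQ predictor with a slope confidence interval."""

    intercept: float
    slope: float
    slope_ci: tuple[float, float]
    r_squared: float | None
    n: int | None
    label: str
    max_score: int | None = None
    # residual statistics enabling prediction intervals (fitted models only)
    _pred_stats: tuple[float, float, float, int] | None = None  # mse, xbar, sxx, df

    def __post_init__(self):
        lo, hi = self.slope_ci
        if not lo <= self.slope <= hi:
            raise ValueError("slope must lie within its confidence interval")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "intercept": self.intercept,
            "slope": self.slope,
            "slope_ci": list(self.slope_ci),
            "r_squared": self.r_squared,
            "n": self.n,
            "max_score": self.max_score,
        }


@dataclass(frozen=True)
class IQEstimate:
    point: float
    ci_low: float
    ci_high: float
    score: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round(self.point, ndigits),
            round(self.ci_low, ndigits),
            round(self.ci_high, ndigits),
        )


#: Published predictor for the 23-item invariantly ordered subset.
MINI_NART_MODEL = PredictorModel(
    intercept=64.94,
    slope=2.345,
    slope_ci=(2.13, 2.56),
    r_squared=0.448,
    n=587,
    label="mini-NART",
    max_score=23,
)

#: Published predictor for the full 50-item test.
NART_MODEL = PredictorModel(
    intercept=55.97,
    slope=1.306,
    slope_ci=(1.19, 1.42),
    r_squared=0.465,
    n=587,
    label="NART",
    max_score=50,
)

PACKAGED_MODELS = {"mini-nart": MINI_NART_MODEL, "nart": NART_MODEL}


def fit_predictor(
    scores,
    criterion,
    label: str = "fitted",
    max_score: int | None = None,
) -> PredictorModel:
    """Ordinary least squares of criterion IQ on scale scores.

    Returns the fitted intercept, slope with its 95% confidence interval,
    and R-squared (variance accounted for).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(criterion, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and criterion must be paired 1-d arrays")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0.0:
        raise ValueError("scores are constant; slope is undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    xbar = float(x.mean())
    sxx = float(np.sum((x - xbar) ** 2))
    return PredictorModel(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        r_squared=float(res.rsquared),
        n=int(x.size),
        label=label,
        max_score=max_score,
        _pred_stats=(float(res.mse_resid), xbar, sxx, int(res.df_resid)),
    )


def predict_iq(
    model: PredictorModel, score: float, interval: str = "slope"
) -> IQEstimate:
    """Predicted IQ with a 95% interval for an observed scale score.

    ``interval="slope"`` (default) follows the published convention:
    bounds are intercept + slope-CI-bound * score.  ``interval="prediction"``
    gives a conventional 95% prediction interval for a new observation and
    requires a model fitted from data.
    """
    if score < 0 or (model.max_score is not None and score > model.max_score):
        raise ValueError(
            f"score {score} out of range for {model.label} "
            f"(maximum {model.max_score})"
        )
    point = model.intercept + model.slope * score
    if interval == "slope":
        lo = model.intercept + model.slope_ci[0] * score
        hi = model.intercept + model.slope_ci[1] * score
    elif interval == "prediction":
        if model._pred_stats is None:
            raise ValueError(
                "prediction intervals need a model fitted from data; "
                f"{model.label!r} is a packaged equation"
            )
        mse, xbar, sxx, df = model._pred_stats
        se = np.sqrt(mse * (1.0 + 1.0 / model.n + (score - xbar) ** 2 / sxx))
        t = sps.t.ppf(0.975, df)
        lo, hi = point - t * se, point + t * se
    else:
        raise ValueError(f"unknown interval type {interval!r}")
    return IQEstimate(float(point), float(lo), float(hi), float(score))


def conversion_table(model: PredictorModel, max_score: int | None = None):
    """Score -> predicted IQ table for integer scores 0..max_score.

    Columns: raw predicted value and interval bounds (2 d.p. presentation
    precision is left to the caller) plus the nearest-integer IQ.
    """
    import pandas as pd

    if max_score is None:
        max_score = model.max_score
    if max_score is None or max_score < 1:
        raise ValueError("max_score must be >= 1")
    rows = []
    for s in range(0, max_score + 1):
        est = predict_iq(model, s)
        rows.append(
            {
                "score": s,
                "predicted_iq": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "iq_rounded": int(round(est.point)),
            }
        )
    return pd.DataFrame(rows)


def criterion_correlation(scores, criterion) -> float:
    """Pearson product-moment correlation between scores and criterion."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(criterion, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired arrays with at least 3 observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)
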