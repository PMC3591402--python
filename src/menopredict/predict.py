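"""Individual-level menopausal-age prediction.

A woman's (age, AMH) measurement is located within the age-dependent AMH
reference percentiles (stage 1); her predicted menopausal-age interval is
then read off the matching percentiles of the menopausal-age distribution
for her BMI-category × smoking profile (stage 2).
"""

from __future__ import annotations

import dataclasses
import math

from .amh import RegressionModel, percentile_band
from .menopause import CovariateProfile, ThresholdModel, menopause_percentiles

__all__ = ["MenopausePrediction", "predict_menopause_interval", "prediction_report"]

#: probability used for the flagged lower-edge extrapolation of the
#: open-ended "< 5%" band
_EXTRAPOLATION_PROB = 0.01


@dataclasses.dataclass(frozen=True)
class MenopausePrediction:
    """Predicted menopausal-age interval for one woman.

    ``band`` is the half-open AMH percentile band (p_low, p_high] her
    measurement fell into; ``age_low``/``age_high`` are the matching
    menopausal-age percentiles for her covariate profile.  The outer
    bands give one-sided intervals: below the 5th percentile the lower
    edge is a flagged extrapolation (``extrapolated_low``), above the
    95th the upper side is unbounded (``age_high = inf``,
    ``unbounded_high``).
    """

    band: tuple[float, float]
    profile: CovariateProfile
    age_low: float
    age_high: float
    extrapolated_low: bool = False
    unbounded_high: bool = False

    def __post_init__(self) -> None:
        if not self.age_low < self.age_high:
            raise ValueError(
                f"age_low must be below age_high, got ({self.age_low}, {self.age_high})"
            )


def predict_menopause_interval(
    age: float,
    amh: float,
    profile: CovariateProfile,
    rm: RegressionModel,
    tm: ThresholdModel,
) -> MenopausePrediction:
    """Two-stage prediction of a menopausal-age interval.

    Warns (via the stage-1 band lookup) when ``age`` is outside the
    validity range of the AMH percentiles.
    """
    band = percentile_band(rm, age, amh)
    p_lo, p_hi = band
    extrapolated_low = False
    unbounded_high = False
    if p_lo == 0.0:  # below the 5th AMH percentile
        lo, hi = menopause_percentiles(tm, rm, profile, (_EXTRAPOLATION_PROB, p_hi))
        extrapolated_low = True
    elif p_hi == 1.0:  # above the 95th AMH percentile
        (lo,) = menopause_percentiles(tm, rm, profile, (p_lo,))
        hi = math.inf
        unbounded_high = True
    else:
        lo, hi = menopause_percentiles(tm, rm, profile, (p_lo, p_hi))
    return MenopausePrediction(
        band=band,
        profile=profile,
        age_low=float(lo),
        age_high=float(hi),
        extrapolated_low=extrapolated_low,
        unbounded_high=unbounded_high,
    )


def prediction_report(
    prediction: MenopausePrediction,
    rm: RegressionModel,
    tm: ThresholdModel,
) -> dict:
    """Serializable record of a prediction and the models behind it.

    Identical inputs produce identical reports; the parameter signatures
    tie the prediction to the exact fitted models used.
    """
    report = {
        "band": list(prediction.band),
        "profile": {
            "bmi_category": prediction.profile.bmi_category,
            "smoker": prediction.profile.smoker,
        },
        "age_low": prediction.age_low,
        "age_high": prediction.age_high,
        "extrapolated_low": prediction.extrapolated_low,
        "unbounded_high": prediction.unbounded_high,
        "threshold_ng_ml": tm.threshold(prediction.profile),
        "models": {
            "regression_signature": rm.param_signature(),
            "threshold_signature": tm.param_signature(),
        },
    }
    return report
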