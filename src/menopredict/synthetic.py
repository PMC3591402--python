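"""Synthetic paired cohorts and the default calibration.

The study's raw cohorts are not public, so analyses and recovery
experiments run on synthetic cohorts with the same statistical structure:

* an AMH cohort (default n = 375, ages 19–44) with log(AMH) quadratic in
  age, peaking at 25, and mean-zero left-skewed skew-t residuals;
* a menopausal-age cohort (default n = 2635) whose ages are drawn from
  the threshold-crossing model, per BMI-category × smoking cell.

The default generating parameters are anchored to the published summary
tables: per-cell AMH thresholds (reference cell 0.31 ng/mL), the
normal-weight non-smoker menopausal-age percentiles (10/50/90 at
44.2/49.5/53.6 years), the stage-2 : stage-1 variance ratio 0.72, cohort
covariate frequencies, and a median AMH of 3.0 ng/mL at age 30.

Calibration notes: with a quadratic mean peaking at 25, exact
interpolation of the three percentile anchors forces the shape parameters
to satisfy a quantile-spacing condition

    (q₀.₁ − q₀.₅)/(q₀.₅ − q₀.₉) = (g(44.2) − g(49.5))/(g(49.5) − g(53.6)),

with g(y) = y² − 50y — a mildly left-skewed law, solved here on the
b = a + 1 family.  The anchors then determine the model only up to a
scale family, which the median-AMH-at-30 anchor pins down.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import optimize

from . import skewt
from .amh import RegressionModel
from .menopause import (
    ThresholdModel,
    build_threshold_model,
    sample_menopause_ages,
)
from .skewt import SkewTParams

__all__ = [
    "GeneratorConfig",
    "TABLE_THRESHOLDS",
    "ANCHOR_PERCENTILES",
    "default_generating_params",
    "generate_amh_cohort",
    "generate_menopause_cohort",
]

#: published per-cell AMH thresholds (ng/mL), (bmi_category, smoker) -> θ
TABLE_THRESHOLDS: dict[tuple[str, bool], float] = {
    ("under", False): 0.45,
    ("under", True): 0.53,
    ("normal", False): 0.31,
    ("normal", True): 0.36,
    ("over", False): 0.25,
    ("over", True): 0.30,
    ("obese", False): 0.28,
    ("obese", True): 0.33,
}

#: calibration anchors: menopausal-age percentiles of the reference
#: (normal-weight non-smoker) cell
ANCHOR_PERCENTILES: dict[float, float] = {0.10: 44.2, 0.50: 49.5, 0.90: 53.6}

_REFERENCE_THRESHOLD = 0.31  # ng/mL, normal-weight non-smoker
_PEAK_AGE = 25.0
_MEDIAN_AMH_AT_30 = 3.0  # ng/mL, reference-percentile-figure anchor
_MEDIAN_AMH_RANGE = (2.5, 3.5)  # plausibility band for the solved model


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """All generative parameters for the paired synthetic cohorts."""

    regression: RegressionModel
    threshold_model: ThresholdModel
    thresholds: dict[tuple[str, bool], float]
    n_amh: int = 375
    n_meno: int = 2635
    age_range: tuple[float, float] = (19.0, 44.0)
    bmi_mean: float = 23.2
    bmi_sd: float = 4.2
    smoke_prob_amh: float = 0.335
    smoke_prob_meno: float = 0.276
    bmi_category_probs: dict[str, float] = dataclasses.field(
        default_factory=lambda: _default_category_probs()
    )
    kappa: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_amh < 1 or self.n_meno < 1:
            raise ValueError("cohort sizes must be at least 1")
        for name in ("smoke_prob_amh", "smoke_prob_meno"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        total = sum(self.bmi_category_probs.values())
        if abs(total - 1.0) > 1e-9 or min(self.bmi_category_probs.values()) < 0:
            raise ValueError("bmi_category_probs must be nonnegative and sum to 1")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def _default_category_probs() -> dict[str, float]:
    # under-weight matches the published count 15/2635; normal and
    # over-weight jointly cover 80% of the cohort (0.45/0.35 split),
    # obese takes the remainder
    under = 15.0 / 2635.0
    probs = {"under": under, "normal": 0.45, "over": 0.35}
    probs["obese"] = 1.0 - sum(probs.values())
    return probs


def _solve_calibration() -> tuple[float, float, float, float, float, float]:
    """Solve (c0, c1, c2, sigma2, a, b) from the printed anchors."""
    g = lambda y: y * y - 2.0 * _PEAK_AGE * y  # quadratic basis with peak built in
    (p1, y1), (p2, y2), (p3, y3) = sorted(ANCHOR_PERCENTILES.items())
    spacing_target = (g(y1) - g(y2)) / (g(y2) - g(y3))

    def q(p, a, b):
        return float(skewt.quantile(p, SkewTParams(0.0, 1.0, a, b)))

    def spacing(a):
        return (q(p1, a, a + 1) - q(p2, a, a + 1)) / (q(p2, a, a + 1) - q(p3, a, a + 1))

    try:
        a = optimize.brentq(lambda s: spacing(s) - spacing_target, 0.6, 500.0, xtol=1e-12)
    except ValueError as exc:  # pragma: no cover - anchors are constants
        raise RuntimeError("calibration constraint system has no solution") from exc
    b = a + 1.0
    m = skewt._base_mean(a, b)
    q1, q2 = q(p1, a, b), q(p2, a, b)
    L = math.log(_REFERENCE_THRESHOLD)

    def model_for(sigma2):
        # exact interpolation of the anchors given the solved shapes
        c2 = sigma2 * (q2 - q1) / (g(y1) - g(y2))
        c0 = L - c2 * g(y2) - sigma2 * (q2 - m)
        return c0, c2

    def median_amh_30(sigma2):
        c0, c2 = model_for(sigma2)
        sigma1 = sigma2 / math.sqrt(0.72)
        return math.exp(c0 + c2 * g(30.0) + sigma1 * (q2 - m))

    sigma2 = optimize.brentq(
        lambda s: median_amh_30(s) - _MEDIAN_AMH_AT_30, 1e-4, 5.0, xtol=1e-14
    )
    c0, c2 = model_for(sigma2)
    c1 = -2.0 * _PEAK_AGE * c2

    med = median_amh_30(sigma2)
    if not _MEDIAN_AMH_RANGE[0] <= med <= _MEDIAN_AMH_RANGE[1]:  # pragma: no cover
        raise RuntimeError(
            f"calibration implies median AMH {med:.2f} ng/mL at age 30, outside "
            f"the plausible range {_MEDIAN_AMH_RANGE}"
        )
    return c0, c1, c2, sigma2, a, b


def default_generating_params(seed: int = 0, kappa: float = 0.72) -> GeneratorConfig:
    """The calibrated default generating parameters.

    The regression coefficients, stage-2 scale and shared shape
    parameters are solved from the anchor constraints (peak at 25, three
    reference-cell menopausal-age percentiles, median AMH at 30); the
    stage-1 scale inflates the stage-2 scale by 1/√κ.
    """
    c0, c1, c2, sigma2, a, b = _solve_calibration()
    sigma1 = sigma2 / math.sqrt(kappa)
    residual1 = skewt.mean_zero(SkewTParams(0.0, sigma1, a, b))
    regression = RegressionModel(
        terms=("age", "age2"),
        coef={"const": c0, "age": c1, "age2": c2},
        residual=residual1,
        loglik=float("nan"),
        n=0,
        n_params=6,
        message="constructed by calibration, not fitted",
    )
    ref = TABLE_THRESHOLDS[("normal", False)]
    threshold_model = build_threshold_model(
        regression,
        alpha=math.log(ref),
        beta_bmi={
            c: math.log(TABLE_THRESHOLDS[(c, False)] / ref)
            for c in ("under", "over", "obese")
        },
        gamma_smoke=math.log(
            TABLE_THRESHOLDS[("normal", True)] / ref
        ),
        kappa=kappa,
    )
    return GeneratorConfig(
        regression=regression,
        threshold_model=threshold_model,
        thresholds=dict(TABLE_THRESHOLDS),
        kappa=kappa,
        seed=seed,
    )


def generate_amh_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Synthetic AMH cohort: uniform ages, truncated-normal BMI, Bernoulli
    smoking, and log(AMH) = μ(age) + mean-zero skew-t noise."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    n = cfg.n_amh
    ages = rng.uniform(cfg.age_range[0], cfg.age_range[1], size=n)
    bmi = rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=n)
    while np.any(bmi < 15.0):  # truncate implausibly low BMI
        redraw = bmi < 15.0
        bmi[redraw] = rng.normal(cfg.bmi_mean, cfg.bmi_sd, size=int(redraw.sum()))
    smoker = rng.binomial(1, cfg.smoke_prob_amh, size=n)
    eps = skewt.sample(n, cfg.regression.residual, rng)
    amh = np.exp(cfg.regression.mean_log_amh(ages) + eps)
    return pd.DataFrame(
        {
            "subject_id": [f"A{i:05d}" for i in range(n)],
            "age_years": ages,
            "amh_ng_ml": amh,
            "bmi": bmi,
            "smoker": smoker,
        }
    )


def generate_menopause_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Synthetic menopausal-age cohort drawn from the threshold model.

    Covariate profiles are sampled from the configured cell frequencies;
    ages come from the per-cell threshold-crossing distribution (inverse
    cdf, truncated to the physiological 35–65 year range).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    n = cfg.n_meno
    cats = list(cfg.bmi_category_probs)
    probs = np.array([cfg.bmi_category_probs[c] for c in cats])
    cat_draw = rng.choice(len(cats), size=n, p=probs / probs.sum())
    smoker = rng.binomial(1, cfg.smoke_prob_meno, size=n)
    ages = np.empty(n)
    resid2 = cfg.threshold_model.stage2_residual
    for ci, c in enumerate(cats):
        for s in (0, 1):
            mask = (cat_draw == ci) & (smoker == s)
            if mask.any():
                ages[mask] = sample_menopause_ages(
                    int(mask.sum()),
                    math.log(cfg.thresholds[(c, bool(s))]),
                    resid2,
                    cfg.regression,
                    rng,
                )
    return pd.DataFrame(
        {
            "subject_id": [f"M{i:05d}" for i in range(n)],
            "age_menopause_years": ages,
            "bmi_category": [cats[i] for i in cat_draw],
            "smoker": smoker,
        }
    )
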