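"""Stage 2: menopause as AMH crossing a covariate-dependent threshold.

The model assumes menopause occurs before age ``y`` exactly when the
(latent) AMH trajectory at ``y`` lies below a critical level θ, so

    P(menopause ≤ y) = P(log AMH(y) < log θ) = F₂(log θ − μ(y)),

with μ(y) the stage-1 regression mean and F₂ a mean-zero skew-t law
sharing the stage-1 shape parameters but with variance scaled by the
factor κ (< 1: part of the cross-sectional AMH variation is inter- and
intra-cycle noise that does not vary menopause timing).  log θ is additive
in BMI category and smoking status, with normal-weight non-smokers as the
reference level.

Menopausal-age cohorts are DataFrames with columns
``subject_id, age_menopause_years, bmi_category, smoker``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import skewt
from .amh import (
    DEFAULT_PROBS,
    ConvergenceError,
    RegressionModel,
    _base_cdf,
    _base_logpdf,
)
from .skewt import SkewTParams

__all__ = [
    "BMI_CATEGORIES",
    "MENOPAUSE_COLUMNS",
    "MENOPAUSE_AGE_BOUNDS",
    "CovariateProfile",
    "ThresholdModel",
    "CdfComparison",
    "UncertaintyTable",
    "all_profiles",
    "build_threshold_model",
    "menopause_cdf",
    "menopause_pdf",
    "fit_threshold_model",
    "menopause_percentiles",
    "observed_vs_model_cdf",
    "estimate_uncertainty",
    "sample_menopause_ages",
    "threshold_loglik",
    "fit_joint_model",
]

BMI_CATEGORIES = ("under", "normal", "over", "obese")
_OFFSET_CATEGORIES = ("under", "over", "obese")  # "normal" is the reference
MENOPAUSE_COLUMNS = ("subject_id", "age_menopause_years", "bmi_category", "smoker")

#: plausible physiological range for recorded menopausal ages
MENOPAUSE_AGE_BOUNDS = (35.0, 65.0)

#: root-finding bracket for menopausal-age percentiles (offset above the
#: stage-1 peak age, upper end of the search)
PERCENTILE_BRACKET = (0.5, 80.0)


@dataclasses.dataclass(frozen=True)
class CovariateProfile:
    """One BMI-category × smoking cell.

    BMI categories follow the usual cut-points: under-weight < 18.5,
    normal 18.5–<25, over-weight 25–<30, obese ≥ 30 kg/m².
    """

    bmi_category: str
    smoker: bool

    def __post_init__(self) -> None:
        if self.bmi_category not in BMI_CATEGORIES:
            raise ValueError(
                f"bmi_category must be one of {BMI_CATEGORIES}, got {self.bmi_category!r}"
            )
        object.__setattr__(self, "smoker", bool(self.smoker))

    @classmethod
    def from_bmi(cls, bmi: float, smoker: bool) -> "CovariateProfile":
        if bmi <= 10:
            raise ValueError(f"implausible BMI {bmi}")
        if bmi < 18.5:
            cat = "under"
        elif bmi < 25:
            cat = "normal"
        elif bmi < 30:
            cat = "over"
        else:
            cat = "obese"
        return cls(cat, smoker)

    def label(self) -> str:
        return f"{self.bmi_category}_{'smoker' if self.smoker else 'nonsmoker'}"


def all_profiles() -> list[CovariateProfile]:
    return [CovariateProfile(c, s) for c in BMI_CATEGORIES for s in (False, True)]


@dataclasses.dataclass(frozen=True)
class ThresholdModel:
    """Fitted (or constructed) covariate-dependent AMH threshold model.

    ``alpha`` is the log-threshold for the reference profile (normal
    weight, non-smoker); ``beta_bmi`` holds additive log offsets for the
    other BMI categories and ``gamma_smoke`` the smoker offset.  ``kappa``
    is the stage-2 : stage-1 variance ratio; ``stage2_residual`` the
    mean-zero skew-t law of log-AMH variation relevant to menopause
    timing (stage-1 shapes, scale × √κ).
    """

    alpha: float
    beta_bmi: dict[str, float]
    gamma_smoke: float
    kappa: float
    stage2_residual: SkewTParams
    loglik: float = float("nan")
    n: int = 0
    converged: bool = True
    unidentifiable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        extra = set(self.beta_bmi) - set(_OFFSET_CATEGORIES)
        if extra:
            raise ValueError(f"beta_bmi keys must be among {_OFFSET_CATEGORIES}, got {extra}")

    def log_threshold(self, profile: CovariateProfile) -> float:
        return (
            self.alpha
            + self.beta_bmi.get(profile.bmi_category, 0.0)
            + (self.gamma_smoke if profile.smoker else 0.0)
        )

    def threshold(self, profile: CovariateProfile) -> float:
        """Critical AMH level θ (ng/mL) below which menopause is predicted."""
        return math.exp(self.log_threshold(profile))

    def param_signature(self) -> str:
        import hashlib
        import json

        payload = json.dumps(
            {
                "alpha": repr(self.alpha),
                "beta_bmi": {k: repr(v) for k, v in sorted(self.beta_bmi.items())},
                "gamma_smoke": repr(self.gamma_smoke),
                "kappa": repr(self.kappa),
                "residual": [
                    repr(getattr(self.stage2_residual, f))
                    for f in ("location", "scale", "a", "b")
                ],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_threshold_model(
    rm: RegressionModel,
    alpha: float,
    beta_bmi: dict[str, float],
    gamma_smoke: float,
    kappa: float,
    **kwargs,
) -> ThresholdModel:
    """Assemble a ThresholdModel whose stage-2 law shares the stage-1 shapes."""
    scale2 = rm.residual.scale * math.sqrt(kappa)
    resid2 = skewt.mean_zero(SkewTParams(0.0, scale2, rm.residual.a, rm.residual.b))
    return ThresholdModel(
        alpha=alpha,
        beta_bmi=dict(beta_bmi),
        gamma_smoke=gamma_smoke,
        kappa=kappa,
        stage2_residual=resid2,
        **kwargs,
    )


def _check_age(y, rm: RegressionModel) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    peak = rm.peak_age
    if np.any(y <= peak):
        raise ValueError(
            f"menopausal age must exceed the stage-1 peak age {peak:.2f} "
            "(the quadratic mean is non-monotone before it)"
        )
    return y


def menopause_cdf(y, profile: CovariateProfile, tm: ThresholdModel, rm: RegressionModel):
    """P(menopause ≤ y) for the given covariate profile."""
    y = _check_age(y, rm)
    gap = tm.log_threshold(profile) - rm.mean_log_amh(y)
    return skewt.cdf(gap, tm.stage2_residual)


def menopause_pdf(y, profile: CovariateProfile, tm: ThresholdModel, rm: RegressionModel):
    """Density of menopausal age: f₂(log θ − μ(y)) · (−μ'(y))."""
    y = _check_age(y, rm)
    gap = tm.log_threshold(profile) - rm.mean_log_amh(y)
    return skewt.pdf(gap, tm.stage2_residual) * (-rm.mean_slope(y))


def _validate_menopause_frame(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("age_menopause_years", "bmi_category", "smoker") if c not in records.columns]
    if missing:
        raise ValueError(f"menopause cohort frame is missing columns {missing}")
    ages = records["age_menopause_years"].to_numpy(float)
    lo, hi = MENOPAUSE_AGE_BOUNDS
    bad = records.index[(ages <= lo) | (ages >= hi)]
    if len(bad):
        raise ValueError(
            f"menopausal ages must lie within {MENOPAUSE_AGE_BOUNDS} years; "
            f"rejected rows {bad.tolist()[:10]}"
        )
    bad_cat = set(records["bmi_category"]) - set(BMI_CATEGORIES)
    if bad_cat:
        raise ValueError(f"unknown bmi_category values {sorted(bad_cat)}")
    return records


def fit_threshold_model(
    records: pd.DataFrame,
    rm: RegressionModel,
    *,
    include_covariates: bool = True,
    interval_censored: bool = False,
    x0: np.ndarray | None = None,
    maxiter: int = 500,
) -> ThresholdModel:
    """Maximum-likelihood fit of the threshold model, stage 1 held fixed.

    Estimates (α, β_bmi, γ_smoke, κ) from menopausal ages; κ is estimated
    on the log scale to enforce positivity.  The likelihood conditions on
    menopause falling inside the accepted (35, 65)-year window, matching
    the validation applied to the records.  Covariate cells with no
    records have their offsets pinned at zero and flagged unidentifiable.
    With ``include_covariates=False`` only α and κ are estimated (the
    no-covariate model used for the marginal menopausal-age percentiles).
    ``interval_censored`` treats each recorded age as known only to
    ±0.5 year (recalled integer ages) and replaces the density
    contribution by the interval probability.
    """
    records = _validate_menopause_frame(records)
    n = len(records)
    if n < 100:
        raise ValueError(f"need at least 100 records, got {n}")
    y = records["age_menopause_years"].to_numpy(float)
    _check_age(y, rm)

    a, b = rm.residual.a, rm.residual.b
    m_base = skewt._base_mean(a, b)
    sigma1 = rm.residual.scale
    mu = rm.mean_log_amh(y)
    log_slope_sum = float(np.sum(np.log(-rm.mean_slope(y))))
    lo, hi = MENOPAUSE_AGE_BOUNDS
    mu_lo, mu_hi = float(rm.mean_log_amh(lo)), float(rm.mean_log_amh(hi))

    cat = records["bmi_category"].to_numpy()
    smoke = records["smoker"].to_numpy(float)

    unidentifiable = []
    offset_cats: list[str] = []
    if include_covariates:
        for c in _OFFSET_CATEGORIES:
            if np.any(cat == c):
                offset_cats.append(c)
            else:
                unidentifiable.append(c)
        smoke_free = bool(smoke.min() < smoke.max())
        if not smoke_free:
            unidentifiable.append("smoker")
    else:
        smoke_free = False

    n_offsets = len(offset_cats)

    # group records by covariate cell: the log-threshold and the
    # truncation normalization are constant within a cell
    mu_plus = rm.mean_log_amh(y + 0.5) if interval_censored else None
    mu_minus = rm.mean_log_amh(y - 0.5) if interval_censored else None
    groups = []
    ic_data = []
    for c in BMI_CATEGORIES if include_covariates else [None]:
        for s in (0.0, 1.0) if (include_covariates and smoke_free) else [None]:
            if c is None:
                mask = np.ones(n, dtype=bool)
            elif s is None:
                mask = cat == c
            else:
                mask = (cat == c) & (smoke == s)
            if not mask.any():
                continue
            oi = offset_cats.index(c) if c in offset_cats else -1
            s_val = 0.0 if s is None else s
            groups.append((mu[mask], int(mask.sum()), oi, s_val))
            if interval_censored:
                ic_data.append(
                    (mu_plus[mask], mu_minus[mask], int(mask.sum()), oi, s_val)
                )

    def unpack(theta):
        alpha = theta[0]
        betas = theta[1 : 1 + n_offsets]
        gamma = theta[1 + n_offsets] if smoke_free else 0.0
        log_kappa = theta[-1]
        return alpha, betas, gamma, log_kappa

    def _dlogf(z):
        # d/dz log f(z) for the standardized density
        t = z / np.sqrt(a + b + z * z)
        dt = (a + b) / (a + b + z * z) ** 1.5
        return ((a + 0.5) / (1.0 + t) - (b + 0.5) / (1.0 - t)) * dt

    def _pdf_base(z):
        return np.exp(_base_logpdf(z, a, b))

    def nll_grad(theta):
        alpha, betas, gamma, log_kappa = unpack(theta)
        sigma2 = sigma1 * math.exp(0.5 * log_kappa)
        ll = log_slope_sum - n * math.log(sigma2)
        grad = np.zeros_like(theta)
        grad[-1] += n / 2.0  # from +n log sigma2 in the nll
        for mu_g, n_g, oi, s in groups:
            log_theta = alpha + (betas[oi] if oi >= 0 else 0.0) + gamma * s
            # mean-zero stage-2 law: gap ~ sigma2 * (Z - E[Z])
            z = (log_theta - mu_g) / sigma2 + m_base
            ll += _base_logpdf(z, a, b).sum()
            dl = _dlogf(z)
            # z depends on (alpha, beta, gamma) through log_theta / sigma2
            # and on log_kappa through -(z - m)/2
            g_theta = -dl.sum() / sigma2
            g_kappa = (dl * (z - m_base)).sum() / 2.0
            # condition on menopause falling inside the accepted age window
            z_lo = (log_theta - mu_lo) / sigma2 + m_base
            z_hi = (log_theta - mu_hi) / sigma2 + m_base
            p_lo = _base_cdf(z_lo, a, b)
            p_hi = _base_cdf(z_hi, a, b)
            mass = p_hi - p_lo
            if mass <= 0:
                return 1e12, grad
            ll -= n_g * math.log(mass)
            f_lo, f_hi = _pdf_base(z_lo), _pdf_base(z_hi)
            g_theta += n_g * (f_hi - f_lo) / (mass * sigma2)
            g_kappa -= n_g * (f_hi * (z_hi - m_base) - f_lo * (z_lo - m_base)) / (2.0 * mass)
            grad[0] += g_theta
            if oi >= 0:
                grad[1 + oi] += g_theta
            if smoke_free:
                grad[1 + n_offsets] += g_theta * s
            grad[-1] += g_kappa
        if not math.isfinite(ll):
            return 1e12, grad
        return -ll, grad

    def nll_interval(theta):
        # interval-censored variant: P(menopause in y ± 0.5) per record
        alpha, betas, gamma, log_kappa = unpack(theta)
        sigma2 = sigma1 * math.exp(0.5 * log_kappa)
        ll = 0.0
        for mp_g, mm_g, n_g, oi, s in ic_data:
            log_theta = alpha + (betas[oi] if oi >= 0 else 0.0) + gamma * s
            z_plus = (log_theta - mp_g) / sigma2 + m_base
            z_minus = (log_theta - mm_g) / sigma2 + m_base
            p = _base_cdf(z_plus, a, b) - _base_cdf(z_minus, a, b)
            if np.any(p <= 0):
                return 1e12
            ll += np.log(p).sum()
            z_lo = (log_theta - mu_lo) / sigma2 + m_base
            z_hi = (log_theta - mu_hi) / sigma2 + m_base
            mass = _base_cdf(z_hi, a, b) - _base_cdf(z_lo, a, b)
            if mass <= 0:
                return 1e12
            ll -= n_g * math.log(mass)
        if not math.isfinite(ll):
            return 1e12
        return -ll

    def nll(theta):
        if interval_censored:
            return nll_interval(theta)
        return nll_grad(theta)[0]

    n_params = 1 + n_offsets + (1 if smoke_free else 0) + 1
    if x0 is not None:
        starts = [np.asarray(x0, dtype=float)]
        if len(starts[0]) != n_params:
            raise ValueError(f"x0 must have length {n_params}")
    else:
        med = float(np.median(y))
        starts = []
        for kappa0 in (0.8, 0.5, 1.3):
            sigma2 = sigma1 * math.sqrt(kappa0)
            q50 = float(skewt.quantile(0.5, SkewTParams(0.0, 1.0, a, b)))
            alpha0 = float(rm.mean_log_amh(med)) + sigma2 * (q50 - m_base)
            x = np.zeros(n_params)
            x[0] = alpha0
            x[-1] = math.log(kappa0)
            starts.append(x)

    best = None
    messages = []
    for s in starts:
        if interval_censored:
            res = optimize.minimize(
                nll_interval, s, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
            )
        else:
            res = optimize.minimize(
                nll_grad, s, method="L-BFGS-B", jac=True,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
            )
        if not res.success:
            nm = optimize.minimize(
                nll, res.x, method="Nelder-Mead",
                options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8},
            )
            if nm.success:
                res = nm
        messages.append(res.message)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError(f"threshold model failed to converge: {messages}")

    alpha, betas, gamma, log_kappa = unpack(best.x)
    kappa = math.exp(log_kappa)
    beta_bmi = {c: float(v) for c, v in zip(offset_cats, betas)}
    return build_threshold_model(
        rm,
        alpha=float(alpha),
        beta_bmi=beta_bmi,
        gamma_smoke=float(gamma),
        kappa=float(kappa),
        loglik=-float(best.fun),
        n=n,
        converged=True,
        unidentifiable=tuple(unidentifiable),
    )


def threshold_loglik(records: pd.DataFrame, rm: RegressionModel, tm: ThresholdModel) -> float:
    """Stage-2 conditional log-likelihood of ``records`` under (tm, rm).

    Uses the same construction as ``fit_threshold_model`` (density of the
    threshold-crossing law, conditioned on the accepted age window), so
    fitted models can be compared against constructed ones.
    """
    records = _validate_menopause_frame(records)
    y = records["age_menopause_years"].to_numpy(float)
    _check_age(y, rm)
    a, b = rm.residual.a, rm.residual.b
    m_base = skewt._base_mean(a, b)
    sigma2 = tm.stage2_residual.scale
    mu = rm.mean_log_amh(y)
    lo, hi = MENOPAUSE_AGE_BOUNDS
    mu_lo, mu_hi = float(rm.mean_log_amh(lo)), float(rm.mean_log_amh(hi))
    ll = float(np.sum(np.log(-rm.mean_slope(y)))) - len(y) * math.log(sigma2)
    for cat in BMI_CATEGORIES:
        for s in (False, True):
            mask = (records["bmi_category"].to_numpy() == cat) & (
                records["smoker"].astype(bool).to_numpy() == s
            )
            if not mask.any():
                continue
            log_theta = tm.log_threshold(CovariateProfile(cat, s))
            z = (log_theta - mu[mask]) / sigma2 + m_base
            p_lo = _base_cdf((log_theta - mu_lo) / sigma2 + m_base, a, b)
            p_hi = _base_cdf((log_theta - mu_hi) / sigma2 + m_base, a, b)
            ll += _base_logpdf(z, a, b).sum() - int(mask.sum()) * math.log(p_hi - p_lo)
    return ll


def fit_joint_model(
    amh_records: pd.DataFrame,
    meno_records: pd.DataFrame,
    *,
    maxiter: int = 2000,
) -> tuple[RegressionModel, ThresholdModel]:
    """Joint maximum-likelihood fit of both stages.

    Maximizes the sum of the stage-1 (AMH regression) and stage-2
    (threshold) log-likelihoods over all parameters simultaneously, so
    the menopausal ages inform the regression extrapolation and vice
    versa.  Two-stage estimation is the package default; this variant
    exists because the two components are inter-dependent — threshold
    differences are better determined than the components separately.
    Restricted to the quadratic age-only mean model.
    """
    from .amh import _shape, _shape_inv, fit_amh_regression

    rm0 = fit_amh_regression(amh_records)
    tm0 = fit_threshold_model(meno_records, rm0)

    y1 = np.log(amh_records["amh_ng_ml"].to_numpy(float))
    age1 = amh_records["age_years"].to_numpy(float)
    n1 = len(y1)
    meno_records = _validate_menopause_frame(meno_records)
    y2 = meno_records["age_menopause_years"].to_numpy(float)
    n2 = len(y2)
    cat = meno_records["bmi_category"].to_numpy()
    smoke = meno_records["smoker"].to_numpy(float)
    offset_cats = [c for c in _OFFSET_CATEGORIES if (cat == c).any()]
    cells = []
    for c in BMI_CATEGORIES:
        for s in (0.0, 1.0):
            mask = (cat == c) & (smoke == s)
            if mask.any():
                oi = offset_cats.index(c) if c in offset_cats else -1
                cells.append((y2[mask], oi, s, int(mask.sum())))
    lo, hi = MENOPAUSE_AGE_BOUNDS

    # parameter vector: c0, c1, c2, log sigma1, u_a, u_b,
    #                   alpha, offsets..., gamma, log kappa
    def split(theta):
        c = theta[:3]
        sigma1 = math.exp(theta[3])
        a, b = _shape(theta[4]), _shape(theta[5])
        alpha = theta[6]
        betas = theta[7 : 7 + len(offset_cats)]
        gamma = theta[7 + len(offset_cats)]
        kappa = math.exp(theta[-1])
        return c, sigma1, a, b, alpha, betas, gamma, kappa

    def nll(theta):
        c, sigma1, a, b, alpha, betas, gamma, kappa = split(theta)
        mu1 = c[0] + c[1] * age1 + c[2] * age1 * age1
        peak = -c[1] / (2.0 * c[2]) if c[2] < 0 else math.inf
        if not (c[2] < 0 and peak < lo - 1.0):
            return 1e12  # mean must decline throughout the menopause window
        m_base = skewt._base_mean(a, b)
        z1 = (y1 - mu1) / sigma1 + m_base
        ll = _base_logpdf(z1, a, b).sum() - n1 * math.log(sigma1)
        sigma2 = sigma1 * math.sqrt(kappa)
        mu_lo = c[0] + c[1] * lo + c[2] * lo * lo
        mu_hi = c[0] + c[1] * hi + c[2] * hi * hi
        for y_g, oi, s, n_g in cells:
            log_theta = alpha + (betas[oi] if oi >= 0 else 0.0) + gamma * s
            mu_g = c[0] + c[1] * y_g + c[2] * y_g * y_g
            z2 = (log_theta - mu_g) / sigma2 + m_base
            ll += _base_logpdf(z2, a, b).sum() - n_g * math.log(sigma2)
            ll += np.log(-(c[1] + 2.0 * c[2] * y_g)).sum()
            mass = _base_cdf((log_theta - mu_hi) / sigma2 + m_base, a, b) - _base_cdf(
                (log_theta - mu_lo) / sigma2 + m_base, a, b
            )
            if mass <= 0:
                return 1e12
            ll -= n_g * math.log(mass)
        if not math.isfinite(ll):
            return 1e12
        return -ll

    x0 = np.concatenate(
        [
            [rm0.c0, rm0.c1, rm0.c2, math.log(rm0.residual.scale)],
            [_shape_inv(rm0.residual.a), _shape_inv(rm0.residual.b)],
            [tm0.alpha],
            [tm0.beta_bmi.get(c, 0.0) for c in offset_cats],
            [tm0.gamma_smoke, math.log(tm0.kappa)],
        ]
    )
    res = optimize.minimize(
        nll, x0, method="Nelder-Mead",
        options={"maxiter": 20000, "fatol": 1e-10, "xatol": 1e-9},
    )
    res2 = optimize.minimize(
        nll, res.x, method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
    )
    best = res2 if (res2.success and res2.fun <= res.fun) else res
    if not (best.success or best.fun <= nll(x0)):
        raise ConvergenceError(f"joint fit failed to converge: {best.message}")

    c, sigma1, a, b, alpha, betas, gamma, kappa = split(best.x)
    residual1 = skewt.mean_zero(SkewTParams(0.0, sigma1, a, b))
    rm = RegressionModel(
        terms=("age", "age2"),
        coef={"const": float(c[0]), "age": float(c[1]), "age2": float(c[2])},
        residual=residual1,
        loglik=-float(best.fun),
        n=n1 + n2,
        n_params=len(best.x),
        message="joint two-stage maximum likelihood",
        age_range=(float(age1.min()), float(age1.max())),
    )
    tm = build_threshold_model(
        rm,
        alpha=float(alpha),
        beta_bmi={c_: float(v) for c_, v in zip(offset_cats, betas)},
        gamma_smoke=float(gamma),
        kappa=float(kappa),
        loglik=-float(best.fun),
        n=n2,
        converged=True,
        unidentifiable=tm0.unidentifiable,
    )
    return rm, tm


def _fit_x0(tm: ThresholdModel, offset_cats: Sequence[str], smoke_free: bool) -> np.ndarray:
    """Warm-start vector matching ``fit_threshold_model``'s packing."""
    return np.array(
        [tm.alpha]
        + [tm.beta_bmi.get(c, 0.0) for c in offset_cats]
        + ([tm.gamma_smoke] if smoke_free else [])
        + [math.log(tm.kappa)]
    )


def menopause_percentiles(
    tm: ThresholdModel,
    rm: RegressionModel,
    profile: CovariateProfile,
    probs: Sequence[float] = DEFAULT_PROBS,
) -> np.ndarray:
    """Ages (years) at which the menopausal-age cdf reaches each prob.

    Monotone root-finding on a bracket just above the stage-1 peak age;
    non-bracketing raises, naming the profile.
    """
    peak = rm.peak_age
    lo = peak + PERCENTILE_BRACKET[0]
    hi = PERCENTILE_BRACKET[1]
    out = np.empty(len(list(probs)))
    for i, p in enumerate(probs):
        if not 0 < p < 1:
            raise ValueError(f"probs must lie in (0,1), got {p}")
        f = lambda age: float(menopause_cdf(age, profile, tm, rm)) - p
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            raise ValueError(
                f"percentile {p} for profile {profile.label()} is not bracketed "
                f"by ages ({lo:.1f}, {hi:.1f}) (cdf endpoints {flo + p:.4f}, {fhi + p:.4f})"
            )
        out[i] = optimize.brentq(f, lo, hi, xtol=1e-10)
    return out


@dataclasses.dataclass(frozen=True)
class CdfComparison:
    """Observed vs model cumulative distribution for one covariate stratum."""

    ages: np.ndarray
    empirical: np.ndarray
    model: np.ndarray
    max_gap: float
    n: int


def observed_vs_model_cdf(
    records: pd.DataFrame,
    tm: ThresholdModel,
    rm: RegressionModel,
    profile: CovariateProfile,
) -> CdfComparison:
    """Empirical vs model cdf of menopausal age within one stratum.

    The concordance summary is the Kolmogorov–Smirnov max gap.  Strata
    with fewer than 20 records are refused (no meaningful comparison).
    """
    records = _validate_menopause_frame(records)
    mask = (records["bmi_category"] == profile.bmi_category) & (
        records["smoker"].astype(bool) == profile.smoker
    )
    ages = np.sort(records.loc[mask, "age_menopause_years"].to_numpy(float))
    n = len(ages)
    if n < 20:
        raise ValueError(
            f"stratum {profile.label()} has only {n} records (< 20); "
            "no meaningful comparison can be made"
        )
    model = np.asarray(menopause_cdf(ages, profile, tm, rm))
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    max_gap = float(np.max(np.maximum(np.abs(ecdf_hi - model), np.abs(model - ecdf_lo))))
    return CdfComparison(ages=ages, empirical=ecdf_hi, model=model, max_gap=max_gap, n=n)


def sample_menopause_ages(
    n: int,
    log_theta: float,
    tm_residual: SkewTParams,
    rm: RegressionModel,
    rng: np.random.Generator,
    age_bounds: tuple[float, float] = MENOPAUSE_AGE_BOUNDS,
) -> np.ndarray:
    """Inverse-cdf draws of menopausal age, truncated to ``age_bounds``.

    Requires a quadratic age-only stage-1 mean (closed-form inversion of
    μ); the truncation removes the sub-0.5% of threshold-model mass lying
    outside the physiological range so generated records always validate.
    """
    if not set(rm.terms) <= {"age", "age2"} or rm.c2 >= 0:
        raise ValueError("sampling requires a concave quadratic age-only mean model")
    peak = rm.peak_age
    mu_peak = float(rm.mean_log_amh(peak))
    lo, hi = age_bounds
    u_lo = float(skewt.cdf(log_theta - rm.mean_log_amh(lo), tm_residual))
    u_hi = float(skewt.cdf(log_theta - rm.mean_log_amh(hi), tm_residual))
    u = rng.uniform(u_lo, u_hi, size=int(n))
    gap = np.asarray(skewt.quantile(u, tm_residual))
    mu_target = log_theta - gap
    return peak + np.sqrt((mu_target - mu_peak) / rm.c2)


@dataclasses.dataclass(frozen=True)
class UncertaintyTable:
    """Parametric-bootstrap uncertainty summaries for the threshold model."""

    thresholds: pd.DataFrame  # index profile label; point, ci_low, ci_high, se
    kappa: pd.Series  # point, ci_low, ci_high, se
    percentile_se: pd.DataFrame  # index profile label, columns percentile probs
    n_boot: int
    n_failed: int
    seed: int


def estimate_uncertainty(
    tm: ThresholdModel,
    rm: RegressionModel,
    records: pd.DataFrame,
    n_boot: int = 200,
    seed: int = 0,
    probs: Sequence[float] = DEFAULT_PROBS,
) -> UncertaintyTable:
    """Parametric bootstrap for thresholds, κ and menopausal-age percentiles.

    Menopausal ages are regenerated from the fitted model at each record's
    observed covariate profile, stage 2 is refitted (warm-started at the
    point estimates), and percentile-method 95% intervals and standard
    errors are reported.  Fully determined by ``seed``.  Passing an empty
    ``probs`` skips the menopausal-age percentile SEs (threshold and κ
    summaries only), which is much faster.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be at least 100, got {n_boot}")
    records = _validate_menopause_frame(records)
    rng = np.random.default_rng(seed)
    profiles = all_profiles()
    labels = [p.label() for p in profiles]

    cat = records["bmi_category"].to_numpy()
    smoke = records["smoker"].astype(bool).to_numpy()

    thr_draws = np.full((n_boot, len(profiles)), np.nan)
    kap_draws = np.full(n_boot, np.nan)
    pct_draws = np.full((n_boot, len(profiles), len(list(probs))), np.nan)
    offset_cats = [c for c in _OFFSET_CATEGORIES if (cat == c).any()]
    x0 = _fit_x0(tm, offset_cats, bool(smoke.min() < smoke.max()))
    n_failed = 0
    boot = records.copy()
    for r in range(n_boot):
        ages = np.empty(len(records))
        for p in profiles:
            mask = (cat == p.bmi_category) & (smoke == p.smoker)
            if mask.any():
                ages[mask] = sample_menopause_ages(
                    int(mask.sum()), tm.log_threshold(p), tm.stage2_residual, rm, rng
                )
        boot["age_menopause_years"] = ages
        try:
            fit = fit_threshold_model(boot, rm, x0=x0)
        except (ConvergenceError, ValueError):
            n_failed += 1
            continue
        kap_draws[r] = fit.kappa
        for j, p in enumerate(profiles):
            thr_draws[r, j] = fit.threshold(p)
            if len(list(probs)):
                try:
                    pct_draws[r, j] = menopause_percentiles(fit, rm, p, probs)
                except ValueError:
                    pass  # extreme draw in a sparse cell: percentile unreachable
    if n_failed > 0.1 * n_boot:
        raise RuntimeError(
            f"{n_failed}/{n_boot} bootstrap refits failed; uncertainty estimates unreliable"
        )

    ok = ~np.isnan(kap_draws)

    def summarize(point: float, draws: np.ndarray) -> dict[str, float]:
        return {
            "point": point,
            "ci_low": float(np.nanpercentile(draws, 2.5)),
            "ci_high": float(np.nanpercentile(draws, 97.5)),
            "se": float(np.nanstd(draws, ddof=1)),
        }

    thresholds = pd.DataFrame(
        [summarize(tm.threshold(p), thr_draws[ok, j]) for j, p in enumerate(profiles)],
        index=pd.Index(labels, name="profile"),
    )
    kappa = pd.Series(summarize(tm.kappa, kap_draws[ok]))
    pct_se = pd.DataFrame(
        np.nanstd(pct_draws[ok], axis=0, ddof=1),
        index=pd.Index(labels, name="profile"),
        columns=[f"p{int(round(p * 100)):02d}" for p in probs],
    )
    return UncertaintyTable(
        thresholds=thresholds,
        kappa=kappa,
        percentile_se=pct_se,
        n_boot=n_boot,
        n_failed=n_failed,
        seed=seed,
    )
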