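"""Stage 1: skew-t regression of log(AMH) on age.

The mean of log(AMH) is modelled as a polynomial in age (quadratic by
default, with optional extra terms for model comparison: age³, age⁴, BMI,
smoking and age-interactions), with residuals following a mean-zero
Jones–Faddy skew-t law.  Everything is fitted jointly by maximum
likelihood.  The fitted model yields age-dependent AMH reference
percentile curves and locates an individual (age, AMH) measurement within
a percentile band — the first stage of menopause prediction.

Cohort data are plain pandas DataFrames with columns
``subject_id, age_years, amh_ng_ml, bmi, smoker`` (smoker ∈ {0, 1}).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from . import skewt
from .skewt import SkewTParams

__all__ = [
    "AMH_COLUMNS",
    "DEFAULT_PROBS",
    "BAND_EDGES",
    "VALIDITY_AGE_RANGE",
    "RegressionModel",
    "PercentileTable",
    "GofResult",
    "ConvergenceError",
    "ValidityRangeWarning",
    "fit_amh_regression",
    "lr_test",
    "amh_percentile_curves",
    "percentile_band",
    "residual_gof",
    "smooth_log_amh",
]

AMH_COLUMNS = ("subject_id", "age_years", "amh_ng_ml", "bmi", "smoker")

#: reference percentile grid for AMH centile curves
DEFAULT_PROBS = (0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95)

#: band edges used when locating an individual measurement
BAND_EDGES = (0.0, 0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95, 1.0)

#: age range over which the fitted mean is considered well estimated;
#: outputs outside it are flagged with a warning, not suppressed
VALIDITY_AGE_RANGE = (25.0, 45.0)

# model terms: name -> builder of the design column
_TERM_BUILDERS = {
    "age": lambda d: d["age_years"].to_numpy(float),
    "age2": lambda d: d["age_years"].to_numpy(float) ** 2,
    "age3": lambda d: d["age_years"].to_numpy(float) ** 3,
    "age4": lambda d: d["age_years"].to_numpy(float) ** 4,
    "bmi": lambda d: d["bmi"].to_numpy(float),
    "smoker": lambda d: d["smoker"].to_numpy(float),
    "age_bmi": lambda d: d["age_years"].to_numpy(float) * d["bmi"].to_numpy(float),
    "age_smoker": lambda d: d["age_years"].to_numpy(float) * d["smoker"].to_numpy(float),
}

_AGE_POLY_TERMS = ("age", "age2", "age3", "age4")


class ConvergenceError(RuntimeError):
    """Raised when no optimizer start reaches a converged maximum."""


class ValidityRangeWarning(UserWarning):
    """Signals use of the fitted model outside its validity age range."""


@dataclasses.dataclass(frozen=True)
class RegressionModel:
    """Fitted (or constructed) log-AMH regression model.

    ``coef`` maps term names (plus ``"const"``) to coefficients in raw
    units (log ng/mL per yearᵏ for age terms).  ``residual`` is the
    mean-zero skew-t law of the residual deviates, so the regression
    surface is the conditional expectation of log(AMH).
    """

    terms: tuple[str, ...]
    coef: dict[str, float]
    residual: SkewTParams
    loglik: float
    n: int
    n_params: int
    converged: bool = True
    message: str = ""
    age_range: tuple[float, float] = (19.0, 44.0)

    def __post_init__(self) -> None:
        mom = skewt.moments(self.residual)
        if abs(mom.mean) > 1e-8:
            raise ValueError(
                f"residual law must have mean zero (got mean {mom.mean:.3g})"
            )

    # -- quadratic-in-age view -------------------------------------------------
    @property
    def c0(self) -> float:
        return self.coef["const"]

    @property
    def c1(self) -> float:
        return self.coef.get("age", 0.0)

    @property
    def c2(self) -> float:
        return self.coef.get("age2", 0.0)

    @property
    def peak_age(self) -> float:
        """Age at which the quadratic mean attains its maximum."""
        if self.c2 >= 0:
            raise ValueError("mean is not concave in age; no interior peak")
        return -self.c1 / (2.0 * self.c2)

    def _require_age_only(self) -> None:
        extra = [t for t in self.terms if t not in _AGE_POLY_TERMS]
        if extra:
            raise ValueError(
                f"operation requires an age-only mean model; extra terms {extra}"
            )

    def mean_log_amh(self, age) -> np.ndarray:
        """μ(age): expected log(AMH) for an age-only mean model."""
        self._require_age_only()
        age = np.asarray(age, dtype=float)
        out = np.full_like(age, self.coef["const"], dtype=float)
        for k, term in enumerate(_AGE_POLY_TERMS, start=1):
            if term in self.coef:
                out = out + self.coef[term] * age**k
        return out

    def mean_slope(self, age) -> np.ndarray:
        """μ'(age) for an age-only mean model."""
        self._require_age_only()
        age = np.asarray(age, dtype=float)
        out = np.zeros_like(age, dtype=float)
        for k, term in enumerate(_AGE_POLY_TERMS, start=1):
            if term in self.coef:
                out = out + k * self.coef[term] * age ** (k - 1)
        return out

    def param_signature(self) -> str:
        import hashlib
        import json

        payload = json.dumps(
            {
                "terms": list(self.terms),
                "coef": {k: repr(v) for k, v in sorted(self.coef.items())},
                "residual": [repr(getattr(self.residual, f)) for f in ("location", "scale", "a", "b")],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass(frozen=True)
class PercentileTable:
    """Age-dependent AMH reference percentiles (values in ng/mL)."""

    ages: np.ndarray
    probs: np.ndarray
    values: np.ndarray  # shape (len(ages), len(probs))

    def __post_init__(self) -> None:
        if np.any(self.values <= 0):
            raise ValueError("percentile values must be positive")
        if np.any(np.diff(self.values, axis=1) <= 0):
            raise ValueError("percentile values must increase in probability")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.ages, name="age_years"),
            columns=[f"p{int(round(p * 100)):02d}" for p in self.probs],
        )


@dataclasses.dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    pit: np.ndarray


# ---------------------------------------------------------------------------
# likelihood machinery


def _base_logpdf(z: np.ndarray, a: float, b: float) -> np.ndarray:
    t = z / np.sqrt(a + b + z * z)
    lognorm = (
        (a + b - 1.0) * math.log(2.0)
        + special.betaln(a, b)
        + 0.5 * math.log(a + b)
    )
    return (a + 0.5) * np.log1p(t) + (b + 0.5) * np.log1p(-t) - lognorm


def _base_cdf(z, a: float, b: float):
    u = 0.5 * (1.0 + z / np.sqrt(a + b + z * z))
    return special.betainc(a, b, u)


def _base_logcdf(z: np.ndarray, a: float, b: float) -> np.ndarray:
    u = 0.5 * (1.0 + z / np.sqrt(a + b + z * z))
    with np.errstate(divide="ignore"):
        return np.log(special.betainc(a, b, u))


def _base_mean(a: float, b: float) -> float:
    return skewt._base_mean(a, b)


def _shape(u: float) -> float:
    # unconstrained -> shape > 0.5001; keeps the mean finite during fitting
    return 0.5001 + math.exp(u)


def _shape_inv(a: float) -> float:
    return math.log(max(a - 0.5001, 1e-8))


def _validate_amh_frame(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("age_years", "amh_ng_ml") if c not in records.columns]
    if missing:
        raise ValueError(f"AMH cohort frame is missing columns {missing}")
    bad = records.index[records["amh_ng_ml"].to_numpy(float) <= 0]
    if len(bad):
        ids = (
            records.loc[bad, "subject_id"].tolist()
            if "subject_id" in records.columns
            else bad.tolist()
        )
        raise ValueError(f"AMH must be positive (log is taken); offending records: {ids[:10]}")
    if np.any(records["age_years"].to_numpy(float) <= 0):
        raise ValueError("ages must be positive")
    return records


def fit_amh_regression(
    records: pd.DataFrame,
    terms: Sequence[str] = ("age", "age2"),
    *,
    n_starts: int = 5,
    maxiter: int = 500,
    censor_below: float | None = None,
) -> RegressionModel:
    """Maximum-likelihood skew-t regression of log(AMH).

    Fits the mean coefficients jointly with the residual scale and the two
    shape parameters, with the residual law constrained to mean zero.  A
    fixed ladder of shape starting values (symmetric, left-skewed,
    right-skewed, heavy, light) guards against the multimodality of skew-t
    likelihoods in the shape parameters; the fit is deterministic for
    identical input.

    ``censor_below`` optionally treats AMH values at or below a detection
    limit as left-censored (cdf likelihood contribution); it is off by
    default.
    """
    records = _validate_amh_frame(records)
    if len(records) < 30:
        raise ValueError(f"need at least 30 records, got {len(records)}")
    terms = tuple(terms)
    unknown = [t for t in terms if t not in _TERM_BUILDERS]
    if unknown:
        raise ValueError(f"unknown model terms {unknown}; allowed: {sorted(_TERM_BUILDERS)}")

    y = np.log(records["amh_ng_ml"].to_numpy(float))
    X = np.column_stack(
        [np.ones(len(records))] + [_TERM_BUILDERS[t](records) for t in terms]
    )
    censored = (
        records["amh_ng_ml"].to_numpy(float) <= censor_below
        if censor_below is not None
        else np.zeros(len(records), dtype=bool)
    )

    # standardize the design internally for conditioning; coefficients are
    # mapped back to raw units afterwards
    col_mean = X.mean(axis=0)
    col_sd = X.std(axis=0)
    col_mean[0], col_sd[0] = 0.0, 1.0
    col_sd[col_sd == 0] = 1.0
    Xs = (X - col_mean) / col_sd

    k = Xs.shape[1]

    def nll(theta: np.ndarray) -> float:
        beta = theta[:k]
        sigma = math.exp(theta[k])
        a = _shape(theta[k + 1])
        b = _shape(theta[k + 2])
        r = y - Xs @ beta
        z = r / sigma + _base_mean(a, b)  # residual law = sigma * (Z - E[Z])
        ll = _base_logpdf(z[~censored], a, b).sum() - (~censored).sum() * math.log(sigma)
        if censored.any():
            ll += _base_logcdf(z[censored], a, b).sum()
        if not math.isfinite(ll):
            return 1e12
        return -ll

    beta0, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    sd0 = float(np.std(y - Xs @ beta0))
    shape_ladder = [(2.0, 2.0), (2.0, 6.0), (6.0, 2.0), (1.2, 1.2), (8.0, 8.0)]
    starts = [
        np.concatenate([beta0, [math.log(max(sd0, 1e-3)), _shape_inv(a0), _shape_inv(b0)]])
        for a0, b0 in shape_ladder[: max(1, int(n_starts))]
    ]

    # box bounds keep the line search away from overflow regions
    bounds = [(-50.0, 50.0)] * k + [(-10.0, 10.0), (-6.0, 9.0), (-6.0, 9.0)]
    best = None
    diagnostics = []
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if not res.success:
            # Line-search failures with finite-difference gradients are
            # polished by derivative-free restarts.  Near-Gaussian data
            # leave the shape likelihood on a plateau where the success
            # flags are unreliable; a fresh-simplex restart that confirms
            # the objective value establishes stationarity.
            nm = res
            for _ in range(4):
                prev = nm.fun
                nm = optimize.minimize(
                    nll,
                    nm.x,
                    method="Nelder-Mead",
                    bounds=bounds,
                    options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8},
                )
                if nm.success:
                    break
                if prev - nm.fun < 1e-7 * (1.0 + abs(nm.fun)):
                    nm.success = True
                    nm.message = "stationary on shape plateau (restart-confirmed)"
                    break
            res2 = optimize.minimize(
                nll,
                nm.x,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-7},
            )
            ok = [r for r in (nm, res2) if r.success]
            res = min(ok, key=lambda r: r.fun) if ok else res2
        diagnostics.append(res.message)
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceError(
            f"skew-t regression failed to converge from any start: {diagnostics}"
        )
    # final derivative-free polish pins the optimum tightly enough that
    # refitting shifted data reproduces coefficients to ~1e-6
    polish = optimize.minimize(
        nll,
        best.x,
        method="Nelder-Mead",
        bounds=bounds,
        options={"maxiter": 4000, "fatol": 1e-12, "xatol": 1e-10},
    )
    if polish.fun <= best.fun:
        best = polish

    beta_s = best.x[:k]
    sigma = math.exp(best.x[k])
    a = _shape(best.x[k + 1])
    b = _shape(best.x[k + 2])

    # unstandardize
    beta = beta_s / col_sd
    beta[0] = beta_s[0] - float(np.sum(beta_s[1:] * col_mean[1:] / col_sd[1:]))

    coef = {"const": float(beta[0])}
    coef.update({t: float(beta[i + 1]) for i, t in enumerate(terms)})
    residual = skewt.mean_zero(SkewTParams(0.0, sigma, a, b))
    ages = records["age_years"].to_numpy(float)
    return RegressionModel(
        terms=terms,
        coef=coef,
        residual=residual,
        loglik=-float(best.fun),
        n=len(records),
        n_params=k + 3,
        converged=True,
        message=str(best.message),
        age_range=(float(ages.min()), float(ages.max())),
    )


def lr_test(full: RegressionModel, reduced: RegressionModel):
    """Likelihood-ratio test of nested mean models.

    Returns ``(statistic, df, p_value)`` with the statistic referred to a
    chi-square distribution on the difference in parameter count.
    """
    if not set(reduced.terms).issubset(full.terms):
        raise ValueError(
            f"models are not nested: {reduced.terms} is not a subset of {full.terms}"
        )
    if full.n != reduced.n:
        raise ValueError("models were fitted on different numbers of records")
    statistic = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.n_params - reduced.n_params
    p_value = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return statistic, df, p_value


def _warn_if_outside_validity(age) -> None:
    age = np.atleast_1d(np.asarray(age, dtype=float))
    lo, hi = VALIDITY_AGE_RANGE
    if np.any((age < lo) | (age > hi)):
        warnings.warn(
            f"age(s) outside the validity range {VALIDITY_AGE_RANGE}; the fitted "
            "mean is poorly estimated there",
            ValidityRangeWarning,
            stacklevel=3,
        )


def amh_percentile_curves(
    model: RegressionModel,
    ages: Iterable[float] | None = None,
    probs: Sequence[float] = DEFAULT_PROBS,
) -> PercentileTable:
    """Age-dependent AMH reference percentile curves.

    The value at (age, p) is ``exp(μ(age) + q_p)`` with ``q_p`` the
    p-quantile of the mean-zero residual law.
    """
    if ages is None:
        ages = np.arange(VALIDITY_AGE_RANGE[0], VALIDITY_AGE_RANGE[1] + 0.25, 0.5)
    ages = np.asarray(list(ages), dtype=float)
    probs_arr = np.asarray(list(probs), dtype=float)
    _warn_if_outside_validity(ages)
    mu = model.mean_log_amh(ages)
    qs = skewt.quantile(probs_arr, model.residual)
    values = np.exp(mu[:, None] + qs[None, :])
    return PercentileTable(ages=ages, probs=probs_arr, values=values)


def percentile_band(model: RegressionModel, age: float, amh: float) -> tuple[float, float]:
    """Locate an (age, AMH) measurement within the reference percentiles.

    Returns the half-open band ``(p_low, p_high]`` from the grid
    ``{0, .05, .10, .25, .50, .75, .90, .95, 1}`` containing the residual
    probability-integral transform of the measurement; a value lying
    exactly on a percentile curve belongs to the band below it.
    """
    if amh <= 0:
        raise ValueError(f"amh must be positive, got {amh}")
    _warn_if_outside_validity(age)
    u = float(skewt.cdf(math.log(amh) - float(model.mean_log_amh(age)), model.residual))
    edges = np.asarray(BAND_EDGES)
    # a measurement numerically on a curve (within 1e-9 in probability)
    # belongs to the band below it
    idx = int(np.searchsorted(edges, u - 1e-9, side="left"))
    idx = min(max(idx, 1), len(edges) - 1)
    return (float(edges[idx - 1]), float(edges[idx]))


def residual_gof(
    model: RegressionModel, records: pd.DataFrame, n_bins: int | None = None
) -> GofResult:
    """Chi-square goodness of fit of the residual law.

    Residuals are mapped through the fitted cdf (probability integral
    transform) and binned into ``n_bins`` equal-probability cells.  The
    default bin count, n − n_params + 1, makes the reported degrees of
    freedom n − n_params and gives statistic/df ≈ 1 when the law is
    correct.
    """
    records = _validate_amh_frame(records)
    n = len(records)
    if n_bins is None:
        n_bins = max(3, n - model.n_params + 1)
    if n_bins < 3:
        raise ValueError(f"n_bins must be at least 3, got {n_bins}")
    mu = model.mean_log_amh(records["age_years"].to_numpy(float))
    r = np.log(records["amh_ng_ml"].to_numpy(float)) - mu
    pit = np.asarray(skewt.cdf(r, model.residual))
    counts, _ = np.histogram(pit, bins=np.linspace(0.0, 1.0, n_bins + 1))
    expected = n / n_bins
    statistic = float(np.sum((counts - expected) ** 2 / expected))
    return GofResult(statistic=statistic, df=n_bins - 1, pit=pit)


def smooth_log_amh(
    records: pd.DataFrame,
    bandwidth: float,
    ages: Iterable[float] | None = None,
) -> pd.DataFrame:
    """Gaussian-kernel smoothed mean of log(AMH) against age.

    A purely descriptive curve used to check visual concordance with the
    quadratic fit; returns a frame with columns ``age_years`` and
    ``mean_log_amh``.
    """
    records = _validate_amh_frame(records)
    if len(records) < 30:
        raise ValueError(f"need at least 30 records, got {len(records)}")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    x = records["age_years"].to_numpy(float)
    y = np.log(records["amh_ng_ml"].to_numpy(float))
    if ages is None:
        ages = np.linspace(x.min(), x.max(), 101)
    grid = np.asarray(list(ages), dtype=float)
    w = np.exp(-0.5 * ((x[None, :] - grid[:, None]) / bandwidth) ** 2)
    curve = (w @ y) / w.sum(axis=1)
    return pd.DataFrame({"age_years": grid, "mean_log_amh": curve})
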