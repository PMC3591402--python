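"""Jones–Faddy skew-t distribution kernel.

Both stages of the menopause-prediction model use the same four-parameter
skew-t family: a location/scale shift of the standardized density

    f(z) ∝ (1 + t)^(a + 1/2) (1 − t)^(b + 1/2),   t = z / sqrt(a + b + z²),

normalized by 2^(a+b−1) B(a, b) sqrt(a + b).  The transform
u = (1 + t)/2 is Beta(a, b)-distributed, which gives closed-form cdf,
quantile and sampling routines (no root-finding).  ``a = b`` recovers a
Student-t with 2a degrees of freedom; ``a < b`` gives negative (left) skew.

Evaluation of pdf/cdf/quantile/sampling is delegated to
``scipy.stats.jf_skew_t`` (same convention).  The log-density used in the
likelihoods is computed here in log space, since the direct density
underflows far in the tails; moments use the closed forms obtained from
Beta moments of the transform.
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple

import numpy as np
from scipy import special
from scipy import stats

__all__ = [
    "SkewTParams",
    "Moments",
    "pdf",
    "logpdf",
    "cdf",
    "quantile",
    "sample",
    "moments",
    "mean_zero",
]

#: shapes this close to the a,b > 1/2 mean-existence boundary are rejected
#: outright rather than silently evaluated.
_SHAPE_FLOOR = 0.5001


@dataclasses.dataclass(frozen=True)
class SkewTParams:
    """Location/scale/shape parameters of a Jones–Faddy skew-t law.

    Parameters
    ----------
    location, scale
        In the units of the modelled variable (log ng/mL throughout this
        package); ``scale > 0``.
    a, b
        Dimensionless shape parameters, both > 0.5001 here (the mean
        exists only for a, b > 1/2 and ``mean_zero`` needs it).  The sign
        of the skewness equals the sign of ``a − b``.
    """

    location: float
    scale: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name in ("location", "scale", "a", "b"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float, np.floating, np.integer)) and math.isfinite(v)):
                raise ValueError(f"{name} must be a finite real number, got {v!r}")
            object.__setattr__(self, name, float(v))
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.a < _SHAPE_FLOOR or self.b < _SHAPE_FLOOR:
            raise ValueError(
                f"shape parameters must exceed {_SHAPE_FLOOR} (got a={self.a}, b={self.b}); "
                "near-boundary shapes have no finite mean and are rejected"
            )

    def frozen(self) -> stats.rv_continuous:
        """The equivalent frozen ``scipy.stats.jf_skew_t`` distribution."""
        return stats.jf_skew_t(self.a, self.b, loc=self.location, scale=self.scale)


class Moments(NamedTuple):
    mean: float
    variance: float | None


def _check_x(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("x must be finite")
    return arr


def _base_mean(a: float, b: float) -> float:
    # E[Z] = sqrt(a+b) (a−b) Γ(a−1/2) Γ(b−1/2) / (2 Γ(a) Γ(b))
    logs = (
        special.gammaln(a - 0.5)
        + special.gammaln(b - 0.5)
        - special.gammaln(a)
        - special.gammaln(b)
    )
    return 0.5 * math.sqrt(a + b) * (a - b) * math.exp(logs)


def pdf(x, p: SkewTParams):
    """Density at ``x``; integrates to one over the real line."""
    _check_x(x)
    return p.frozen().pdf(x)


def logpdf(x, p: SkewTParams):
    """Log-density, stable deep into both tails."""
    z = (_check_x(x) - p.location) / p.scale
    t = z / np.sqrt(p.a + p.b + z * z)
    lognorm = (
        (p.a + p.b - 1.0) * math.log(2.0)
        + special.betaln(p.a, p.b)
        + 0.5 * math.log(p.a + p.b)
        + math.log(p.scale)
    )
    return (p.a + 0.5) * np.log1p(t) + (p.b + 0.5) * np.log1p(-t) - lognorm


def cdf(x, p: SkewTParams):
    """Distribution function via the incomplete-beta transform."""
    _check_x(x)
    return p.frozen().cdf(x)


def quantile(prob, p: SkewTParams):
    """Quantile function (inverse cdf) via the Beta quantile transform."""
    q = np.asarray(prob, dtype=float)
    if np.any(~np.isfinite(q)) or np.any(q <= 0.0) or np.any(q >= 1.0):
        raise ValueError("prob must lie strictly inside (0, 1)")
    return p.frozen().ppf(prob)


def sample(n: int, p: SkewTParams, seed) -> np.ndarray:
    """Draw ``n`` variates; identical ``seed`` gives identical output.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.beta(p.a, p.b, size=int(n))
    z = (2.0 * u - 1.0) * math.sqrt(p.a + p.b) / (2.0 * np.sqrt(u * (1.0 - u)))
    return p.location + p.scale * z


def moments(p: SkewTParams) -> Moments:
    """Closed-form mean and variance.

    The variance exists only for ``a > 1 and b > 1``; otherwise it is
    reported as ``None`` (an explicit undefined signal) rather than a
    number.
    """
    m = _base_mean(p.a, p.b)
    mean = p.location + p.scale * m
    if p.a > 1.0 and p.b > 1.0:
        # E[Z²] = (a+b)/4 · (a/(b−1) + b/(a−1) − 2)
        ez2 = 0.25 * (p.a + p.b) * (p.a / (p.b - 1.0) + p.b / (p.a - 1.0) - 2.0)
        variance = p.scale**2 * (ez2 - m * m)
    else:
        variance = None
    return Moments(mean=mean, variance=variance)


def mean_zero(p: SkewTParams) -> SkewTParams:
    """Shift location so the distribution has exactly zero mean.

    Scale and shapes are unchanged; applying twice is a no-op.  Used to
    identify regression residual laws (the regression mean is then the
    expectation).
    """
    m = _base_mean(p.a, p.b)
    return SkewTParams(location=-p.scale * m, scale=p.scale, a=p.a, b=p.b)
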