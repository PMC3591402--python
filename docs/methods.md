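# Methods

## The model

### Stage 1: cross-sectional AMH reference model

For a woman of age *y* (years), serum AMH (ng/mL) is modelled on the log
scale as

    log AMH = μ(y) + ε,   μ(y) = c₀ + c₁ y + c₂ y²,

with ε following a Jones–Faddy skew-t distribution constrained to mean
zero, so μ is the conditional expectation. The skew-t has four
parameters (location, scale σ₁, shapes a, b): the standardized variable
z satisfies u = (1 + z/√(a+b+z²))/2 ~ Beta(a, b), giving closed-form
cdf, quantile and sampling through the incomplete-beta transform.
`a = b` recovers a Student-t with 2a degrees of freedom; `a < b` gives
left skew (sign of skewness = sign of a − b). The mean exists for
a, b > 1/2 and the variance for a, b > 1; shapes within 10⁻⁴ of the
mean-existence boundary are rejected outright rather than silently
evaluated, because the mean-zero constraint needs a finite mean.

All parameters (regression coefficients, σ₁, a, b) are estimated jointly
by maximum likelihood. Age-dependent reference percentiles are
`exp(μ(y) + q_p)` with q_p the residual quantile; a measurement is
assigned to the half-open band (p_low, p_high] between adjacent
percentiles of the grid {5, 10, 25, 50, 75, 90, 95}% — a value exactly
on a curve belongs to the band below it (the tie rule is a convention;
ties have probability zero in the model).

### Stage 2: menopause as threshold crossing

Menopause before age *y* is identified with the (latent) AMH trajectory
at *y* lying below a critical level θ:

    P(menopause ≤ y) = P(log AMH(y) < log θ) = F₂(log θ − μ(y)),

where F₂ is a mean-zero skew-t sharing the stage-1 shapes (a, b) with
scale σ₂ = σ₁·√κ. The variance ratio κ < 1 expresses that part of the
cross-sectional AMH variation is inter- and intra-cycle measurement
noise irrelevant to menopause timing. log θ is additive in BMI category
(cut-points 18.5 / 25 / 30 kg/m²) and smoking status, with normal-weight
non-smokers as the reference level (the modal cell). The density is
f₂(log θ − μ(y))·(−μ′(y)), positive wherever the mean declines.

Two structural consequences are worth stating plainly:

- the distribution is *defective at the lower end*: F at the age of peak
  AMH is P(log AMH(peak) < log θ) > 0 (≈ 0.1–0.4% per cell under the
  default calibration). The model simply does not describe menopause
  before the peak age, and percentile lookups that fall into this
  defective mass raise rather than extrapolate;
- the upper tail is polynomial (skew-t), so a tiny mass lies beyond 80
  years; percentile root-finding brackets (peak + 0.5, 80) years and
  fails loudly if a requested percentile is outside.

Stage 2 is fitted to menopausal ages by maximum likelihood with stage 1
held fixed (two-stage estimation). The likelihood conditions on
menopause falling inside the accepted physiological window (35, 65)
years — the same window the record validation enforces — via a per-cell
normalization term. κ is estimated on the log scale to enforce
positivity; covariate cells with no records have their offsets pinned to
zero and flagged unidentifiable instead of being silently estimated.

### Individual prediction

Locate (age, AMH) in a stage-1 percentile band, then evaluate the
stage-2 menopausal-age percentiles of the woman's covariate cell at the
band's edges. The open outer bands give one-sided intervals: below the
5th AMH percentile the lower edge is computed at the 1st percentile and
flagged as an extrapolation; above the 95th the upper side is reported
unbounded.

## Calibration of the default generating parameters

The source cohorts are unavailable and the regression coefficients were
never published, so the defaults are solved from printed anchors:

1. μ′(25) = 0 (peak at age 25);
2. the reference cell's menopausal-age percentiles: F reaches 0.10 /
   0.50 / 0.90 at 44.2 / 49.5 / 53.6 years with θ_ref = 0.31 ng/mL;
3. median AMH at age 30 equals 3.0 ng/mL (centre of the 2.5–3.5 ng/mL
   range implied by the published reference-percentile figure).

With the peak imposed, exact interpolation of the three percentile
anchors by *any* (c₀, c₂, σ₂) requires the shapes to satisfy a
quantile-spacing condition,

    (q₀.₁ − q₀.₅)/(q₀.₅ − q₀.₉) = (g(44.2) − g(49.5))/(g(49.5) − g(53.6)),
    g(y) = y² − 50y,

whose right side is ≈ 1.064 — a mildly left-skewed law, consistent with
the reported left skewness of the AMH residuals. The shapes are solved
on the one-parameter family b = a + 1 (a ≈ 5.15, base skewness ≈ −0.19);
the family choice fixes the second shape degree of freedom, which the
anchors cannot identify (any family crossing the spacing condition
reproduces the anchors exactly; tail weight beyond the 10–90% range is
not constrained by the printed tables). The anchors then determine the
model only up to a common scaling of (c₂, σ₂), which anchor 3 pins
down. Everything else is read off directly: per-cell thresholds from
the published threshold table, κ = 0.72, σ₁ = σ₂/√0.72.

The calibrated model reproduces the *other* cells' published
percentiles to within a few tenths of a year (e.g. over-weight
non-smoker median 50.6 vs 50.4; normal-weight smoker 48.6 vs 48.6),
which is the package's main external-consistency check.

## Synthetic cohorts

`generate_amh_cohort` (default n = 375): ages uniform on 19–44 (the
recruitment age-distribution was not published; uniform is assumed),
BMI normal(23.2, 4.2²) truncated at 15, smoking Bernoulli(0.335),
log AMH = μ(age) + mean-zero skew-t noise with scale σ₁.

`generate_menopause_cohort` (default n = 2635): covariate cells from
(under 15/2635, normal 0.45, over 0.35, obese remainder) × smoking
Bernoulli(0.276) — the normal/over split within their combined 80% share
is a choice, as only the share was published. Ages are inverse-cdf
draws from the cell's threshold-crossing law, truncated to (35, 65)
years so every generated record passes validation; the truncation
removes ≲ 0.5% of mass per cell. The default per-cell thresholds are
the eight published point estimates, which are not exactly additive in
the log (printed rounding); the fitted model is additive, so estimated
offsets are a pooled compromise — relevant only below the resolution of
the recovery tolerances.

What the generator does *not* emulate: recall bias and digit preference
in reported menopausal ages, secular trends, the multi-centre structure
of the menopause cohort, assay left-censoring at the 0.14 ng/mL
detection limit (a left-censored likelihood exists behind the
`censor_below` flag but is off by default), and any age-BMI or
age-smoking association. Passing recovery tests therefore show that the
estimators recover the generating process under the model's own
assumptions at the study sizes — not robustness to these real-data
features.

## Numerical choices

- **Kernel.** Density/cdf/quantile/sampling delegate to
  `scipy.stats.jf_skew_t` (identical parameterization). The likelihood
  uses a log-space density written here, as the direct density
  underflows beyond |z| ≈ 40 at typical shapes; moments use closed
  forms via log-gamma.
- **Stage-1 optimizer.** L-BFGS-B on transformed parameters (log scale,
  shapes as 0.5001 + eᵘ, standardized design columns) with a fixed
  five-point ladder of shape starts — symmetric, left-skewed,
  right-skewed, heavy, light — because skew-t likelihoods can be
  multimodal in the shapes; ftol 10⁻¹², followed by a derivative-free
  polish so that refitting shifted data reproduces coefficients to
  ~10⁻⁶. Near-Gaussian samples put the shape likelihood on a plateau
  (t → normal as a, b → ∞ along a ridge); when line searches fail
  there, Nelder–Mead restarts are applied until a fresh restart confirms
  the objective value, and shapes may legitimately end at the box bound
  (a, b ≤ ~8100). Shape estimates at n = 375 are weakly identified and
  should not be interpreted individually.
- **Stage-2 optimizer.** L-BFGS-B with an analytic gradient (the
  bootstrap refits thousands of times); three κ starting values
  (0.8, 0.5, 1.3); warm starts for bootstrap refits.
- **Goodness of fit.** The residual check is a probability-integral
  transform chi-square over equal-probability bins; the default bin
  count n − p + 1 makes the reported degrees of freedom n − p and the
  null expectation of statistic/df ≈ 1. With ~1 expected count per bin
  this is a calibration summary (mean-matched), not an exact chi-square
  reference; simulation places its null statistic/df median within
  [0.85, 1.15] at n = 375.
- **Smoother.** The visual-concordance curve is a Gaussian-kernel
  (Nadaraya–Watson) local mean; it carries the usual first-order
  boundary bias at the edges of the age range, so concordance checks
  use bandwidths ≤ 2 years.
- **Uncertainty.** `estimate_uncertainty` is a seeded parametric
  bootstrap of *stage 2 only*: menopausal ages are regenerated from the
  fitted model at the observed covariate profiles and stage 2 refitted.
  Intervals are percentile-method 95%; they are conditional on the
  stage-1 fit and therefore much narrower than total uncertainty for
  the thresholds (whose dominant error is the extrapolation of μ to
  ~50 years). Simulation puts the conditional coverage of the reference
  threshold's interval at ~95%. Refits that fail (> 10% aborts the
  procedure) or whose percentiles become unreachable in a sparse cell
  (the under-weight cells hold < 1% of records) are recorded as missing
  draws.
- **Determinism.** All randomness flows through
  `numpy.random.default_rng` seeded from user-supplied integers; the
  AMH and menopause generators use independent child streams of the
  config seed. Identical seeds give bit-identical cohorts, fits and
  bootstrap tables; pipeline reruns from one config are byte-identical.

## Problem sizes used in the shipped checks

Simulation-based checks run at the study sizes (375 / 2635) with
replicate counts chosen to keep the full suite in the tens of minutes
on one CPU: 50 replicates for full-pipeline recovery (medians compared
at the published values' tolerances), 500 null replicates for the
likelihood-ratio test's type-I error, 100 outer replicates × 100
bootstrap draws for interval coverage, and 10⁵-row cohorts for
generator-vs-model convergence checks.

## Known limitations

- Menopausal ages are treated as exact continuous values by default;
  recalled ages are plausibly integer-rounded. An interval-censored
  (±0.5 year) likelihood is available via
  ``fit_threshold_model(..., interval_censored=True)``; on rounded
  synthetic ages it agrees with the exact-age fit to well within
  sampling noise.
- Two-stage estimation (the default) ignores stage-1 uncertainty in
  stage-2 standard errors (see above). ``fit_joint_model`` maximizes
  the combined likelihood over all parameters as an alternative; the
  bootstrap machinery, however, resamples stage 2 only in either case.
- Stage 2 shares the stage-1 shape parameters by assumption; the data
  published in summary form cannot distinguish this from a re-estimated
  shape.
- The threshold model is cross-sectionally identified: it predicts
  population percentile bands, not an individual's trajectory, and says
  nothing about menopause before the AMH peak age.
- Covariates beyond BMI category and smoking (parity, hormonal
  contraception) are out of scope.
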