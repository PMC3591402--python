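"""Stage-2 threshold model: cdf/pdf, fitting, percentiles, bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import menopredict as mp
from menopredict.menopause import (
    CovariateProfile,
    estimate_uncertainty,
    fit_joint_model,
    observed_vs_model_cdf,
    sample_menopause_ages,
    threshold_loglik,
)


@pytest.fixture(scope="module")
def ref():
    return CovariateProfile("normal", False)


class TestCovariateProfile:
    @pytest.mark.parametrize(
        "bmi,expected",
        [(17.0, "under"), (18.5, "normal"), (24.9, "normal"), (25.0, "over"),
         (29.9, "over"), (30.0, "obese")],
    )
    def test_bmi_cutpoints(self, bmi, expected):
        assert CovariateProfile.from_bmi(bmi, False).bmi_category == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            CovariateProfile("skinny", False)


class TestMenopauseCdf:
    def test_error_before_peak_age(self, true_rm, true_tm, ref):
        with pytest.raises(ValueError, match="peak"):
            mp.menopause_cdf(24.0, ref, true_tm, true_rm)

    def test_negligible_before_age_30(self, true_rm, true_tm, ref):
        assert mp.menopause_cdf(30.0, ref, true_tm, true_rm) < 5e-3

    def test_half_at_calibrated_median(self, true_rm, true_tm, ref):
        assert mp.menopause_cdf(49.5, ref, true_tm, true_rm) == pytest.approx(0.5, abs=1e-6)

    def test_nondecreasing_to_one(self, true_rm, true_tm, ref):
        y = np.linspace(26, 100, 300)
        c = np.asarray(mp.menopause_cdf(y, ref, true_tm, true_rm))
        assert np.all(np.diff(c) >= 0)
        assert c[-1] > 0.999

    def test_matches_integral_of_pdf(self, true_rm, true_tm, ref):
        lo = true_rm.peak_age + 1e-6
        val, _ = integrate.quad(
            lambda t: float(mp.menopause_pdf(t, ref, true_tm, true_rm)), lo, 50.0, limit=200
        )
        expected = float(mp.menopause_cdf(50.0, ref, true_tm, true_rm)) - float(
            mp.menopause_cdf(lo, ref, true_tm, true_rm)
        )
        assert val == pytest.approx(expected, abs=1e-6)


class TestMenopausePdf:
    def test_matches_numeric_derivative_of_cdf(self, true_rm, true_tm, ref):
        h = 1e-5
        deriv = (
            float(mp.menopause_cdf(50.0 + h, ref, true_tm, true_rm))
            - float(mp.menopause_cdf(50.0 - h, ref, true_tm, true_rm))
        ) / (2 * h)
        assert float(mp.menopause_pdf(50.0, ref, true_tm, true_rm)) == pytest.approx(
            deriv, abs=1e-6
        )

    def test_total_mass_accounts_for_defective_lower_end(self, true_rm, true_tm, ref):
        # the threshold-crossing law puts a small probability on "AMH
        # already below threshold at the peak age"; the density over
        # (peak, 80) integrates to F(80) - F(peak), not exactly 1
        lo = true_rm.peak_age + 1e-9
        total, _ = integrate.quad(
            lambda t: float(mp.menopause_pdf(t, ref, true_tm, true_rm)), lo, 80.0, limit=400
        )
        expected = float(mp.menopause_cdf(80.0, ref, true_tm, true_rm)) - float(
            mp.menopause_cdf(lo, ref, true_tm, true_rm)
        )
        assert total == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(1.0, abs=5e-3)

    def test_unimodal_shape_spot_check(self, true_rm, true_tm, ref):
        assert float(mp.menopause_pdf(36.0, ref, true_tm, true_rm)) < float(
            mp.menopause_pdf(49.5, ref, true_tm, true_rm)
        )


class TestFitThresholdModel:
    def test_single_replicate_recovery(self, fitted_tm, ref):
        assert fitted_tm.converged
        assert 0.2 <= fitted_tm.threshold(ref) <= 0.45
        assert 0.5 <= fitted_tm.kappa <= 1.1

    def test_loglik_beats_generating_params(self, fitted_tm, fitted_rm, true_tm, meno_cohort):
        # optimizer sanity: the fitted likelihood dominates the truth's,
        # both evaluated with the same stage-1 model
        truth_for_fitted_rm = mp.build_threshold_model(
            fitted_rm,
            alpha=true_tm.alpha,
            beta_bmi=true_tm.beta_bmi,
            gamma_smoke=true_tm.gamma_smoke,
            kappa=true_tm.kappa,
        )
        ll_truth = threshold_loglik(meno_cohort, fitted_rm, truth_for_fitted_rm)
        assert fitted_tm.loglik >= ll_truth

    def test_null_offsets_recovered(self, gen_config, true_rm):
        flat = {(c, s): 0.31 for c in ("under", "normal", "over", "obese") for s in (False, True)}
        offsets = []
        for s in range(5):
            cfg = gen_config.replace(seed=500 + s, thresholds=flat)
            tm = mp.fit_threshold_model(mp.generate_menopause_cohort(cfg), true_rm)
            offsets.append(
                [tm.beta_bmi["over"], tm.beta_bmi["obese"], tm.gamma_smoke]
            )
        med = np.median(np.abs(np.array(offsets)), axis=0)
        assert np.all(med < 0.1)

    def test_empty_cell_flagged_unidentifiable(self, meno_cohort, fitted_rm):
        no_obese = meno_cohort[meno_cohort["bmi_category"] != "obese"]
        tm = mp.fit_threshold_model(no_obese, fitted_rm)
        assert "obese" in tm.unidentifiable
        assert "obese" not in tm.beta_bmi

    def test_too_few_records_rejected(self, meno_cohort, fitted_rm):
        with pytest.raises(ValueError, match="at least 100"):
            mp.fit_threshold_model(meno_cohort.head(50), fitted_rm)

    def test_out_of_range_age_rejected_with_rows(self, meno_cohort, fitted_rm):
        bad = meno_cohort.copy()
        bad.loc[bad.index[3], "age_menopause_years"] = 72.0
        with pytest.raises(ValueError, match="rejected rows"):
            mp.fit_threshold_model(bad, fitted_rm)

    def test_interval_censored_variant_agrees_on_rounded_ages(
        self, meno_cohort, fitted_rm, fitted_tm
    ):
        # ages recalled to whole years: the ±0.5-year interval likelihood
        # should land near the exact-age fit
        rounded = meno_cohort.assign(
            age_menopause_years=meno_cohort["age_menopause_years"].round().clip(36, 64)
        )
        tm_ic = mp.fit_threshold_model(rounded, fitted_rm, interval_censored=True)
        assert tm_ic.kappa == pytest.approx(fitted_tm.kappa, abs=0.1)
        assert math.log(tm_ic.threshold(CovariateProfile("normal", False))) == pytest.approx(
            math.log(fitted_tm.threshold(CovariateProfile("normal", False))), abs=0.15
        )


class TestJointFit:
    def test_joint_likelihood_dominates_two_stage(
        self, amh_cohort, meno_cohort, fitted_rm, fitted_tm
    ):
        rm_j, tm_j = fit_joint_model(amh_cohort, meno_cohort)
        assert rm_j.loglik >= fitted_rm.loglik + fitted_tm.loglik - 1e-6
        # joint estimates stay in the neighbourhood of the two-stage ones
        assert tm_j.kappa == pytest.approx(fitted_tm.kappa, abs=0.25)
        assert rm_j.peak_age == pytest.approx(fitted_rm.peak_age, abs=2.0)


class TestMenopausePercentiles:
    def test_roundtrip_through_cdf(self, true_rm, true_tm, ref):
        probs = (0.05, 0.25, 0.5, 0.9)
        ages = mp.menopause_percentiles(true_tm, true_rm, ref, probs)
        for p, age in zip(probs, ages):
            assert float(mp.menopause_cdf(age, ref, true_tm, true_rm)) == pytest.approx(
                p, abs=1e-8
            )

    def test_strictly_increasing_in_prob(self, true_rm, true_tm, ref):
        ages = mp.menopause_percentiles(true_tm, true_rm, ref)
        assert np.all(np.diff(ages) > 0)

    def test_smokers_earlier_within_every_category(self, true_rm, true_tm):
        for cat in ("under", "normal", "over", "obese"):
            non = mp.menopause_percentiles(true_tm, true_rm, CovariateProfile(cat, False))
            smo = mp.menopause_percentiles(true_tm, true_rm, CovariateProfile(cat, True))
            assert np.all(smo < non)

    def test_bmi_stochastic_ordering(self, true_rm, true_tm):
        # higher threshold (lower BMI) -> earlier menopause at every p
        for smoker in (False, True):
            under = mp.menopause_percentiles(true_tm, true_rm, CovariateProfile("under", smoker))
            normal = mp.menopause_percentiles(true_tm, true_rm, CovariateProfile("normal", smoker))
            over = mp.menopause_percentiles(true_tm, true_rm, CovariateProfile("over", smoker))
            assert np.all(under < normal) and np.all(normal < over)

    def test_no_covariate_percentiles_between_extremes(self, meno_cohort, fitted_rm, fitted_tm):
        tm0 = mp.fit_threshold_model(meno_cohort, fitted_rm, include_covariates=False)
        marginal = mp.menopause_percentiles(tm0, fitted_rm, CovariateProfile("normal", False))
        per_profile = np.array(
            [mp.menopause_percentiles(fitted_tm, fitted_rm, p) for p in mp.all_profiles()]
        )
        assert np.all(marginal > per_profile.min(axis=0) - 0.25)
        assert np.all(marginal < per_profile.max(axis=0) + 0.25)

    def test_invalid_prob_rejected(self, true_rm, true_tm, ref):
        with pytest.raises(ValueError):
            mp.menopause_percentiles(true_tm, true_rm, ref, (0.0,))


class TestObservedVsModelCdf:
    def _stratum_frame(self, tm, rm, profile, n, seed):
        ages = sample_menopause_ages(
            n, tm.log_threshold(profile), tm.stage2_residual, rm,
            np.random.default_rng(seed),
        )
        return pd.DataFrame(
            {
                "subject_id": [f"M{i}" for i in range(n)],
                "age_menopause_years": ages,
                "bmi_category": profile.bmi_category,
                "smoker": int(profile.smoker),
            }
        )

    def test_self_sampled_concordance(self, true_rm, true_tm, ref):
        passes = 0
        for s in range(10):
            df = self._stratum_frame(true_tm, true_rm, ref, 1000, seed=600 + s)
            res = observed_vs_model_cdf(df, true_tm, true_rm, ref)
            passes += res.max_gap < 0.06
        assert passes >= 9

    def test_empirical_curve_is_step_to_one(self, true_rm, true_tm, ref):
        df = self._stratum_frame(true_tm, true_rm, ref, 200, seed=611)
        res = observed_vs_model_cdf(df, true_tm, true_rm, ref)
        assert res.empirical[-1] == 1.0
        assert np.all(np.diff(res.empirical) >= 0)

    def test_shift_inflates_gap_monotonically(self, true_rm, true_tm, ref):
        df = self._stratum_frame(true_tm, true_rm, ref, 500, seed=612)
        gaps = []
        for shift in (0.0, 2.0, 5.0):
            shifted = df.assign(
                age_menopause_years=(df["age_menopause_years"] + shift).clip(upper=64.9)
            )
            gaps.append(observed_vs_model_cdf(shifted, true_tm, true_rm, ref).max_gap)
        assert gaps[0] < gaps[1] < gaps[2]

    def test_small_stratum_refused(self, true_rm, true_tm, ref):
        df = self._stratum_frame(true_tm, true_rm, ref, 15, seed=613)
        with pytest.raises(ValueError, match="only 15"):
            observed_vs_model_cdf(df, true_tm, true_rm, ref)


@pytest.fixture(scope="module")
def unc(fitted_tm, fitted_rm, meno_cohort):
    return estimate_uncertainty(
        fitted_tm, fitted_rm, meno_cohort, n_boot=100, seed=99, probs=(0.1, 0.5, 0.9)
    )


class TestEstimateUncertainty:
    def test_intervals_contain_point_estimates(self, unc):
        assert np.all(unc.thresholds["ci_low"] <= unc.thresholds["point"])
        assert np.all(unc.thresholds["point"] <= unc.thresholds["ci_high"])
        assert unc.kappa["ci_low"] <= unc.kappa["point"] <= unc.kappa["ci_high"]

    def test_reproducible_for_same_seed(self, unc, fitted_tm, fitted_rm, meno_cohort):
        again = estimate_uncertainty(
            fitted_tm, fitted_rm, meno_cohort, n_boot=100, seed=99, probs=(0.1, 0.5, 0.9)
        )
        pd.testing.assert_frame_equal(unc.thresholds, again.thresholds)
        pd.testing.assert_frame_equal(unc.percentile_se, again.percentile_se)

    def test_percentile_se_positive(self, unc):
        assert np.all(unc.percentile_se.to_numpy() > 0)

    def test_small_n_boot_rejected(self, fitted_tm, fitted_rm, meno_cohort):
        with pytest.raises(ValueError, match="n_boot"):
            estimate_uncertainty(fitted_tm, fitted_rm, meno_cohort, n_boot=50, seed=1)
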