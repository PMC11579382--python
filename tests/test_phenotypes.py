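import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from growthgwas import ModelSpec, SplineSpec
from growthgwas.lmm import LMMFit
from growthgwas.phenotypes import (
    DEFAULT_WINDOWS,
    SubjectTrajectory,
    derive_phenotypes,
    find_ap_ar,
    iqr_exclusion,
    percent_bmi_change,
    phenotype_summaries,
    predict_trajectory,
    window_auc,
    window_slope,
)
from growthgwas.splines import design_matrix


def make_fit(beta, spec=None, blup_cols=None):
    """Minimal fitted-model object around known coefficients."""
    spec = spec or ModelSpec(
        SplineSpec("cubic_spline", (1.0, 8.0, 12.0)), SplineSpec("cubic_slope")
    )
    q = spec.random.n_columns if spec.random else 0
    names = spec.fixed.column_names
    return LMMFit(
        spec=spec,
        beta=pd.Series(np.asarray(beta, dtype=float), index=names),
        beta_se=pd.Series(np.zeros(len(beta)), index=names),
        G=pd.DataFrame(np.eye(q) * 0.01),
        sigma2=0.001,
        phi=None,
        loglik=0.0,
        n_params=len(beta) + q * (q + 1) // 2 + 1,
        converged="ok",
        message="",
        n_subjects=1,
        n_obs=1,
        method="ML",
    )


def poly_trajectory(coefs, lo=0.0384, hi=17.0, step=0.01):
    """Trajectory for an explicit polynomial (ascending coefficients)."""
    n = int(round((hi - lo) / step)) + 1
    t = lo + step * np.arange(n)
    y = np.polynomial.polynomial.polyval(t, coefs)
    return SubjectTrajectory(iid="T", ages=t, log_bmi=y, step=step)


class TestPredictTrajectory:
    def test_grid_has_expected_points(self, fitted_male):
        fit, _ = fitted_male
        traj = predict_trajectory(fit, None, age_range=(0.0, 1.0), step=0.01)
        assert len(traj.ages) == 101
        assert traj.ages[0] == 0.0 and traj.ages[-1] == pytest.approx(1.0)

    def test_zero_blup_gives_fixed_curve(self, fitted_male):
        fit, _ = fitted_male
        a = predict_trajectory(fit, None)
        b = predict_trajectory(fit, np.zeros(4))
        assert np.array_equal(a.log_bmi, b.log_bmi)

    def test_design_matrix_path_equals_direct_polynomial(self):
        """Two evaluation routes for the same curve agree to 1e-12."""
        beta = np.array([2.5, 0.8, -0.5, 0.1, -0.1, 0.01, 0.005])
        fit = make_fit(beta)
        traj = predict_trajectory(fit, None, age_range=(0.0384, 17.0))
        t = traj.ages
        direct = (
            beta[0]
            + beta[1] * t
            + beta[2] * t**2
            + beta[3] * t**3
            + beta[4] * np.clip(t - 1, 0, None) ** 3
            + beta[5] * np.clip(t - 8, 0, None) ** 3
            + beta[6] * np.clip(t - 12, 0, None) ** 3
        )
        assert np.allclose(traj.log_bmi, direct, atol=1e-12)


class TestFindApAr:
    def test_constructed_cubic_with_known_extrema(self):
        # y'(t) = a (t - 0.8)(t - 5): rises to a maximum at 0.8, falls to a
        # minimum at 5.0 (expand a(t^2 - 5.8t + 4) and integrate)
        a = 0.05
        coefs = [3.0, a * 4.0, -a * 5.8 / 2, a / 3]
        traj = poly_trajectory(coefs)
        ap_age, ap_bmi, ar_age, ar_bmi = find_ap_ar(traj)
        assert ap_age == pytest.approx(0.80, abs=0.011)
        assert ar_age == pytest.approx(5.00, abs=0.011)
        assert ap_bmi == pytest.approx(np.exp(np.polynomial.polynomial.polyval(ap_age, coefs)))
        assert ap_age < ar_age

    def test_monotone_curve_has_no_ap_ar(self):
        traj = poly_trajectory([2.0, 0.05])  # strictly increasing
        assert all(np.isnan(v) for v in find_ap_ar(traj))

    def test_nadir_before_peak_is_rejected(self):
        # y'(t) = -a (t - 1.0)(t - 6): minimum at 1.0, maximum at 6.0
        a = 0.05
        coefs = [3.0, -a * 6.0, a * 7.0 / 2, -a / 3]
        traj = poly_trajectory(coefs)
        assert all(np.isnan(v) for v in find_ap_ar(traj))

    def test_extremum_outside_window_ignored(self):
        # maximum at 0.1 (below 0.25): no AP in window, min at 5 has no prior peak
        a = 0.05
        coefs = [3.0, a * 0.5, -a * 5.1 / 2, a / 3]
        traj = poly_trajectory(coefs)
        assert all(np.isnan(v) for v in find_ap_ar(traj))


class TestWindowSlope:
    def test_linear_curve_gives_exact_slope(self):
        traj = poly_trajectory([1.0, 0.1])
        for a, b in DEFAULT_WINDOWS.values():
            assert window_slope(traj, a, b) == pytest.approx(0.1, abs=1e-12)

    def test_constant_curve_gives_zero(self):
        traj = poly_trajectory([2.0])
        assert window_slope(traj, 1.5, 3.5) == 0.0

    def test_window_outside_grid_is_missing(self):
        traj = poly_trajectory([2.0], lo=1.0, hi=10.0)
        assert np.isnan(window_slope(traj, 12.0, 17.0))

    def test_matches_endpoint_evaluation_of_spline_curve(self, fitted_male):
        fit, _ = fitted_male
        traj = predict_trajectory(fit, None)
        a, b = 1.5, 3.5
        ya = design_matrix([a], fit.spec.fixed)[0] @ fit.fixed_coef()
        yb = design_matrix([b], fit.spec.fixed)[0] @ fit.fixed_coef()
        assert window_slope(traj, a, b) == pytest.approx((yb - ya) / (b - a), abs=1e-9)


class TestWindowAuc:
    def test_constant_curve(self):
        fit = make_fit([2.0, 0, 0, 0, 0, 0, 0])
        assert window_auc(fit, None, 1.0, 4.0) == pytest.approx(6.0)

    def test_linear_curve_integrates_to_half(self):
        fit = make_fit([0.0, 1.0, 0, 0, 0, 0, 0])
        assert window_auc(fit, None, 0.0, 1.0) == pytest.approx(0.5)

    def test_matches_adaptive_quadrature_with_blup(self):
        rng = np.random.default_rng(7)
        beta = np.array([2.5, 0.8, -0.5, 0.1, -0.1, 0.01, 0.005])
        fit = make_fit(beta)
        b_i = rng.normal(0, 0.05, 4)
        for a, b in DEFAULT_WINDOWS.values():
            closed = window_auc(fit, b_i, a, b)
            numeric, _ = quad(
                lambda t: float(
                    design_matrix([t], fit.spec.fixed)[0] @ beta
                    + design_matrix([t], fit.spec.random)[0] @ b_i
                ),
                a,
                b,
                points=[k for k in (1.0, 8.0, 12.0) if a < k < b],
            )
            assert closed == pytest.approx(numeric, abs=1e-8)

    def test_auc_additivity(self):
        beta = np.array([2.5, 0.8, -0.5, 0.1, -0.1, 0.01, 0.005])
        fit = make_fit(beta)
        total = window_auc(fit, None, 0.5, 9.0)
        split = window_auc(fit, None, 0.5, 4.0) + window_auc(fit, None, 4.0, 9.0)
        assert total == pytest.approx(split, abs=1e-10)


def test_slope_invariant_to_grid_step(fitted_male):
    fit, _ = fitted_male
    t1 = predict_trajectory(fit, None, step=0.01)
    t2 = predict_trajectory(fit, None, step=0.001)
    s1 = window_slope(t1, 1.5, 3.5)
    s2 = window_slope(t2, 1.5, 3.5)
    assert s1 == pytest.approx(s2, abs=1e-6)


def test_derive_phenotypes_full_table(fitted_male):
    fit, male = fitted_male
    ph = derive_phenotypes(fit, male)
    assert ph.shape[1] == 12
    present = ph.dropna(subset=["ap_age"])
    assert (present["ap_age"] < present["ar_age"]).all()
    assert present["ap_age"].between(0.25, 10).all()
    # infancy slope should be strongly positive on the BMI rise to the AP
    assert ph["slope_infancy"].mean() > 0.3


def test_short_cohort_has_missing_adolescent_phenotypes(fitted_male):
    fit, male = fitted_male
    ph = derive_phenotypes(fit, male, age_range=(0.0384, 16.0))
    assert ph["slope_adolescence"].isna().all()
    assert ph["auc_adolescence"].isna().all()
    assert ph["slope_late_childhood"].notna().all()


class TestIqrExclusion:
    def test_flags_value_outside_twice_iqr(self):
        df = pd.DataFrame({"p": [1.0, 2.0, 3.0, 4.0, 100.0]})
        q1, q3 = np.quantile(df["p"], [0.25, 0.75])
        assert 100.0 > q3 + 2 * (q3 - q1)
        mask, kept = iqr_exclusion(df)
        assert mask.sum() == 1
        assert 100.0 not in kept["p"].values

    def test_identical_values_no_exclusions(self):
        df = pd.DataFrame({"p": [5.0] * 10})
        mask, kept = iqr_exclusion(df)
        assert mask.sum() == 0

    def test_outlier_on_one_phenotype_excludes_subject_entirely(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "slope": rng.normal(0, 1, 30),
                "ar_age": np.r_[rng.normal(5, 0.3, 29), 40.0],
            },
            index=[f"S{i}" for i in range(30)],
        )
        mask, kept = iqr_exclusion(df)
        assert mask.loc["S29"]
        assert "S29" not in kept.index


def test_percent_bmi_change_identity():
    slopes = np.array([0.56, 0.36, 0.02])
    expected = 100.0 * (np.exp(slopes) - 1.0)
    assert percent_bmi_change(0.56) == pytest.approx(expected[0])
    assert [percent_bmi_change(s) for s in slopes] == pytest.approx(expected)


def test_phenotype_summaries_structure(fitted_male):
    fit, male = fitted_male
    ph = derive_phenotypes(fit, male)
    sex = pd.Series("male", index=ph.index)
    end_bmi = np.exp(
        pd.Series(
            design_matrix(np.full(len(ph), 17.0), fit.spec.fixed) @ fit.fixed_coef(),
            index=ph.index,
        )
        + np.random.default_rng(1).normal(0, 0.1, len(ph))
    )
    out = phenotype_summaries(ph, sex, end_bmi)
    corr = out["correlations"]
    assert np.allclose(np.diag(corr.values), 1.0)
    assert corr.loc["auc_infancy", "ap_bmi"] > 0.5  # overlapping windows co-vary
    assert out["end_bmi_adj_r2"].notna().all()


def test_phenotypes_track_shared_random_driver(fitted_male, small_cohort):
    """Subject-level BMI deviations drive AP BMI and infancy AUC together."""
    cfg, _, truth = small_cohort
    fit, male = fitted_male
    ph = derive_phenotypes(fit, male)
    b0 = truth["subjects"].loc[ph.index, "b0"]
    assert ph["auc_infancy"].corr(
        ph["ap_bmi"].apply(np.log)
    ) > 0.5
    assert ph["auc_infancy"].corr(b0) > 0.3
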