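"""Trajectory phenotypes: adiposity peak/rebound, window slopes and AUCs.

From a fitted mixed model and each subject's BLUPs, the predicted log-BMI
curve (fixed + random coefficients, evaluated every 0.01 year) yields
twelve per-subject phenotypes: age and BMI at the adiposity peak (AP, the
first interior maximum between 0.25 and 10 years) and the adiposity
rebound (AR, the first nadir after the AP), plus rates of change (slopes)
and cumulative exposure (areas under the log-BMI curve) over four windows
of approximately linear change — infancy (2 weeks to 0.5 yr), early
childhood (1.5-3.5 yr), late childhood (6.5-10 yr), adolescence (12-17
yr).  Slopes are two-point differences of the predicted curve; AUCs are
closed-form integrals of the spline coefficients.  Subjects outside twice
the interquartile range on any phenotype are excluded from all downstream
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .lmm import LMMFit, blups
from .splines import design_matrix, integral_row

__all__ = [
    "SubjectTrajectory",
    "DEFAULT_WINDOWS",
    "predict_trajectory",
    "find_ap_ar",
    "window_slope",
    "window_auc",
    "derive_phenotypes",
    "iqr_exclusion",
    "phenotype_summaries",
    "percent_bmi_change",
]

MIN_AGE_WEEKS2 = 2.0 / 52.0
AP_AR_WINDOW = (0.25, 10.0)
DEFAULT_WINDOWS = {
    "infancy": (MIN_AGE_WEEKS2, 0.5),
    "childhood": (1.5, 3.5),
    "late_childhood": (6.5, 10.0),
    "adolescence": (12.0, 17.0),
}
PHENOTYPE_COLUMNS = [
    "ap_age",
    "ap_bmi",
    "ar_age",
    "ar_bmi",
    "slope_infancy",
    "slope_childhood",
    "slope_late_childhood",
    "slope_adolescence",
    "auc_infancy",
    "auc_childhood",
    "auc_late_childhood",
    "auc_adolescence",
]


@dataclass
class SubjectTrajectory:
    """Predicted log BMI on a fine, regular age grid.

    When built from a fitted model the spline bases and coefficients ride
    along, so slopes can be evaluated at exact window endpoints rather
    than snapped grid ages (making them independent of the grid step).
    """

    iid: str
    ages: np.ndarray
    log_bmi: np.ndarray
    step: float = 0.01
    basis_fixed: object = None
    coef_fixed: np.ndarray | None = None
    basis_random: object = None
    coef_random: np.ndarray | None = None

    def at(self, t: float) -> float:
        """Exact curve value when coefficients are attached, else nearest
        grid value."""
        if self.basis_fixed is not None:
            y = float(design_matrix([t], self.basis_fixed)[0] @ self.coef_fixed)
            if self.basis_random is not None and self.coef_random is not None:
                y += float(design_matrix([t], self.basis_random)[0] @ self.coef_random)
            return y
        return float(self.log_bmi[int(np.argmin(np.abs(self.ages - t)))])


def _grid(age_range, step):
    lo, hi = age_range
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def predict_trajectory(
    fit: LMMFit,
    blup_i,
    age_range=(MIN_AGE_WEEKS2, 17.0),
    step: float = 0.01,
    iid: str = "",
) -> SubjectTrajectory:
    """Subject curve ``X(t) beta + Z(t) b_i`` on the prediction grid.

    Covariate dummies are held at their reference level (zero), so the
    curve is the spline part only.  ``blup_i`` may be a Series/array of
    random coefficients or None (population curve).
    """
    ages = _grid(age_range, step)
    y = design_matrix(ages, fit.spec.fixed) @ fit.fixed_coef()
    b = None
    if blup_i is not None and fit.spec.random is not None:
        b = np.asarray(blup_i, dtype=float)
        y = y + design_matrix(ages, fit.spec.random) @ b
    return SubjectTrajectory(
        iid=iid,
        ages=ages,
        log_bmi=y,
        step=step,
        basis_fixed=fit.spec.fixed,
        coef_fixed=fit.fixed_coef(),
        basis_random=fit.spec.random if b is not None else None,
        coef_random=b,
    )


def find_ap_ar(traj: SubjectTrajectory, window=AP_AR_WINDOW, tol: float = 1e-12):
    """Locate the adiposity peak and rebound on the predicted curve.

    AP is the first interior local maximum (discrete derivative changes
    sign + to -) of log BMI with age inside ``window``; AR is the first
    interior local minimum after the AP, inside the same window.  BMIs are
    returned on the natural scale (exp of predicted log BMI).  If either
    turning point is absent, or the AP does not precede the AR, all four
    values are missing — a boundary plateau never counts as a turning
    point, and exact ties break to the earliest age.
    """
    y = traj.log_bmi
    t = traj.ages
    d = np.diff(y)
    nan = (np.nan,) * 4
    lo, hi = window
    interior = np.where((t[1:-1] >= lo) & (t[1:-1] <= hi))[0]
    ap_idx = None
    for i in interior:  # i indexes t[i+1]
        if d[i] > tol and d[i + 1] < -tol:
            ap_idx = i + 1
            break
    if ap_idx is None:
        return nan
    ar_idx = None
    for i in interior:
        if i + 1 <= ap_idx:
            continue
        if d[i] < -tol and d[i + 1] > tol:
            ar_idx = i + 1
            break
    if ar_idx is None or t[ap_idx] >= t[ar_idx]:
        return nan
    return (
        float(t[ap_idx]),
        float(np.exp(y[ap_idx])),
        float(t[ar_idx]),
        float(np.exp(y[ar_idx])),
    )


def window_slope(traj: SubjectTrajectory, a: float, b: float) -> float:
    """Two-point slope (y(b) - y(a)) / (b - a), log-BMI units per year.

    A window extending beyond the prediction grid gives a missing value.
    With model coefficients attached the endpoints are evaluated exactly
    (grid-step independent); otherwise they snap to the nearest grid age.
    """
    if a >= b:
        raise ValueError("window must have a < b")
    t = traj.ages
    eps = traj.step / 2 + 1e-9
    if a < t[0] - eps or b > t[-1] + eps:
        return np.nan
    if traj.basis_fixed is not None:
        return float((traj.at(b) - traj.at(a)) / (b - a))
    ia = int(np.argmin(np.abs(t - a)))
    ib = int(np.argmin(np.abs(t - b)))
    return float((traj.log_bmi[ib] - traj.log_bmi[ia]) / (t[ib] - t[ia]))


def window_auc(fit: LMMFit, blup_i, a: float, b: float) -> float:
    """Closed-form ``int_a^b yhat(t) dt`` in log-BMI x years.

    Integrates the monomial and truncated-power basis terms analytically
    (``(t-k)_+^3`` integrates to ``(t-k)_+^4 / 4``), so the result is
    exact for the fitted spline regardless of any prediction grid.
    """
    if a >= b:
        raise ValueError("window must have a < b")
    total = float(integral_row(fit.spec.fixed, a, b) @ fit.fixed_coef())
    if blup_i is not None and fit.spec.random is not None:
        total += float(integral_row(fit.spec.random, a, b) @ np.asarray(blup_i, dtype=float))
    return total


def derive_phenotypes(
    fit: LMMFit,
    table: pd.DataFrame,
    age_range=(MIN_AGE_WEEKS2, 17.0),
    windows: dict | None = None,
    step: float = 0.01,
) -> pd.DataFrame:
    """All twelve estimated phenotypes, one row per subject.

    Windows that fall outside ``age_range`` (e.g. adolescence in a cohort
    followed only to 16 years) come back missing for every subject.
    Missingness is per-phenotype: a subject without an AP/AR keeps their
    slopes and AUCs.
    """
    windows = DEFAULT_WINDOWS if windows is None else windows
    b = blups(fit, table)
    rows = {}
    for iid, brow in b.iterrows():
        traj = predict_trajectory(fit, brow.values, age_range=age_range, step=step, iid=iid)
        ap_age, ap_bmi, ar_age, ar_bmi = find_ap_ar(traj)
        row = {"ap_age": ap_age, "ap_bmi": ap_bmi, "ar_age": ar_age, "ar_bmi": ar_bmi}
        for name, (wa, wb) in windows.items():
            if wa < age_range[0] - step / 2 or wb > age_range[1] + step / 2:
                row[f"slope_{name}"] = np.nan
                row[f"auc_{name}"] = np.nan
            else:
                row[f"slope_{name}"] = window_slope(traj, wa, wb)
                row[f"auc_{name}"] = window_auc(fit, brow.values, wa, wb)
        rows[iid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "iid"
    cols = [c for c in PHENOTYPE_COLUMNS if c in out.columns]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra]


def iqr_exclusion(phenotypes: pd.DataFrame, k: float = 2.0):
    """Flag subjects outside ``[Q1 - k*IQR, Q3 + k*IQR]`` on any phenotype.

    Quartiles use linear interpolation (NumPy's default, R type 7).
    Returns ``(outlier mask, filtered table)``; a subject flagged on one
    phenotype is excluded from every downstream analysis.  All-missing
    phenotype columns are skipped.
    """
    mask = pd.Series(False, index=phenotypes.index)
    for col in phenotypes.columns:
        vals = phenotypes[col].dropna()
        if len(vals) < 4:
            continue
        q1, q3 = np.quantile(vals.to_numpy(dtype=float), [0.25, 0.75])
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        bad = (phenotypes[col] < lo) | (phenotypes[col] > hi)
        mask |= bad.fillna(False)
    return mask, phenotypes[~mask]


def percent_bmi_change(slope: float, years: float = 1.0) -> float:
    """Percent BMI change implied by a log-BMI slope over ``years``.

    A slope s on the log scale compounds to ``100 * (exp(s * years) - 1)``
    percent on the BMI scale — e.g. 0.56/yr over one year is a 75% rise.
    """
    return 100.0 * (np.exp(slope * years) - 1.0)


def phenotype_summaries(
    phenotypes: pd.DataFrame,
    sex: pd.Series,
    end_bmi: pd.Series | None = None,
) -> dict:
    """Descriptive validation: per-sex means/SDs, correlations, end-BMI R2.

    ``sex`` and ``end_bmi`` are indexed by iid.  Correlations are Pearson,
    pairwise-complete.  When ``end_bmi`` (BMI at the end of the modelled
    trajectory) is given, each phenotype is z-scored within the cohort and
    regressed on z-scored end BMI with a sex indicator; the adjusted R2
    per phenotype quantifies how much end-of-trajectory BMI the phenotype
    captures.
    """
    sex = sex.reindex(phenotypes.index)
    by_sex = phenotypes.groupby(sex).agg(["mean", "std"])
    corr = phenotypes.corr(method="pearson")
    out = {"by_sex": by_sex, "correlations": corr}
    if end_bmi is not None:
        end_z = _zscore(end_bmi.reindex(phenotypes.index))
        sex_num = (sex == "male").astype(float)
        r2 = {}
        for col in phenotypes.columns:
            z = _zscore(phenotypes[col])
            dat = pd.DataFrame({"y": z, "end": end_z, "sex": sex_num}).dropna()
            if len(dat) < 10:
                r2[col] = np.nan
                continue
            X = sm.add_constant(dat[["end", "sex"]])
            r2[col] = float(sm.OLS(dat["y"], X).fit().rsquared_adj)
        out["end_bmi_adj_r2"] = pd.Series(r2)
    return out


def _zscore(s: pd.Series) -> pd.Series:
    return (s - s.mean()) / s.std()
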