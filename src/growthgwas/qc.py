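"""Quality control for longitudinal height/weight records.

Implements a self-contained, deterministic version of the standard
paediatric-anthropometry cleaning taxonomy: missing components, same-day
duplicates, carried-forward values, unit-switch errors, extreme values,
implausible height decreases, moderate outliers against an exponentially
weighted moving average of the subject's own measurements, and an
error-load rule that drops subjects with too many flagged records.

Robust z-scores are computed against a running median of the cohort
(within sex, ordered by age): the residual from the running median removes
the age trend, and its scale is a median absolute deviation within broad
age bins, so no external growth reference is needed.  All thresholds live
in :class:`QCConfig` and are documented module decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import LB_PER_KG

__all__ = ["QCConfig", "QCFlag", "flag_records", "derive_analysis_set"]

QC_FLAGS = (
    "missing_component",
    "same_day_duplicate",
    "carried_forward",
    "unit_switch",
    "extreme_z",
    "height_decrease",
    "single_measure_pair_mismatch",
    "moderate_outlier_ewma",
    "error_load",
    "age_out_of_window",
    "multiple_birth",
)


class QCFlag:
    """Namespace for the closed flag vocabulary."""

    members = frozenset(QC_FLAGS)

    @classmethod
    def validate(cls, flag: str) -> str:
        if flag not in cls.members:
            raise ValueError(f"unknown QC flag {flag!r}")
        return flag


@dataclass(frozen=True)
class QCConfig:
    """Cleaning thresholds (all module decisions, stated in the docs).

    unit_switch_z / unit_switch_ok_z: a weight is a kg<->lb switch when its
    robust |z| exceeds the first and the converted value falls below the
    second.  extreme_z: |z| beyond this is biologically implausible.
    height_drop_cm: maximum tolerated decrease between sequential heights.
    ewma_half_life_yr / ewma_c: moderate-outlier rule — measurement further
    than c robust SDs from the EWMA of the subject's other de-trended
    residuals.  error_load_frac: subjects with more than this fraction of
    records flagged lose all records.  running_window: records in the
    running-median window; age_bin_yr: bin width for the residual scale.
    """

    unit_switch_z: float = 3.5
    unit_switch_ok_z: float = 2.0
    extreme_z: float = 25.0
    height_drop_cm: float = 3.0
    ewma_half_life_yr: float = 0.5
    ewma_c: float = 3.0
    error_load_frac: float = 0.5
    pair_mismatch_z: float = 5.0
    ewma_min_weight: float = 0.2
    running_window: int = 31


def _running_median_z(df: pd.DataFrame, value_col: str, cfg: QCConfig):
    """Robust z of log(value) against a sex-specific running median.

    Values are de-trended by a centred running median over age order (the
    window is in records, so it adapts to sampling density); the residual
    scale is a local 1.4826*MAD over the same window, floored by half the
    global MAD.  Returns ``(z, scale)`` — the scale is reused to express
    a candidate unit-switch correction in z units.
    """
    z = pd.Series(np.nan, index=df.index)
    scale_out = pd.Series(np.nan, index=df.index)
    ok = df[value_col].notna() & (df[value_col] > 0)
    for _, sub in df[ok].groupby("sex", sort=True):
        sub = sub.sort_values(["age", "rid"], kind="stable")
        logv = np.log(sub[value_col].to_numpy(dtype=float))
        win = min(cfg.running_window, len(sub))
        roll = pd.Series(logv).rolling(window=win, center=True, min_periods=1)
        med = roll.median().to_numpy()
        resid = logv - med
        # local MAD: resid is locally centred, so median |resid| suffices
        local = (
            pd.Series(np.abs(resid))
            .rolling(window=win, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        global_mad = 1.4826 * np.nanmedian(np.abs(resid - np.nanmedian(resid)))
        floor = max(0.5 * max(global_mad, 1e-3), 0.01)
        scale = np.maximum(1.4826 * local, floor)
        z.loc[sub.index] = resid / scale
        scale_out.loc[sub.index] = scale
    return z, scale_out


def _ewma_outlier(sub: pd.DataFrame, resid: pd.Series, cfg: QCConfig) -> np.ndarray:
    """Moderate-outlier test on one subject's de-trended residuals."""
    r = resid.loc[sub.index].to_numpy(dtype=float)
    ages = sub["age"].to_numpy(dtype=float)
    n = len(r)
    out = np.zeros(n, dtype=bool)
    if n < 3:
        return out
    lam = np.log(2.0) / cfg.ewma_half_life_yr
    sd = 1.4826 * np.median(np.abs(r - np.median(r)))
    sd = max(sd, 0.02)  # floor: log-scale measurement noise
    for i in range(n):
        w = np.exp(-lam * np.abs(ages - ages[i]))
        w[i] = 0.0
        mask = np.isfinite(r) & (w > 1e-6)
        mask[i] = False
        # too little nearby information to judge this measurement
        if w[mask].sum() <= cfg.ewma_min_weight:
            continue
        ewma = np.sum(w[mask] * r[mask]) / w[mask].sum()
        if np.isfinite(r[i]) and abs(r[i] - ewma) > cfg.ewma_c * max(sd, 1e-8):
            out[i] = True
    return out


def flag_records(records: pd.DataFrame, qc_config: QCConfig | None = None):
    """Apply the cleaning taxonomy; returns ``(flagged records, summary)``.

    The input must be sorted by (iid, age).  Flags are recomputed from the
    data alone (existing flags are ignored and reproduced), which makes the
    operation idempotent.  The returned records carry a ``flags`` column
    (comma-joined, '' = clean); the summary counts records per flag.
    """
    cfg = qc_config or QCConfig()
    df = records.reset_index(drop=True).copy()
    key = df[["iid", "age"]].to_numpy()
    if any(
        (key[i][0] == key[i + 1][0] and key[i][1] > key[i + 1][1])
        for i in range(len(df) - 1)
    ):
        raise ValueError("records must be sorted by (iid, age)")
    bad_sex = ~df["sex"].isin(["male", "female"])
    if bad_sex.any():
        raise ValueError(f"unknown sex codes: {sorted(df.loc[bad_sex, 'sex'].unique())}")
    if "rid" not in df.columns:
        df.insert(0, "rid", np.arange(len(df)))

    flags: dict[int, set[str]] = {i: set() for i in df.index}

    def add(mask, flag):
        QCFlag.validate(flag)
        for i in df.index[np.asarray(mask, dtype=bool)]:
            flags[i].add(flag)

    # 1. missing / non-positive components
    missing = (
        df["weight"].isna()
        | df["height"].isna()
        | (df["weight"] <= 0)
        | (df["height"] <= 0)
    )
    add(missing, "missing_component")

    # 2. same-day duplicates: keep first in file order, flag the rest
    dup = df.duplicated(subset=["iid", "age"], keep="first")
    add(dup, "same_day_duplicate")

    # 3. carried forward: identical consecutive value of the same measure
    for col in ("weight", "height"):
        same_subj = df["iid"].eq(df["iid"].shift())
        carried = same_subj & df[col].eq(df[col].shift()) & df[col].notna()
        carried &= ~dup  # a same-day duplicate is its own category
        add(carried, "carried_forward")

    # 4-5. unit switches then extreme values, from robust weight/height z
    zw, scale = _running_median_z(df, "weight", cfg)
    zh, _ = _running_median_z(df, "height", cfg)
    with np.errstate(invalid="ignore"):
        big = zw.abs() > cfg.unit_switch_z
    log_factor = np.log(LB_PER_KG)
    # a kg->lb switch shifts log weight by +log(2.2046): the corrected z is
    # z minus that shift over the local residual scale, tested both ways
    unit = pd.Series(False, index=df.index)
    for sign in (+1.0, -1.0):
        zc = zw - sign * log_factor / scale
        unit |= big & (zc.abs() < cfg.unit_switch_ok_z) & (sign * zw > 0)
    add(unit.fillna(False), "unit_switch")

    extreme = (zw.abs() > cfg.extreme_z) | (zh.abs() > cfg.extreme_z)
    extreme &= ~unit.fillna(False)
    add(extreme.fillna(False), "extreme_z")

    # 6. height decrease > threshold between sequential measurements
    same_subj = df["iid"].eq(df["iid"].shift())
    drop_m = same_subj & ((df["height"].shift() - df["height"]) > cfg.height_drop_cm / 100.0)
    add(drop_m.fillna(False), "height_decrease")

    # 7. single measurement pair: weight z vs height z wildly inconsistent
    counts = df.groupby("iid")["rid"].transform("count")
    single = counts == 1
    mismatch = single & ((zw - zh).abs() > cfg.pair_mismatch_z)
    add(mismatch.fillna(False), "single_measure_pair_mismatch")

    # 8. moderate outliers vs EWMA of the subject's other residuals
    resid_w = zw * scale  # de-trended log-weight residuals
    hard = {
        i
        for i, f in flags.items()
        if f & {"unit_switch", "extreme_z", "same_day_duplicate", "missing_component"}
    }
    for _, sub in df.groupby("iid", sort=True):
        keep = [i for i in sub.index if i not in hard]
        if len(keep) < 3:
            continue
        sub_ok = sub.loc[keep]
        out = _ewma_outlier(sub_ok, resid_w, cfg)
        for i, bad in zip(sub_ok.index, out):
            if bad:
                flags[i].add("moderate_outlier_ewma")

    # 9. error load: too many flagged records -> flag the whole subject
    flagged_now = df.index.map(lambda i: bool(flags[i]))
    frac = (
        pd.Series(flagged_now, index=df.index).groupby(df["iid"]).transform("mean")
    )
    add((frac > cfg.error_load_frac).to_numpy(), "error_load")

    df["flags"] = [",".join(sorted(flags[i])) for i in df.index]
    summary = (
        pd.Series(
            [f for i in df.index for f in flags[i]], dtype=object
        ).value_counts()
        .rename_axis("flag")
        .reset_index(name="n")
    )
    summary["pct"] = 100.0 * summary["n"] / max(len(df), 1)
    return df, summary


def derive_analysis_set(
    records: pd.DataFrame,
    min_age: float = 2.0 / 52.0,
    max_age: float = 18.0,
    multiple_birth: pd.Series | None = None,
) -> pd.DataFrame:
    """Build the modelling table from flagged records.

    Drops every flagged record, restricts to ``min_age <= age <= max_age``
    (the analysis window; shorter cohorts pass a smaller ``max_age``),
    optionally drops multiple-birth subjects, then derives
    ``log_bmi = ln(weight / height**2)``.  Returns columns
    (iid, sex, age, log_bmi, source).
    """
    df = records.copy()
    if "flags" not in df.columns:
        raise ValueError("records must be flagged first (run flag_records)")
    clean = df[df["flags"].fillna("") == ""]
    clean = clean[(clean["age"] >= min_age) & (clean["age"] <= max_age)]
    if multiple_birth is not None:
        multi = set(multiple_birth[multiple_birth.astype(bool)].index)
        clean = clean[~clean["iid"].isin(multi)]
    clean = clean[(clean["weight"] > 0) & (clean["height"] > 0)]
    out = clean[["iid", "sex", "age"]].copy()
    out["log_bmi"] = np.log(clean["weight"] / clean["height"] ** 2)
    if "source" in clean.columns:
        out["source"] = clean["source"]
    return out.reset_index(drop=True)
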