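"""Candidate-model grid, preferred-model choice and knot refinement.

The default grid crosses three fixed-effect bases for age — cubic slope,
linear splines with knots at 5.5 and 11 years, cubic splines with knots at
(2, 8, 12) years — with reduced-complexity random-effect bases and with or
without a CAR(1) residual correlation: sixteen candidate mixed models,
each fitted separately by sex.  Every cell records a convergence status
(ok / warning / error); ranking considers AIC and BIC but never prefers a
failed fit.  The preferred model across cohorts is the eligible
specification (status ok in every cohort and sex) with the smallest summed
AIC, BIC then parameter count breaking ties, and the better-AIC but
ineligible specifications are reported alongside.  Knot refinement refits
the chosen cubic-spline model over a grid of first and second knots and
recommends the combination with the best AIC whose implied mean adiposity
peak age is plausible.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from .lmm import LMMFit, ModelSpec, diagnostics, fit_lmm
from .phenotypes import derive_phenotypes
from .splines import SplineSpec

__all__ = ["default_grid", "run_model_grid", "select_preferred", "refine_knots"]


def default_grid(
    cubic_knots=(2.0, 8.0, 12.0), linear_knots=(5.5, 11.0), covariates=()
) -> list[ModelSpec]:
    """The sixteen-cell candidate grid (eight structures x CAR(1) on/off)."""
    cs = SplineSpec("cubic_slope")
    ls = SplineSpec("linear_spline", linear_knots)
    cub = SplineSpec("cubic_spline", cubic_knots)
    structures = [
        (cs, SplineSpec("cubic_slope")),
        (cs, SplineSpec("quadratic")),
        (cs, SplineSpec("linear")),
        (ls, SplineSpec("linear_spline", linear_knots)),
        (cub, SplineSpec("cubic_spline", cubic_knots)),
        (cub, SplineSpec("quadratic_spline", cubic_knots)),
        (cub, SplineSpec("linear_spline", cubic_knots)),
        (cub, SplineSpec("cubic_slope")),
    ]
    return [
        ModelSpec(fixed=f, random=r, correlation=corr, covariates=tuple(covariates))
        for f, r in structures
        for corr in ("none", "car1")
    ]


def run_model_grid(
    table: pd.DataFrame,
    grid: list[ModelSpec] | None = None,
    sexes=("male", "female"),
    method: str = "ML",
) -> pd.DataFrame:
    """Fit every grid cell per sex; one result row per (model, sex).

    Failures are captured as status ``error`` rows — no exception escapes
    the grid.  Rows with status ok are ranked by AIC within sex; warning
    and error rows get no rank.
    """
    grid = default_grid() if grid is None else grid
    rows = []
    for sex in sexes:
        sub = table[table["sex"] == sex]
        for spec in grid:
            t0 = time.perf_counter()
            status, message, aic, bic, diag, fit = "error", "", np.nan, np.nan, None, None
            try:
                fit = fit_lmm(sub, spec, method=method)
                status, message = fit.converged, fit.message
                if fit.ok:
                    diag = diagnostics(fit, sub)
                    aic, bic = diag.aic, diag.bic
            except Exception as exc:  # defensive: grid must finish
                message = str(exc)
            rows.append(
                {
                    "model": spec.label(),
                    "sex": sex,
                    "status": status,
                    "aic": aic,
                    "bic": bic,
                    "rmse": diag.rmse if diag else np.nan,
                    "icc": diag.icc if diag else np.nan,
                    "r2_marginal": diag.r2_marginal if diag else np.nan,
                    "r2_conditional": diag.r2_conditional if diag else np.nan,
                    "n_params": fit.n_params if fit is not None else 0,
                    "runtime_s": time.perf_counter() - t0,
                    "message": message,
                    "spec": spec,
                }
            )
    out = pd.DataFrame(rows)
    out["rank"] = np.nan
    for sex in sexes:
        ok = (out["sex"] == sex) & (out["status"] == "ok")
        out.loc[ok, "rank"] = out.loc[ok, "aic"].rank(method="first")
    return out


def select_preferred(grids: list[pd.DataFrame]):
    """Choose one model across cohorts; returns ``(spec, report)``.

    Eligible = status ok in every cohort and sex.  Among eligible, the
    smallest AIC summed over all cohort x sex cells wins; ties go to
    summed BIC, then to fewer parameters.  The report lists ineligible
    specifications whose summed AIC (over the cells where it exists)
    would have beaten the winner, mirroring the convergence-aware
    selection narrative.  With no eligible model, falls back to the
    specification with the fewest failed cells.
    """
    if not grids:
        raise ValueError("need at least one cohort grid")
    allg = pd.concat(
        [g.assign(cohort=i) for i, g in enumerate(grids)], ignore_index=True
    )
    agg = allg.groupby("model").agg(
        n_cells=("status", "size"),
        n_ok=("status", lambda s: int((s == "ok").sum())),
        n_error=("status", lambda s: int((s == "error").sum())),
        sum_aic=("aic", "sum"),
        sum_bic=("bic", "sum"),
        n_params=("n_params", "max"),
    )
    agg["eligible"] = agg["n_ok"] == agg["n_cells"]
    # AIC differences below 1e-6 are numerical noise: round before ranking
    # so that BIC (then parameter count) genuinely breaks ties
    agg["_aic_key"] = np.round(agg["sum_aic"], 6)
    agg["_bic_key"] = np.round(agg["sum_bic"], 6)
    eligible = agg[agg["eligible"]]
    if len(eligible):
        ranked = eligible.sort_values(
            ["_aic_key", "_bic_key", "n_params"], kind="stable"
        )
        winner = ranked.index[0]
        better = agg[(~agg["eligible"]) & (agg["sum_aic"] < ranked["sum_aic"].iloc[0])]
        note = ""
    else:
        ranked = agg.sort_values(
            ["n_error", "_aic_key", "_bic_key"], kind="stable"
        )
        winner = ranked.index[0]
        better = agg.iloc[0:0]
        note = "no specification converged cleanly everywhere; fewest-failure fallback"
    spec = allg.loc[allg["model"] == winner, "spec"].iloc[0]
    agg = agg.drop(columns=["_aic_key", "_bic_key"])
    report = {
        "preferred": winner,
        "table": agg.sort_values(["eligible", "sum_aic"], ascending=[False, True]),
        "ineligible_better_aic": list(better.index),
        "note": note,
    }
    return spec, report


def refine_knots(
    table: pd.DataFrame,
    base_spec: ModelSpec,
    knot1=(1.0, 1.5, 2.0),
    knot2=(6.0, 7.0, 8.0),
    knot3: float = 12.0,
    ap_window=(0.5, 1.0),
    sexes=("male", "female"),
    method: str = "ML",
):
    """Refit the cubic-spline model over a first/second-knot grid.

    For each (knot1, knot2, knot3) combination, reports AIC/BIC summed
    over sexes plus the mean estimated age at the adiposity peak and
    rebound.  The recommended combination is the smallest-AIC cell whose
    mean AP age falls inside ``ap_window`` (prior evidence puts the
    population mean near nine months); failed cells are excluded.
    Returns ``(report, recommended knots or None)``.
    """
    if base_spec.fixed.form != "cubic_spline":
        raise ValueError("knot refinement applies to cubic-spline models")
    rows = []
    for k1 in knot1:
        for k2 in knot2:
            knots = (float(k1), float(k2), float(knot3))
            spec = ModelSpec(
                fixed=SplineSpec("cubic_spline", knots),
                random=_with_knots(base_spec.random, knots),
                correlation=base_spec.correlation,
                covariates=base_spec.covariates,
            )
            aics, bics, aps, ars, statuses = [], [], [], [], []
            for sex in sexes:
                sub = table[table["sex"] == sex]
                try:
                    fit = fit_lmm(sub, spec, method=method)
                except Exception:
                    statuses.append("error")
                    continue
                statuses.append(fit.converged)
                if not fit.ok:
                    continue
                d = diagnostics(fit, sub)
                aics.append(d.aic)
                bics.append(d.bic)
                ph = derive_phenotypes(fit, sub)
                aps.append(float(ph["ap_age"].mean()))
                ars.append(float(ph["ar_age"].mean()))
            failed = any(s == "error" for s in statuses) or not aics
            rows.append(
                {
                    "knot1": k1,
                    "knot2": k2,
                    "knot3": knot3,
                    "status": "error" if failed else (
                        "warning" if any(s == "warning" for s in statuses) else "ok"
                    ),
                    "aic": float(np.sum(aics)) if aics else np.nan,
                    "bic": float(np.sum(bics)) if bics else np.nan,
                    "mean_ap_age": float(np.nanmean(aps)) if aps else np.nan,
                    "mean_ar_age": float(np.nanmean(ars)) if ars else np.nan,
                }
            )
    report = pd.DataFrame(rows)
    usable = report[report["status"] != "error"]
    plausible = usable[
        (usable["mean_ap_age"] >= ap_window[0]) & (usable["mean_ap_age"] <= ap_window[1])
    ]
    if len(plausible):
        best = plausible.sort_values(["aic", "bic"], kind="stable").iloc[0]
        rec = (float(best["knot1"]), float(best["knot2"]), float(best["knot3"]))
    else:
        rec = None
    return report, rec


def _with_knots(random: SplineSpec | None, knots) -> SplineSpec | None:
    if random is None or random.tp_degree == 0:
        return random
    return SplineSpec(random.form, knots[: len(random.knots)])
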