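"""Fit the preferred BMI-trajectory mixed model and read its diagnostics.

The model: log BMI follows a cubic spline in age with knots at 1, 8 and
12 years in the fixed effects, a cubic polynomial in the random effects,
independent residuals, fitted per sex by maximum likelihood.
"""

import numpy as np

from growthgwas import ModelSpec, SplineSpec, diagnostics, fit_lmm
from growthgwas.simulate import default_config, simulate_cohort

cfg = default_config(n_subjects=300, seed=11)
records, _ = simulate_cohort(cfg)
table = records.assign(log_bmi=np.log(records["weight"] / records["height"] ** 2))

spec = ModelSpec(
    fixed=SplineSpec("cubic_spline", (1.0, 8.0, 12.0)),
    random=SplineSpec("cubic_slope"),
)
for sex in ("male", "female"):
    sub = table[table["sex"] == sex]
    fit = fit_lmm(sub, spec)
    d = diagnostics(fit, sub)
    print(f"--- {sex}: status={fit.converged}")
    print("  spline coefficients:", np.round(fit.fixed_coef(), 4))
    print(f"  residual SD {np.sqrt(fit.sigma2):.4f} log-BMI units, "
          f"ICC {d.icc:.3f} (subject-level share of variance at birth)")
    print(f"  AIC {d.aic:.1f}  BIC {d.bic:.1f}  RMSE {d.rmse:.4f}  "
          f"R2 marginal {d.r2_marginal:.3f} / conditional {d.r2_conditional:.3f}")

print(
    "\nThe conditional R2 (fixed curve + subject effects) is far above the "
    "marginal R2 (fixed curve alone): most variation is between children, "
    "which is exactly what the subject-level random effects capture."
)
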